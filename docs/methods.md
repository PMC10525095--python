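# Methods

This note records the modelling choices behind `vitstack`: what the
pipeline computes, what the synthetic cohorts do and do not emulate, and
the decisions taken where the design was genuinely open.

## Problem setting

The pipeline targets binary lesion-aggressiveness grading (low grade, LG=0,
vs high grade, HG=1) from single-channel volumetric acquisitions, the
setting of axial T2-weighted prostate MRI with biopsy-confirmed Gleason
grades.  Cohorts of this kind are small (around a hundred lesions), highly
imbalanced (roughly 2:1 LG:HG), and carry metadata that matters for
evaluation hygiene: patient identity (patients can contribute several
lesions) and anatomical zone (peripheral zone PZ, anterior stroma AS,
transition zone TZ), both used as stratification variables.

## Synthetic phantom cohorts

`synthetic.generate_cohort` draws seeded phantoms so every downstream stage
is testable without data downloads.  Each phantom is a bright ellipsoidal
"gland" (semi-axes 25–40% of the matrix, mild per-case brightness
variation) on a dark noisy background, with a Gaussian-footprint lesion
blob on a known slice, multiplicatively modulating the local signal.
Grade enters through the blob:

* mean contrast ~ N(0.30, 0.10) for LG, shifted by `effect_size × 0.10`
  for HG — `effect_size` is therefore a separation in within-class SD
  units;
* speckle SD `0.05 × (1 + 0.2·effect_size·label)`, so second-order texture
  also carries grade, and the zero-effect cohort is identical in law
  across classes.

Defaults emulate the study composition: 112 lesions over 99 patients
(surplus lesions assigned to random patients, making patient-wise splitting
non-trivial), 77 LG / 35 HG, 50 PZ / 47 AS / 15 TZ, in-plane matrices drawn
from {320, 384} with 384 the mode so resampling is exercised, 7 slices,
0.5 mm in-plane spacing, 3.6 mm slice thickness carried as metadata only.
`effect_size` defaults to 2.5: the best achievable AUROC from the mean
contrast alone is Φ(effect_size/√2) ≈ 0.96 — clearly learnable but not
trivially saturated, which is what a usable benchmark cohort needs.
Lesion slices are drawn at least two slices from the acquisition edges
(lesions live inside the gland); edge clamping in slice selection is
covered by direct tests instead.

Phantoms record their in-plane lesion centre, mirroring the lesion
coordinates shipped with real challenge datasets.
`lesion_contrast_statistic` uses it: mean ROI intensity on the lesion slice
divided by the same ROI on the neighbouring slices, which cancels
multiplicative brightness/geometry nuisance and recovers the drawn
contrast.  The separability checks classify on this statistic.

What the phantoms do **not** emulate: MR physics (bias fields, coil
profiles, TE/TR contrast), anatomy beyond one ellipsoid, inter-scanner
variation, zone-dependent lesion appearance, or any correlation between
zone and grade.  Passing tests therefore show the pipeline's mechanics and
statistics are correct, not that the transformer would reach any particular
accuracy on clinical data.

## Preprocessing

Lesion-centred slice selection keeps the lesion slice ±2 (five slices);
indices past the volume edge are clamped with nearest-slice replication so
the output shape contract (crop × crop × 5 × 1) is uniform.  In-plane
resampling is corner-aligned bilinear interpolation to a 384-pixel
reference (upsampling in the intended regime; downsampling works but logs a
warning), followed by a centre crop to 128 pixels with floor-division
offsets for odd differences.

Class balancing selects `(n_major − n_minor) / 3` minority volumes without
replacement under a fixed seed and emits exactly one vertical flip, one
horizontal flip and one rotation per selected volume — the natural reading
of "three augmented versions using the stated techniques" that uses each
technique once.  The rotation angle is drawn once per volume from ±25° and
applied identically to every slice (bilinear).  A gap not divisible by 3
raises a typed error in strict mode; in non-strict mode (used after
bootstrap resampling, where the gap is arbitrary) the remainder is left
unaugmented and logged.  Normalisation subtracts a single scalar — the
training-set grand-mean voxel value — from all sets.

## The 3D transformer

The architecture is a standard pre-norm ViT encoder over 3D patches
spanning the full slice depth, with a classification-token readout and a
one-logit sigmoid head.  The readout is an assumption: the architecture
diagrams this family of models publishes leave the head unspecified, and
the class-token head is the standard ViT choice.  The 18-configuration grid
ties the embedding size to the patch content (`D = P²C/k`); the MLP widths
are the literal grid values {2048, 3072} — the alternative rule
`d = P²·C·N` (shipped as a documented helper, `derive_mlp_size`) would give
16384 on the canonical crop and is not used by the grid.

Everything is NumPy/float64 with hand-derived backward passes (no deep
learning framework is required at runtime); `tests/test_nn.py` checks the
full model's gradients against central finite differences.  Training is
Adam (β = 0.9/0.999, non-decoupled L2 weight decay 1e-2 folded into the
gradient, matching the common framework convention), binary cross-entropy,
batch size 4, 1000 steps with linear learning-rate warmup over 1000 steps —
warmup equal to the step budget makes the schedule a pure linear ramp, and
it is implemented exactly so.  Dropout defaults to 0.  All randomness
(init, shuffling, dropout) flows from explicit seeds; two runs with the
same seed are bit-identical.

The overfit smoke test uses a 32×32×5 crop (4 patch tokens) and a small
grid-consistent configuration (D=16, k=16, L=2, d=64) so the full
1000-step budget completes in seconds on one CPU, with the canonical
hyperparameters unchanged.

## Stacking ensembles

The meta-classifier is a single linear map `y = xAᵀ + b` with sigmoid
output, trained with Adam/BCE for 100 epochs on the concatenated outputs of
the frozen bases.  "Output of a base model" is ambiguous between the
scalar pre-sigmoid logit, the post-sigmoid probability, and the
classification-token embedding; all three are supported
(`feature_mode`), with the scalar logit — the minimal reading — as the
default.  Bases are frozen by construction (they are only queried for
features), and a test asserts their parameters are bit-identical before and
after meta-training.  A probability of exactly 0.5 classifies negative
(strict "exceeds 0.5" rule).

## Metrics

CSP and CSE use inclusive confidence bands (≤ 0.3, ≥ 0.7): the operative
definition of a confident correct prediction is stated inclusively even
where the formulas use strict inequalities, and the inclusive reading is
implemented (boundaries configurable).  AUPRC uses the average-precision
convention rather than trapezoidal interpolation, which avoids optimistic
interpolation on skewed data — the reason AUPRC is reported at all.  Note
that on a small test set the *expected* average precision of a random
ranking exceeds the prevalence (a known small-sample bias of the AP
estimator); the prevalence baseline is the analytic value of the uninformative
(constant-score) classifier, which is what the chance-baseline check
asserts exactly, with Monte Carlo used for the AUROC = 0.5 baseline.
Undefined class-conditional metrics (no negatives for CSP/BSNC, no
positives for CSE/BSPC) raise a typed `UndefinedMetricError` rather than
returning a sentinel.

## Splits, bootstrap, statistics

Splits are patient-wise and stratified on the joint (grade, zone) label.
The 80/20 split apportions `floor(0.2·n)` test lesions across strata by
largest remainder (hitting 22 of 112 exactly), then fills each stratum's
quota with randomly drawn patients whose lesions all lie in that stratum;
patients spanning strata stay in training.  Five-fold CV deals shuffled
patients to the fold currently holding the fewest lesions of their stratum.
Under patient-wise assignment with multi-lesion patients a strict ±1-lesion
marginal balance per fold is not attainable in general; the per-stratum
across-fold spread is within one lesion when every patient has one lesion,
and the tests assert exactly that.

The bootstrap draws 100 resamples of the training set with replacement
(same size), re-trains via a user-supplied builder, evaluates on the fixed
hold-out test set, and summarises each metric by its median and percentile
(2.5/97.5) 95% CI — the simplest defensible reading of a bootstrap CI.
Resamples are not re-stratified; class balancing is re-applied after
resampling in non-strict mode.  Comparison records Shapiro–Wilk p-values
(the motivation for a non-parametric test) and runs the two-sided Wilcoxon
signed-rank test on the 100 paired differences, discarding zero differences
(classic convention); the reported W is the smaller signed-rank sum, the
convention of `scipy.stats.wilcoxon`.  All-zero differences are reported as
a degenerate comparison (W=0, p=1) instead of an error.

## Known limitations

* The phantom generator's simplicity means absolute metric values on
  phantoms say nothing about clinical performance; only the pipeline's
  arithmetic, contracts and statistical machinery are validated.
* The published per-cell split table of the study this family of pipelines
  follows is internally inconsistent with its own subtotals; this
  implementation trusts the totals (90 train+val / 22 test of 112; 54 LG /
  27 HG pre-balancing training text; 16 LG / 6 HG test).
* NumPy training is single-threaded BLAS-bound; the canonical 128-crop
  configurations train in minutes, not seconds, and no GPU path exists.
* Ensembles larger than three members, soft-voting baselines, and
  hyperparameter search are out of scope.
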