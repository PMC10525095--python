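"""Study protocol: patient-wise stratified splits, five-fold CV, bootstrap
re-training, and paired statistical comparison.

All splitting is patient-wise — every lesion of a patient lands on the same
side of every split — so no anatomical information leaks between training
and evaluation.  Splits are stratified jointly on lesion grade and
anatomical zone, with integer targets obtained by largest-remainder
apportionment so printed totals (e.g. 22 test lesions out of 112 at 20%)
are hit exactly.

Model comparison follows the protocol of re-training on 100 bootstrap
resamples of the training set, evaluating each re-trained model on the fixed
hold-out test set, summarising each metric's distribution by its median and
percentile 95% CI, and testing paired differences with the Wilcoxon
signed-rank test (after recording Shapiro-Wilk normality checks that
motivate the non-parametric choice).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .metrics import MetricsReport, compute_report, records_from_arrays

__all__ = [
    "SplitError", "SplitPlan", "BootstrapDistribution", "StatTestResult",
    "stratified_split", "five_fold_cv", "bootstrap_train_eval",
    "compare_models",
]

log = logging.getLogger(__name__)


class SplitError(ValueError):
    """No patient-wise assignment can satisfy the stratum targets."""


@dataclass(frozen=True)
class SplitPlan:
    """Lesion-level assignment table with its seed.

    ``assignment`` maps manifest row index -> group name ("train"/"test" or
    "fold0".."fold4").
    """

    assignment: dict[int, str]
    strata: dict[int, tuple[int, str]]
    seed: int

    def indices(self, group: str) -> list[int]:
        return sorted(i for i, g in self.assignment.items() if g == group)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "index": sorted(self.assignment),
            "group": [self.assignment[i] for i in sorted(self.assignment)],
        })


def _largest_remainder_counts(sizes: Mapping, total: int) -> dict:
    keys = sorted(sizes)
    weights = np.array([sizes[k] for k in keys], dtype=float)
    quotas = weights / weights.sum() * total
    counts = np.floor(quotas).astype(int)
    for i in np.argsort(-(quotas - counts))[: total - counts.sum()]:
        counts[i] += 1
    return dict(zip(keys, counts.tolist()))


def _patient_table(manifest: pd.DataFrame) -> pd.DataFrame:
    for col in ("patient_id", "label", "zone"):
        if col not in manifest.columns:
            raise ValueError(f"manifest lacks required column {col!r}")
    df = manifest.reset_index(drop=True).copy()
    df["stratum"] = list(zip(df["label"].astype(int), df["zone"].astype(str)))
    return df


def _pick_exact(counts: list[int], target: int,
                rng: np.random.Generator, retries: int = 200) -> list[int] | None:
    """Indices of a random subset of ``counts`` summing exactly to ``target``."""
    n = len(counts)
    for _ in range(retries):
        order = rng.permutation(n)
        chosen, s = [], 0
        for i in order:
            if s + counts[i] <= target:
                chosen.append(int(i))
                s += counts[i]
            if s == target:
                return chosen
        if s == target:
            return chosen
    return None


def stratified_split(manifest: pd.DataFrame, test_fraction: float = 0.2,
                     seed: int = 0) -> SplitPlan:
    """Patient-wise train/test split stratified on (grade, zone).

    The test set receives ``floor(n * test_fraction)`` lesions, apportioned
    across strata by largest remainder.  Test patients are drawn only from
    patients whose lesions all share one stratum (patients spanning strata
    stay in training), and the draw is retried with seeded randomisation
    until every stratum target is met exactly.
    """
    if not 0.0 <= test_fraction < 1.0:
        raise ValueError("test_fraction must be in [0, 1)")
    df = _patient_table(manifest)
    n_test = int(np.floor(len(df) * test_fraction))
    assignment = {i: "train" for i in df.index}
    strata = {int(i): s for i, s in df["stratum"].items()}
    if n_test == 0:
        return SplitPlan(assignment, strata, seed)

    targets = _largest_remainder_counts(
        df["stratum"].value_counts().to_dict(), n_test)
    rng = np.random.default_rng(seed)
    for stratum, target in sorted(targets.items()):
        if target == 0:
            continue
        in_stratum = df[df["stratum"] == stratum]
        # candidate patients: all their lesions lie in this stratum
        by_patient = df.groupby("patient_id")["stratum"].agg(["nunique"])
        pure = set(by_patient[by_patient["nunique"] == 1].index)
        cand = (in_stratum[in_stratum["patient_id"].isin(pure)]
                .groupby("patient_id").size())
        if cand.sum() < target:
            raise SplitError(
                f"stratum {stratum} has too few single-stratum patients "
                f"({int(cand.sum())} lesions) for its test target {target}")
        picked = _pick_exact(cand.tolist(), target, rng)
        if picked is None:
            raise SplitError(
                f"could not hit test target {target} exactly in stratum {stratum}")
        for pid in cand.index[picked]:
            for i in df.index[df["patient_id"] == pid]:
                assignment[int(i)] = "test"
    return SplitPlan(assignment, strata, seed)


def five_fold_cv(manifest: pd.DataFrame, seed: int = 0,
                 n_folds: int = 5) -> list[SplitPlan]:
    """Patient-wise stratified cross-validation folds.

    Every lesion appears in exactly one validation fold.  Within each
    stratum, patients are shuffled and dealt to the currently smallest fold
    (by lesion count), which keeps per-fold class/zone proportions within
    about one lesion of the global ones.  Patients spanning several strata
    are dealt under their first stratum.
    """
    df = _patient_table(manifest)
    if df["patient_id"].nunique() < n_folds:
        raise ValueError(f"need at least {n_folds} patients")
    rng = np.random.default_rng(seed)
    fold_of_patient: dict[str, int] = {}
    fold_sizes = np.zeros(n_folds, dtype=int)
    stratum_sizes: dict[tuple, np.ndarray] = {}

    patients = df.groupby("patient_id").agg(
        stratum=("stratum", "first"), n=("stratum", "size"))
    for stratum in sorted(df["stratum"].unique()):
        per_fold = stratum_sizes.setdefault(stratum, np.zeros(n_folds, dtype=int))
        pids = patients.index[patients["stratum"] == stratum].to_numpy()
        rng.shuffle(pids)
        for pid in pids:
            if pid in fold_of_patient:
                continue
            # fewest lesions of this stratum, ties broken by overall size
            fold = int(np.lexsort((fold_sizes, per_fold))[0])
            fold_of_patient[pid] = fold
            n = int(patients.loc[pid, "n"])
            fold_sizes[fold] += n
            per_fold[fold] += n

    strata = {int(i): s for i, s in df["stratum"].items()}
    plans = []
    for fold in range(n_folds):
        assignment = {
            int(i): ("val" if fold_of_patient[df.loc[i, "patient_id"]] == fold
                     else "train")
            for i in df.index}
        plans.append(SplitPlan(assignment, strata, seed))
    return plans


@dataclass(frozen=True)
class BootstrapDistribution:
    """Per-metric values across bootstrap re-trainings, with summaries."""

    values: np.ndarray
    median: float
    ci_low: float
    ci_high: float

    @classmethod
    def from_values(cls, values) -> "BootstrapDistribution":
        v = np.asarray(values, dtype=np.float64)
        return cls(values=v, median=float(np.percentile(v, 50)),
                   ci_low=float(np.percentile(v, 2.5)),
                   ci_high=float(np.percentile(v, 97.5)))


def bootstrap_train_eval(train_set: Sequence, test_set: Sequence,
                         model_builder: Callable, n: int = 100,
                         seed: int = 0) -> dict[str, BootstrapDistribution]:
    """Re-train on ``n`` bootstrap resamples, evaluate each on the fixed test set.

    Each resample draws ``len(train_set)`` items with replacement.
    ``model_builder(resampled_train, seed)`` must return a callable mapping a
    list of items to positive-class probabilities.  Returns one
    :class:`BootstrapDistribution` per metric (median and percentile
    2.5/97.5 bounds).
    """
    if n < 1:
        raise ValueError("need at least one bootstrap sample")
    train_set = list(train_set)
    test_set = list(test_set)
    test_labels = [v.label for v in test_set]
    rng = np.random.default_rng(seed)
    per_metric: dict[str, list[float]] = {m: [] for m in MetricsReport.METRIC_NAMES}
    for i in range(n):
        idx = rng.integers(0, len(train_set), size=len(train_set))
        resample = [train_set[j] for j in idx]
        sub_seed = int(rng.integers(0, 2**31 - 1))
        predict = model_builder(resample, sub_seed)
        probs = np.asarray(predict(test_set), dtype=np.float64)
        report = compute_report(records_from_arrays(probs, test_labels))
        for m, v in report.as_dict().items():
            per_metric[m].append(v)
    return {m: BootstrapDistribution.from_values(v) for m, v in per_metric.items()}


@dataclass(frozen=True)
class StatTestResult:
    """Wilcoxon signed-rank comparison of two paired metric distributions."""

    W: float
    p: float
    significant: bool
    degenerate: bool = False
    shapiro_p_a: float = float("nan")
    shapiro_p_b: float = float("nan")


def compare_models(dist_a, dist_b, alpha: float = 0.05) -> StatTestResult:
    """Paired two-sided Wilcoxon signed-rank test on two metric distributions.

    Accepts :class:`BootstrapDistribution` objects or plain arrays of equal
    length.  Shapiro-Wilk p-values for each distribution are recorded (the
    normality check motivating the non-parametric test).  Zero differences
    are discarded (classic convention); the reported W is the smaller of the
    two signed-rank sums.  If every paired difference is zero the test is
    degenerate and reported as W=0, p=1.
    """
    a = np.asarray(getattr(dist_a, "values", dist_a), dtype=np.float64)
    b = np.asarray(getattr(dist_b, "values", dist_b), dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError("paired distributions must have equal length")
    sh_a = float(stats.shapiro(a).pvalue) if np.ptp(a) > 0 else float("nan")
    sh_b = float(stats.shapiro(b).pvalue) if np.ptp(b) > 0 else float("nan")
    diff = a - b
    if np.all(diff == 0):
        return StatTestResult(W=0.0, p=1.0, significant=False, degenerate=True,
                              shapiro_p_a=sh_a, shapiro_p_b=sh_b)
    res = stats.wilcoxon(diff, zero_method="wilcox", alternative="two-sided")
    return StatTestResult(W=float(res.statistic), p=float(res.pvalue),
                          significant=bool(res.pvalue < alpha),
                          shapiro_p_a=sh_a, shapiro_p_b=sh_b)


def compare_all_metrics(dists_a: Mapping[str, BootstrapDistribution],
                        dists_b: Mapping[str, BootstrapDistribution],
                        alpha: float = 0.05) -> dict[str, StatTestResult]:
    return {m: compare_models(dists_a[m], dists_b[m], alpha) for m in dists_a}
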