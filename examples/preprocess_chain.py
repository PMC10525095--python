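"""Walk one lesion volume through the preprocessing chain.

Shows the shape at each stage — lesion-centred slice selection (5 slices),
bilinear resampling to the 384-pixel reference, 128-pixel centre crop — and
then the augmentation-based class balancing arithmetic on a 54/27 training
composition.
"""

from vitstack import (CohortSpec, PreprocessConfig, balance_by_augmentation,
                      center_crop, generate_cohort, mean_normalize,
                      preprocess_volume, resample_inplane, select_slices)

cfg = PreprocessConfig()
volumes, _ = generate_cohort(CohortSpec(n_patients=81, n_lesions=81,
                                        class_fractions=(54 / 81, 27 / 81),
                                        seed=1))
v = volumes[0]
print("raw volume:          ", v.voxels.shape, f"(lesion on slice {v.lesion_slice})")
v = select_slices(v, cfg)
print("after slice selection:", v.voxels.shape)
v = resample_inplane(v, cfg)
print("after resampling:     ", v.voxels.shape)
v = center_crop(v, cfg)
print("after centre crop:    ", v.voxels.shape)

pre = [preprocess_volume(x, cfg) for x in volumes]
labels = [x.label for x in pre]
print(f"\ntraining composition: {labels.count(0)} LG / {labels.count(1)} HG")
balanced = balance_by_augmentation(pre, cfg)
out = [x.label for x in balanced]
print(f"after balancing:      {out.count(0)} LG / {out.count(1)} HG "
      f"({len(balanced) - len(pre)} augmented volumes added)")

(groups, mean) = mean_normalize(balanced)
print(f"training grand mean subtracted: {mean:.4f}")
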