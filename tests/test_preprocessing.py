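"""Preprocessing chain: slice selection, resampling, cropping, balancing,
normalization."""

import numpy as np
import pytest

from vitstack import (ImbalanceError, LesionVolume, PreprocessConfig,
                      balance_by_augmentation, center_crop, mean_normalize,
                      preprocess_volume, resample_inplane, select_slices)
from conftest import make_volume


def indexed_volume(n_slices=20, size=8, lesion_slice=10):
    """Volume whose every voxel equals its slice index, for tracing selection."""
    vox = np.tile(np.arange(n_slices, dtype=np.float64)[None, None, :, None],
                  (size, size, 1, 1))
    return LesionVolume(voxels=vox, lesion_slice=lesion_slice, label=0,
                        zone="PZ", patient_id="P0")


class TestSelectSlices:
    @pytest.mark.parametrize("lesion_slice,expected", [
        (10, [8, 9, 10, 11, 12]),
        (0, [0, 0, 0, 1, 2]),
        (1, [0, 0, 1, 2, 3]),
        (19, [17, 18, 19, 19, 19]),
    ])
    def test_window_with_edge_replication(self, lesion_slice, expected):
        out = select_slices(indexed_volume(lesion_slice=lesion_slice))
        assert out.voxels.shape[2] == 5
        assert out.voxels[0, 0, :, 0].tolist() == expected
        assert out.lesion_slice == 2  # lesion recentred in the window

    def test_window_width_follows_config(self):
        cfg = PreprocessConfig(slices_each_side=1)
        assert select_slices(indexed_volume(), cfg).voxels.shape[2] == 3


def bilinear_oracle(img, out_size):
    """Brute-force bilinear interpolation, corners aligned to corners."""
    n = img.shape[0]
    out = np.zeros((out_size, out_size))
    for i in range(out_size):
        for j in range(out_size):
            y = i * (n - 1) / (out_size - 1)
            x = j * (n - 1) / (out_size - 1)
            y0, x0 = int(np.floor(y)), int(np.floor(x))
            y1, x1 = min(y0 + 1, n - 1), min(x0 + 1, n - 1)
            dy, dx = y - y0, x - x0
            out[i, j] = (img[y0, x0] * (1 - dy) * (1 - dx)
                         + img[y0, x1] * (1 - dy) * dx
                         + img[y1, x0] * dy * (1 - dx)
                         + img[y1, x1] * dy * dx)
    return out


class TestResample:
    def test_reference_size_input_returned_unchanged(self):
        v = make_volume(size=16)
        out = resample_inplane(v, PreprocessConfig(reference_size=16,
                                                   crop_size=16))
        assert out is v

    def test_constant_slice_stays_constant(self):
        vox = np.full((10, 10, 5, 1), 3.25)
        v = LesionVolume(vox, 2, 0, "PZ", "P0")
        out = resample_inplane(v, PreprocessConfig(reference_size=16, crop_size=16))
        assert np.allclose(out.voxels, 3.25)

    def test_matches_bilinear_oracle(self):
        rng = np.random.default_rng(0)
        img = rng.uniform(size=(2, 2))
        vox = np.tile(img[:, :, None, None], (1, 1, 5, 1))
        v = LesionVolume(vox, 2, 0, "PZ", "P0")
        out = resample_inplane(v, PreprocessConfig(reference_size=4, crop_size=4))
        assert np.allclose(out.voxels[:, :, 0, 0], bilinear_oracle(img, 4),
                           atol=1e-12)
        # and on a larger random slice
        img = rng.uniform(size=(5, 5))
        vox = np.tile(img[:, :, None, None], (1, 1, 5, 1))
        out = resample_inplane(LesionVolume(vox, 2, 0, "PZ", "P0"),
                               PreprocessConfig(reference_size=9, crop_size=9))
        assert np.allclose(out.voxels[:, :, 0, 0], bilinear_oracle(img, 9),
                           atol=1e-12)

    def test_values_bounded_by_input_range(self):
        v = make_volume(size=11, seed=3)
        out = resample_inplane(v, PreprocessConfig(reference_size=17, crop_size=17))
        assert out.voxels.min() >= v.voxels.min() - 1e-12
        assert out.voxels.max() <= v.voxels.max() + 1e-12

    def test_rejects_non_square(self):
        vox = np.zeros((8, 10, 5, 1))
        v = LesionVolume(vox, 2, 0, "PZ", "P0")
        with pytest.raises(ValueError, match="square"):
            resample_inplane(v, PreprocessConfig(reference_size=16, crop_size=16))


class TestCenterCrop:
    def test_384_to_128_window(self):
        vox = np.zeros((384, 384, 1, 1))
        vox[128:256, 128:256, 0, 0] = 1.0
        v = LesionVolume(vox, 0, 0, "PZ", "P0")
        out = center_crop(v, PreprocessConfig(crop_size=128))
        assert out.voxels.shape[:2] == (128, 128)
        assert np.all(out.voxels == 1.0)

    def test_identity_when_crop_equals_size(self):
        v = make_volume(size=16)
        out = center_crop(v, PreprocessConfig(reference_size=16, crop_size=16))
        assert np.array_equal(out.voxels, v.voxels)

    def test_center_pixel_survives_at_center(self):
        vox = np.zeros((17, 17, 1, 1))
        vox[8, 8, 0, 0] = 7.0
        v = LesionVolume(vox, 0, 0, "PZ", "P0")
        out = center_crop(v, PreprocessConfig(reference_size=17, crop_size=5))
        assert out.voxels[2, 2, 0, 0] == 7.0

    def test_rejects_oversized_crop(self):
        with pytest.raises(ValueError):
            center_crop(make_volume(size=8),
                        PreprocessConfig(reference_size=16, crop_size=16))


def tiny_training_set(n_major, n_minor, minority_label=1, size=8):
    vols = []
    for i in range(n_major):
        vols.append(make_volume(label=1 - minority_label, size=size, seed=i,
                                patient=f"A{i}", lesion_id=f"A{i}"))
    for i in range(n_minor):
        vols.append(make_volume(label=minority_label, size=size, seed=100 + i,
                                patient=f"B{i}", lesion_id=f"B{i}", zone="AS"))
    return vols


class TestBalancing:
    def test_54_27_yields_9_selected_and_balanced_54_each(self):
        out = balance_by_augmentation(tiny_training_set(54, 27))
        labels = [v.label for v in out]
        assert len(out) == 54 + 27 + 27  # 9 volumes x 3 copies added
        assert labels.count(0) == 54 and labels.count(1) == 54
        added = out[81:]
        assert len({v.lesion_id.rsplit("_", 1)[0] for v in added}) == 9
        assert {v.lesion_id.rsplit("_", 1)[1] for v in added} == \
               {"vflip", "hflip", "rot"}

    def test_balanced_input_unchanged(self):
        vols = tiny_training_set(5, 5)
        out = balance_by_augmentation(vols)
        assert [id(v) for v in out] == [id(v) for v in vols]

    def test_10_4_selects_2(self):
        out = balance_by_augmentation(tiny_training_set(10, 4))
        labels = [v.label for v in out]
        assert labels.count(0) == 10 and labels.count(1) == 10

    def test_non_divisible_gap_signalled(self):
        with pytest.raises(ImbalanceError):
            balance_by_augmentation(tiny_training_set(10, 3))

    def test_non_strict_leaves_remainder_unaugmented(self):
        out = balance_by_augmentation(tiny_training_set(10, 3), strict=False)
        labels = [v.label for v in out]
        assert labels.count(0) == 10 and labels.count(1) == 9

    def test_metadata_preserved_and_seed_reproducible(self):
        a = balance_by_augmentation(tiny_training_set(10, 4))
        b = balance_by_augmentation(tiny_training_set(10, 4))
        for va, vb in zip(a[14:], b[14:]):
            assert np.array_equal(va.voxels, vb.voxels)
            assert va.label == 1 and va.zone == "AS"
            assert va.patient_id.startswith("B")

    def test_flips_are_exact_axis_reversals(self):
        vols = tiny_training_set(4, 1)
        out = balance_by_augmentation(vols)
        source = vols[4]
        by_kind = {v.lesion_id.rsplit("_", 1)[1]: v for v in out[5:]}
        assert np.array_equal(by_kind["vflip"].voxels, source.voxels[::-1])
        assert np.array_equal(by_kind["hflip"].voxels, source.voxels[:, ::-1])

    def test_rotation_uses_one_angle_for_all_slices(self):
        # recover the applied angle independently per slice from a smooth
        # off-centre bump; every slice must report the same angle
        from scipy import ndimage
        vols = tiny_training_set(4, 0, size=24)
        ii, jj = np.mgrid[0:24, 0:24].astype(float)
        smooth = np.stack([np.exp(-((ii - 8) ** 2 + (jj - 16) ** 2) / 30.0)
                           * (1.0 + 0.2 * z) for z in range(5)], axis=2)
        src = make_volume(label=1, size=24, seed=50, patient="B0",
                          lesion_id="B0", zone="AS").replace(
            voxels=smooth[:, :, :, None])
        vols.append(src)
        out = balance_by_augmentation(vols, strict=False)
        rot = next(v for v in out[5:] if v.lesion_id.endswith("_rot"))

        def best_angle(z):
            errs = {}
            for angle in np.arange(-25.0, 25.01, 1.0):
                ref = ndimage.rotate(src.voxels[:, :, z, 0], angle,
                                     reshape=False, order=1, mode="nearest")
                errs[angle] = float(np.abs(ref - rot.voxels[:, :, z, 0]).sum())
            return min(errs, key=errs.get)

        angles = {best_angle(z) for z in range(5)}
        assert len(angles) == 1


class TestMeanNormalize:
    def test_constant_train_maps_to_zero(self):
        vols = [make_volume(seed=i) for i in range(3)]
        vols = [v.replace(voxels=np.full_like(v.voxels, 7.0)) for v in vols]
        (groups, mean) = mean_normalize(vols)
        assert mean == pytest.approx(7.0)
        assert all(np.allclose(v.voxels, 0.0) for v in groups[0])

    def test_training_grand_mean_becomes_zero(self):
        vols = [make_volume(seed=i) for i in range(4)]
        (groups, mean) = mean_normalize(vols)
        total = sum(float(v.voxels.sum()) for v in groups[0])
        count = sum(v.voxels.size for v in groups[0])
        assert abs(total / count) < 1e-6

    def test_other_sets_shifted_by_train_mean(self):
        train = [make_volume(seed=0).replace(
            voxels=np.full((8, 8, 5, 1), 7.0, dtype=np.float32))]
        val = [make_volume(seed=1).replace(
            voxels=np.full((8, 8, 5, 1), 9.0, dtype=np.float32))]
        (groups, mean) = mean_normalize(train, val)
        assert np.allclose(groups[1][0].voxels, 2.0)

    def test_empty_train_rejected(self):
        with pytest.raises(ValueError):
            mean_normalize([])


class TestPipelineShape:
    def test_output_shape_contract(self, small_cohort):
        vols, _ = small_cohort
        cfg = PreprocessConfig()
        for v in vols[:3]:
            out = preprocess_volume(v, cfg)
            assert out.voxels.shape == (128, 128, 5, 1)
        small = preprocess_volume(vols[0], PreprocessConfig(crop_size=32))
        assert small.voxels.shape == (32, 32, 5, 1)
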