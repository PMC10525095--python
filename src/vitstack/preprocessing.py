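"""Lesion-centred preprocessing chain.

The pipeline turns a raw acquisition into the fixed-shape tensor the
transformer consumes: pick the lesion slice plus two slices on either side,
bilinearly resample every slice to a common reference matrix, centre-crop to
the gland region, balance the training classes by augmenting a seeded subset
of minority volumes, and subtract the training-set grand-mean intensity from
every set.  Under the defaults the output is a 128 x 128 x 5 x 1 volume.
"""

from __future__ import annotations

import dataclasses
import logging
import os
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import yaml
from scipy import ndimage

from .synthetic import LesionVolume

__all__ = [
    "PreprocessConfig",
    "ImbalanceError",
    "select_slices",
    "resample_inplane",
    "center_crop",
    "balance_by_augmentation",
    "mean_normalize",
    "preprocess_volume",
    "preprocess_cohort",
]

log = logging.getLogger(__name__)


class ImbalanceError(ValueError):
    """Raised when the class imbalance cannot be closed by whole augmentation rounds."""


@dataclass(frozen=True)
class PreprocessConfig:
    reference_size: int = 384
    crop_size: int = 128
    slices_each_side: int = 2
    rotation_range: float = 25.0  # degrees, symmetric about 0
    augment_copies_per_volume: int = 3
    seed: int = 42

    def __post_init__(self) -> None:
        if self.crop_size > self.reference_size:
            raise ValueError("crop_size must be <= reference_size")
        if self.slices_each_side < 0:
            raise ValueError("slices_each_side must be >= 0")
        if self.rotation_range < 0:
            raise ValueError("rotation_range must be >= 0")
        if self.augment_copies_per_volume < 1:
            raise ValueError("augment_copies_per_volume must be >= 1")

    @classmethod
    def from_yaml(cls, path: str | os.PathLike) -> "PreprocessConfig":
        with open(path) as fh:
            return cls(**(yaml.safe_load(fh) or {}))


def select_slices(volume: LesionVolume,
                  cfg: PreprocessConfig = PreprocessConfig()) -> LesionVolume:
    """Keep the lesion slice and ``slices_each_side`` slices above and below it.

    Indices outside the acquisition are clamped to the nearest valid slice
    (edge replication), so the output depth is always
    ``2 * slices_each_side + 1`` and the lesion slice sits at its centre.
    """
    if volume.n_slices < 1:
        raise ValueError("volume has no slices")
    s = cfg.slices_each_side
    idx = np.clip(np.arange(volume.lesion_slice - s, volume.lesion_slice + s + 1),
                  0, volume.n_slices - 1)
    return volume.replace(voxels=volume.voxels[:, :, idx, :], lesion_slice=s)


def _bilinear_resize_slice(sl: np.ndarray, out_size: int) -> np.ndarray:
    """Bilinear resize of one square slice; corner pixels map onto corners."""
    n = sl.shape[0]
    if n == out_size:
        return sl.copy()
    if out_size == 1:
        return sl[:1, :1].copy()
    coords = np.linspace(0.0, n - 1.0, out_size)
    grid = np.meshgrid(coords, coords, indexing="ij")
    return ndimage.map_coordinates(sl.astype(np.float64), grid, order=1,
                                   mode="nearest")


def resample_inplane(volume: LesionVolume,
                     cfg: PreprocessConfig = PreprocessConfig()) -> LesionVolume:
    """Bilinearly resample every slice to ``reference_size`` squared.

    The chain normally upsamples (the reference is the largest matrix in the
    cohort); downsampling still works but is logged as a warning since it
    discards resolution.
    """
    h, w = volume.voxels.shape[:2]
    if h != w:
        raise ValueError(f"in-plane slices must be square, got {h}x{w}")
    r = cfg.reference_size
    if h == r:
        return volume
    if h > r:
        log.warning("downsampling %dx%d slice to %dx%d", h, w, r, r)
    out = np.empty((r, r, volume.n_slices, 1), dtype=np.float64)
    for z in range(volume.n_slices):
        out[:, :, z, 0] = _bilinear_resize_slice(volume.voxels[:, :, z, 0], r)
    return volume.replace(voxels=out.astype(volume.voxels.dtype))


def center_crop(volume: LesionVolume,
                cfg: PreprocessConfig = PreprocessConfig()) -> LesionVolume:
    """Retain the central ``crop_size`` x ``crop_size`` window of each slice.

    The offset is ``(S - c) // 2`` (floor for odd differences).
    """
    h, w = volume.voxels.shape[:2]
    c = cfg.crop_size
    if c > min(h, w):
        raise ValueError(f"crop size {c} exceeds image size {h}x{w}")
    top = (h - c) // 2
    left = (w - c) // 2
    return volume.replace(voxels=volume.voxels[top:top + c, left:left + c, :, :])


def preprocess_volume(volume: LesionVolume,
                      cfg: PreprocessConfig = PreprocessConfig()) -> LesionVolume:
    """Slice selection, in-plane resampling and centre crop for one volume."""
    return center_crop(resample_inplane(select_slices(volume, cfg), cfg), cfg)


def _rotate_volume(vox: np.ndarray, angle: float) -> np.ndarray:
    """Rotate every slice of an (H, W, Z, 1) stack by the same angle (bilinear)."""
    out = np.empty_like(vox, dtype=np.float64)
    for z in range(vox.shape[2]):
        out[:, :, z, 0] = ndimage.rotate(vox[:, :, z, 0].astype(np.float64),
                                         angle, reshape=False, order=1,
                                         mode="nearest")
    return out.astype(vox.dtype)


def _augment_three(volume: LesionVolume, angle: float) -> list[LesionVolume]:
    """One vertical flip, one horizontal flip, one rotation by ``angle``."""
    vox = volume.voxels
    return [
        volume.replace(voxels=vox[::-1, :, :, :].copy(),
                       lesion_id=volume.lesion_id + "_vflip"),
        volume.replace(voxels=vox[:, ::-1, :, :].copy(),
                       lesion_id=volume.lesion_id + "_hflip"),
        volume.replace(voxels=_rotate_volume(vox, angle),
                       lesion_id=volume.lesion_id + "_rot"),
    ]


def balance_by_augmentation(training_volumes: Sequence[LesionVolume],
                            cfg: PreprocessConfig = PreprocessConfig(),
                            strict: bool = True) -> list[LesionVolume]:
    """Equalise class counts by augmenting a seeded minority subset.

    Selects ``(n_major - n_minor) / copies`` minority volumes without
    replacement with a fixed seed and emits ``copies`` augmented versions of
    each: a vertical flip, a horizontal flip, and a rotation by a seeded
    uniform angle in ``rotation_range`` applied identically to all slices
    with bilinear interpolation.  Labels, zones and patient ids are
    untouched.  Already-balanced input is returned unchanged.

    With ``strict`` (default), a gap not divisible by ``copies`` raises
    :class:`ImbalanceError`; with ``strict=False`` the remainder volumes are
    left unaugmented and a warning is logged (used after bootstrap
    resampling, where the gap is arbitrary).
    """
    volumes = list(training_volumes)
    by_class: dict[int, list[LesionVolume]] = {0: [], 1: []}
    for v in volumes:
        by_class[v.label].append(v)
    n0, n1 = len(by_class[0]), len(by_class[1])
    if n0 == n1:
        return volumes
    minority = 0 if n0 < n1 else 1
    gap = abs(n0 - n1)
    copies = cfg.augment_copies_per_volume
    if gap % copies != 0:
        if strict:
            raise ImbalanceError(
                f"class gap {gap} is not divisible by {copies} copies per volume")
        log.warning("class gap %d not divisible by %d; %d volume(s) of slack left",
                    gap, copies, gap % copies)
    k = gap // copies
    pool = by_class[minority]
    if k > len(pool):
        raise ImbalanceError(
            f"need {k} minority volumes to augment but only {len(pool)} available")
    rng = np.random.default_rng(cfg.seed)
    chosen = rng.choice(len(pool), size=k, replace=False)
    out = volumes.copy()
    for i in chosen:
        angle = float(rng.uniform(-cfg.rotation_range, cfg.rotation_range))
        out.extend(_augment_three(pool[int(i)], angle))
    return out


def mean_normalize(train_set: Sequence[LesionVolume],
                   *other_sets: Sequence[LesionVolume]
                   ) -> tuple[list[list[LesionVolume]], float]:
    """Subtract the training-set grand-mean voxel value from every set.

    A single scalar mean over all training voxels is computed and subtracted
    from every voxel of the training set and of each additional set, aligning
    their intensity distributions.  Returns ``([train, *others], mean)``.
    """
    train_set = list(train_set)
    if not train_set:
        raise ValueError("training set is empty")
    total = sum(float(v.voxels.sum()) for v in train_set)
    count = sum(v.voxels.size for v in train_set)
    mean = total / count
    normalized = []
    for group in (train_set, *[list(g) for g in other_sets]):
        normalized.append([v.replace(voxels=v.voxels - np.asarray(mean, dtype=v.voxels.dtype))
                           for v in group])
    return normalized, mean


def preprocess_cohort(train: Sequence[LesionVolume],
                      *other_sets: Sequence[LesionVolume],
                      cfg: PreprocessConfig = PreprocessConfig(),
                      balance: bool = True,
                      strict_balance: bool = True,
                      ) -> tuple[list[list[LesionVolume]], float]:
    """Full chain: per-volume preprocessing, training balancing, normalization."""
    groups = [[preprocess_volume(v, cfg) for v in g] for g in (train, *other_sets)]
    if balance:
        groups[0] = balance_by_augmentation(groups[0], cfg, strict=strict_balance)
    return mean_normalize(*groups)
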