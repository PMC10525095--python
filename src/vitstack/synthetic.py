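"""Seeded phantom cohorts for exercising the lesion-grading pipeline.

Each phantom emulates one axial T2-weighted acquisition around a biopsied
lesion: a bright ellipsoidal "gland" on a dark background, plus a textured
lesion blob on a known slice.  Lesion grade (low-grade LG=0 vs high-grade
HG=1) modulates both the mean contrast and the speckle variance of the blob,
so that first- and second-order texture statistics carry class signal — the
kind of signal lesion-grading models are assumed to pick up.  The separation
between the two grade distributions is controlled by a single dimensionless
``effect_size`` (in within-class standard-deviation units); at
``effect_size=0`` the two classes are identical in law.

Cohorts are fully determined by their seed: regenerating with the same
``CohortSpec`` yields bit-identical voxel arrays.
"""

from __future__ import annotations

import dataclasses
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

__all__ = [
    "CohortSpec",
    "LesionVolume",
    "generate_cohort",
    "write_cohort",
    "read_cohort",
]

ZONES = ("PZ", "AS", "TZ")
CLASSES = ("LG", "HG")

#: In-plane voxel spacing of the emulated acquisition (mm); informational.
DEFAULT_IN_PLANE_SPACING = 0.5
#: Slice thickness carried as metadata only (mm).
DEFAULT_SLICE_THICKNESS = 3.6


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of a phantom cohort.

    Defaults emulate the study cohort: 112 lesions from 99 patients,
    77 LG / 35 HG, 50 PZ / 47 AS / 15 TZ, with a mixture of 320- and
    384-pixel acquisition matrices (384 the mode) so in-plane resampling
    is exercised.
    """

    n_patients: int = 99
    n_lesions: int = 112
    class_fractions: tuple[float, float] = (77 / 112, 35 / 112)
    zone_fractions: tuple[float, float, float] = (50 / 112, 47 / 112, 15 / 112)
    matrix_sizes: tuple[int, ...] = (320, 384)
    matrix_weights: tuple[float, ...] = (0.4, 0.6)
    n_slices: int = 7
    effect_size: float = 2.5
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.class_fractions) - 1.0) > 1e-9:
            raise ValueError("class_fractions must sum to 1")
        if abs(sum(self.zone_fractions) - 1.0) > 1e-9:
            raise ValueError("zone_fractions must sum to 1")
        if self.n_lesions < self.n_patients:
            raise ValueError("n_lesions must be >= n_patients")
        if self.n_slices < 5:
            raise ValueError("n_slices must be >= 5 (lesion slice +/- 2)")
        for s in self.matrix_sizes:
            if s < 256:
                raise ValueError("matrix sizes must be >= 256 pixels")
        if len(self.matrix_weights) != len(self.matrix_sizes):
            raise ValueError("matrix_weights must match matrix_sizes")
        if self.effect_size < 0:
            raise ValueError("effect_size must be non-negative")

    @classmethod
    def from_yaml(cls, path: str | os.PathLike) -> "CohortSpec":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key in ("class_fractions", "zone_fractions", "matrix_sizes", "matrix_weights"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_yaml(self, path: str | os.PathLike) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump({k: list(v) if isinstance(v, tuple) else v
                            for k, v in dataclasses.asdict(self).items()}, fh)


@dataclass
class LesionVolume:
    """One lesion's image stack plus its study metadata.

    ``voxels`` has shape (H, W, Z, C) with C=1; values are finite and
    non-negative as generated.  ``lesion_slice`` is the 0-based index of the
    slice through the lesion centre.
    """

    voxels: np.ndarray
    lesion_slice: int
    label: int  # 0 = LG, 1 = HG
    zone: str
    patient_id: str
    lesion_id: str = ""
    in_plane_spacing: float = DEFAULT_IN_PLANE_SPACING
    #: (row, col) of the lesion centre in-plane, if known (phantoms record it,
    #: mirroring the lesion coordinates shipped with the study dataset).
    lesion_center: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        v = np.asarray(self.voxels)
        if v.ndim != 4 or v.shape[3] != 1:
            raise ValueError("voxels must have shape (H, W, Z, 1)")
        if not (0 <= self.lesion_slice < v.shape[2]):
            raise ValueError("lesion_slice out of range")
        if self.label not in (0, 1):
            raise ValueError("label must be 0 (LG) or 1 (HG)")
        if self.zone not in ZONES:
            raise ValueError(f"zone must be one of {ZONES}")

    @property
    def shape(self) -> tuple[int, int, int, int]:
        return self.voxels.shape

    @property
    def n_slices(self) -> int:
        return self.voxels.shape[2]

    def replace(self, **kw) -> "LesionVolume":
        return dataclasses.replace(self, **kw)


def _largest_remainder(fractions: Sequence[float], total: int) -> list[int]:
    """Apportion ``total`` integer counts to ``fractions`` (largest remainder)."""
    quotas = np.asarray(fractions, dtype=float) * total
    counts = np.floor(quotas).astype(int)
    short = total - counts.sum()
    order = np.argsort(-(quotas - counts))
    for i in order[:short]:
        counts[i] += 1
    return counts.tolist()


def _render_volume(rng: np.random.Generator, size: int, n_slices: int,
                   label: int, effect_size: float,
                   lesion_slice: int) -> np.ndarray:
    """Draw one phantom acquisition.

    Background noise, a smooth bright ellipsoidal gland centred in-plane,
    and a multiplicative textured lesion blob on ``lesion_slice``.  The blob's
    mean contrast is N(0.30, 0.10) for LG, shifted up by
    ``effect_size * 0.10`` for HG; its speckle SD also scales with grade.
    """
    yy, xx = np.mgrid[0:size, 0:size].astype(np.float64)
    cy = cx = (size - 1) / 2.0
    # gland semi-axes ~35-40% of the matrix, mild per-case variation
    ax = size * rng.uniform(0.30, 0.40)
    ay = size * rng.uniform(0.25, 0.35)
    zc = (n_slices - 1) / 2.0
    az = max(n_slices * 0.45, 1.5)

    vol = np.empty((size, size, n_slices), dtype=np.float64)
    base = rng.uniform(0.9, 1.1)  # per-case gland brightness
    for z in range(n_slices):
        r2 = ((xx - cx) / ax) ** 2 + ((yy - cy) / ay) ** 2 + ((z - zc) / az) ** 2
        gland = base * np.clip(1.0 - r2, 0.0, None)
        vol[:, :, z] = 0.15 + gland

    # lesion blob: gaussian footprint somewhere inside the gland
    contrast_sd = 0.10  # within-class SD; effect_size is in these units
    contrast = rng.normal(0.30 + label * effect_size * contrast_sd, contrast_sd)
    speckle_sd = 0.05 * (1.0 + 0.2 * effect_size * label)
    lx = cx + rng.uniform(-0.25, 0.25) * ax
    ly = cy + rng.uniform(-0.25, 0.25) * ay
    lr = size * rng.uniform(0.04, 0.07)  # blob radius ~ 1-2 cm at 0.5 mm
    foot = np.exp(-(((xx - lx) ** 2 + (yy - ly) ** 2) / (2 * lr * lr)))
    texture = rng.normal(0.0, speckle_sd, size=(size, size))
    sl = vol[:, :, lesion_slice]
    vol[:, :, lesion_slice] = sl * (1.0 + foot * (contrast + texture))

    vol += rng.normal(0.0, 0.02, size=vol.shape)  # acquisition noise
    np.clip(vol, 0.0, None, out=vol)
    return vol[:, :, :, None].astype(np.float32), (float(ly), float(lx), float(lr))


def generate_cohort(spec: CohortSpec) -> tuple[list[LesionVolume], pd.DataFrame]:
    """Generate a seeded phantom cohort and its manifest.

    Returns exactly ``spec.n_lesions`` volumes whose class and zone counts
    equal the largest-remainder rounding of the spec fractions.  Surplus
    lesions beyond one per patient are assigned to randomly chosen patients
    so patient-wise splitting is non-trivial.  Identical specs (including
    seed) produce bit-identical voxel arrays.
    """
    rng = np.random.default_rng(spec.seed)

    n_lg, n_hg = _largest_remainder(spec.class_fractions, spec.n_lesions)
    zone_counts = _largest_remainder(spec.zone_fractions, spec.n_lesions)

    labels = np.array([0] * n_lg + [1] * n_hg)
    zones = np.concatenate([np.full(c, z) for z, c in zip(ZONES, zone_counts)])
    rng.shuffle(labels)
    rng.shuffle(zones)

    # one lesion per patient, then surplus lesions to random patients
    patient_of = list(range(spec.n_patients))
    surplus = rng.choice(spec.n_patients, size=spec.n_lesions - spec.n_patients,
                         replace=True)
    patient_of.extend(int(p) for p in surplus)
    rng.shuffle(patient_of)

    sizes = rng.choice(np.asarray(spec.matrix_sizes),
                       p=np.asarray(spec.matrix_weights, dtype=float)
                       / np.sum(spec.matrix_weights),
                       size=spec.n_lesions)

    volumes: list[LesionVolume] = []
    for i in range(spec.n_lesions):
        # lesions sit inside the gland, away from the acquisition edges
        lesion_slice = int(rng.integers(2, spec.n_slices - 2))
        vox, center = _render_volume(rng, int(sizes[i]), spec.n_slices,
                                     int(labels[i]), spec.effect_size,
                                     lesion_slice)
        volumes.append(LesionVolume(
            voxels=vox,
            lesion_slice=lesion_slice,
            label=int(labels[i]),
            zone=str(zones[i]),
            patient_id=f"P{patient_of[i]:04d}",
            lesion_id=f"L{i:04d}",
            lesion_center=center[:2],
        ))
    return volumes, cohort_manifest(volumes)


def cohort_manifest(volumes: Sequence[LesionVolume]) -> pd.DataFrame:
    return pd.DataFrame({
        "patient_id": [v.patient_id for v in volumes],
        "file": [f"{v.lesion_id or f'L{i:04d}'}.nii" for i, v in enumerate(volumes)],
        "lesion_slice": [v.lesion_slice for v in volumes],
        "label": [v.label for v in volumes],
        "zone": [v.zone for v in volumes],
    })


def write_cohort(volumes: Sequence[LesionVolume], directory: str | os.PathLike,
                 force: bool = False) -> Path:
    """Write one NIfTI per volume plus a CSV manifest; returns the manifest path.

    Refuses to overwrite an existing manifest unless ``force``.  Voxel data
    are stored as float32 so a round-trip read reproduces them exactly.
    """
    if not volumes:
        raise ValueError("cohort is empty")
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest_path = directory / "manifest.csv"
    if manifest_path.exists() and not force:
        raise FileExistsError(f"{manifest_path} exists; pass force=True to overwrite")

    rows = []
    for i, v in enumerate(volumes):
        fname = f"{v.lesion_id or f'L{i:04d}'}.nii"
        affine = np.diag([v.in_plane_spacing, v.in_plane_spacing,
                          DEFAULT_SLICE_THICKNESS, 1.0])
        img = nib.Nifti1Image(np.asarray(v.voxels, dtype=np.float32), affine)
        nib.save(img, directory / fname)
        rows.append((v.patient_id, fname, v.lesion_slice, v.label, v.zone))
    pd.DataFrame(rows, columns=["patient_id", "file", "lesion_slice",
                                "label", "zone"]).to_csv(manifest_path, index=False)
    return manifest_path


def lesion_contrast_statistic(volume: LesionVolume, roi_fraction: float = 0.04
                              ) -> float:
    """First-order lesion texture statistic: ROI intensity contrast.

    Mean intensity in a small square region of interest around the lesion
    centre on the lesion slice, divided by the mean of the same in-plane
    region on the two neighbouring slices.  The ratio cancels per-case
    brightness and gland-shape nuisance, isolating the grade-dependent
    lesion contrast; it is the simple statistic the separability sanity
    checks classify on.  Requires ``lesion_center`` metadata.
    """
    if volume.lesion_center is None:
        raise ValueError("volume has no lesion_center metadata")
    h, w = volume.voxels.shape[:2]
    r = max(2, int(round(min(h, w) * roi_fraction)))
    cy, cx = (int(round(c)) for c in volume.lesion_center)
    sl = slice(max(cy - r, 0), min(cy + r + 1, h))
    sc = slice(max(cx - r, 0), min(cx + r + 1, w))
    z = volume.lesion_slice
    neighbours = [zz for zz in (z - 1, z + 1) if 0 <= zz < volume.n_slices]
    lesion = float(volume.voxels[sl, sc, z, 0].mean())
    ref = float(np.mean([volume.voxels[sl, sc, zz, 0].mean()
                         for zz in neighbours]))
    return lesion / max(ref, 1e-9)


def read_cohort(manifest_path: str | os.PathLike) -> list[LesionVolume]:
    """Load a cohort written by :func:`write_cohort`."""
    manifest_path = Path(manifest_path)
    df = pd.read_csv(manifest_path)
    volumes = []
    for _, row in df.iterrows():
        img = nib.load(manifest_path.parent / row["file"])
        vox = np.asarray(img.dataobj, dtype=np.float32)
        volumes.append(LesionVolume(
            voxels=vox,
            lesion_slice=int(row["lesion_slice"]),
            label=int(row["label"]),
            zone=str(row["zone"]),
            patient_id=str(row["patient_id"]),
            lesion_id=Path(str(row["file"])).stem,
            in_plane_spacing=float(abs(img.affine[0, 0])),
        ))
    return volumes
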