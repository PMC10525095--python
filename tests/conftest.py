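import numpy as np
import pandas as pd
import pytest

from vitstack import CohortSpec, LesionVolume, generate_cohort


def make_volume(label=0, size=8, n_slices=5, lesion_slice=2, zone="PZ",
                patient="P0", seed=0, lesion_id="L0"):
    """A tiny in-memory lesion volume for unit tests."""
    rng = np.random.default_rng(seed)
    vox = rng.uniform(0.0, 1.0, size=(size, size, n_slices, 1)).astype(np.float32)
    return LesionVolume(voxels=vox, lesion_slice=lesion_slice, label=label,
                        zone=zone, patient_id=patient, lesion_id=lesion_id)


def make_manifest(n=112, n_patients=99, n_lg=77, zone_counts=(50, 47, 15),
                  seed=0):
    """A cohort manifest with the study composition, no voxel rendering."""
    rng = np.random.default_rng(seed)
    labels = np.array([0] * n_lg + [1] * (n - n_lg))
    zones = np.concatenate([np.full(c, z) for z, c in
                            zip(("PZ", "AS", "TZ"), zone_counts)])
    rng.shuffle(labels)
    rng.shuffle(zones)
    patients = list(range(n_patients)) + list(rng.choice(n_patients,
                                                         n - n_patients))
    rng.shuffle(patients)
    return pd.DataFrame({"patient_id": [f"P{p:04d}" for p in patients],
                         "label": labels, "zone": zones})


@pytest.fixture(scope="session")
def small_cohort():
    """20 rendered lesions, balanced enough for split/metric tests."""
    spec = CohortSpec(n_patients=18, n_lesions=20, n_slices=7,
                      class_fractions=(0.6, 0.4),
                      zone_fractions=(0.5, 0.3, 0.2), seed=11)
    return generate_cohort(spec)


@pytest.fixture(scope="session")
def separable_eight():
    """Eight strongly separated phantoms (4 LG / 4 HG) for overfit smoke tests."""
    spec = CohortSpec(n_patients=8, n_lesions=8, class_fractions=(0.5, 0.5),
                      effect_size=6.0, seed=7)
    return generate_cohort(spec)[0]
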