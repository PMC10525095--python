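"""Stacking ensembles of base 3D vision transformers.

A stacking ensemble concatenates the outputs of m already-trained (and
frozen) base models into a feature vector x and feeds it to a linear
meta-classifier y = x A^T + b whose sigmoid output is the ensemble's
positive-class probability.  The meta-classifier is the only part trained
at this stage; it learns how much to trust each base model.  All unordered
combinations of the 18 canonical bases with m = 2 or 3 give the 153 + 816
candidate ensembles of the canonical study.

What "output of a base model" means is ambiguous between the base's scalar
pre-sigmoid logit, its post-sigmoid probability, and its classification-token
embedding; all three are supported via ``feature_mode``, with the scalar
logit — the minimal reading — as the default.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from . import nn

__all__ = [
    "MetaClassifier", "EnsembleTrainSpec", "EnsembleSpec",
    "enumerate_combinations", "meta_forward", "classify",
    "extract_features", "train_ensemble", "predict_proba_ensemble",
]

FEATURE_MODES = ("logit", "probability", "embedding")


def enumerate_combinations(n_base: int, sizes: Sequence[int] = (2, 3)
                           ) -> list[tuple[int, ...]]:
    """All unordered distinct member tuples (1-based ids), lexicographic.

    ``enumerate_combinations(18, {2})`` has C(18, 2) = 153 entries and
    ``enumerate_combinations(18, {3})`` has C(18, 3) = 816.
    """
    sizes = sorted(set(int(s) for s in sizes))
    if not sizes or sizes[0] < 1:
        raise ValueError("combination sizes must be positive")
    if sizes[-1] > n_base:
        raise ValueError(f"cannot draw {sizes[-1]} models from {n_base}")
    out: list[tuple[int, ...]] = []
    for m in sizes:
        out.extend(itertools.combinations(range(1, n_base + 1), m))
    return out


@dataclass(frozen=True)
class EnsembleTrainSpec:
    """Meta-classifier training hyperparameters."""

    learning_rate: float = 1e-4
    weight_decay: float = 1e-2
    epochs: int = 100
    batch_size: int = 4
    seed: int = 42


@dataclass(frozen=True)
class EnsembleSpec:
    member_config_ids: tuple[int, ...]
    feature_mode: str = "logit"
    train_spec: EnsembleTrainSpec = field(default_factory=EnsembleTrainSpec)

    def __post_init__(self) -> None:
        ids = self.member_config_ids
        if len(set(ids)) != len(ids):
            raise ValueError("member config ids must be distinct")
        if tuple(sorted(ids)) != tuple(ids):
            raise ValueError("member config ids must be sorted ascending")
        if self.feature_mode not in FEATURE_MODES:
            raise ValueError(f"feature_mode must be one of {FEATURE_MODES}")


@dataclass
class MetaClassifier:
    """Linear map y = x A^T + b over the concatenated base features."""

    A: np.ndarray  # shape (1, n_features)
    b: float
    m: int
    feature_mode: str = "logit"
    member_config_ids: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        self.A = np.atleast_2d(np.asarray(self.A, dtype=np.float64))
        if self.A.shape[0] != 1:
            raise ValueError("meta-classifier has exactly one output row")


def meta_forward(meta: MetaClassifier, features: np.ndarray) -> np.ndarray:
    """Sigmoid of the meta-classifier's linear output.

    ``features`` is one vector of length ``n_features`` or a batch
    ``(B, n_features)``; returns a scalar or length-B array of
    probabilities.
    """
    x = np.asarray(features, dtype=np.float64)
    single = x.ndim == 1
    x = np.atleast_2d(x)
    if x.shape[1] != meta.A.shape[1]:
        raise ValueError(f"expected {meta.A.shape[1]} features, got {x.shape[1]}")
    p = nn.sigmoid(x @ meta.A.T + meta.b)[:, 0]
    return float(p[0]) if single else p


def classify(probability, threshold: float = 0.5):
    """Predicted label: 1 iff the probability strictly exceeds the threshold.

    A probability of exactly 0.5 is classified negative.
    """
    p = np.asarray(probability, dtype=np.float64)
    if np.any(p < 0) or np.any(p > 1):
        raise ValueError("probabilities must lie in [0, 1]")
    out = (p > threshold).astype(int)
    return int(out) if out.ndim == 0 else out


def extract_features(base_models: Sequence, volumes: Sequence,
                     feature_mode: str = "logit") -> np.ndarray:
    """Concatenated frozen-base features, one row per volume.

    ``logit`` / ``probability`` contribute one column per base;
    ``embedding`` contributes each base's classification-token state.
    Base models need only expose ``logits(volumes)`` (and ``embeddings``
    for the embedding mode), so lightweight stand-ins are usable in tests.
    """
    if feature_mode not in FEATURE_MODES:
        raise ValueError(f"feature_mode must be one of {FEATURE_MODES}")
    cols = []
    for base in base_models:
        if feature_mode == "embedding":
            cols.append(np.asarray(base.embeddings(volumes), dtype=np.float64))
        else:
            z = np.asarray(base.logits(volumes), dtype=np.float64)[:, None]
            cols.append(nn.sigmoid(z) if feature_mode == "probability" else z)
    return np.concatenate(cols, axis=1)


def train_ensemble(base_models: Mapping[int, object], spec: EnsembleSpec,
                   train_set: Sequence, val_set: Sequence = ()
                   ) -> MetaClassifier:
    """Train the linear meta-classifier on frozen base-model features.

    Base models are only queried for features; their parameters are never
    touched.  Training runs ``epochs`` seeded-shuffled passes of Adam +
    binary cross-entropy over the concatenated features.
    """
    missing = [i for i in spec.member_config_ids if i not in base_models]
    if missing:
        raise KeyError(f"member config ids {missing} have no trained base model")
    members = [base_models[i] for i in spec.member_config_ids]
    X = extract_features(members, list(train_set), spec.feature_mode)
    y = np.array([v.label for v in train_set], dtype=np.float64)

    ts = spec.train_spec
    rng = np.random.default_rng(ts.seed)
    w = nn.Parameter(np.zeros((X.shape[1], 1)))
    b = nn.Parameter(np.zeros(1))
    opt = nn.Adam([w, b], lr=ts.learning_rate, weight_decay=ts.weight_decay)
    n = len(y)
    for _ in range(ts.epochs):
        order = rng.permutation(n)
        for start in range(0, n, ts.batch_size):
            idx = order[start:start + ts.batch_size]
            logits = X[idx] @ w.value[:, 0] + b.value[0]
            _, g = nn.bce_with_logits(logits, y[idx])
            w.grad[...] = (X[idx] * g[:, None]).sum(axis=0)[:, None]
            b.grad[...] = g.sum()
            opt.step()
    return MetaClassifier(A=w.value.T, b=float(b.value[0]), m=len(members),
                          feature_mode=spec.feature_mode,
                          member_config_ids=tuple(spec.member_config_ids))


def predict_proba_ensemble(meta: MetaClassifier,
                           base_models: Mapping[int, object],
                           volumes: Sequence) -> np.ndarray:
    """Ensemble positive-class probabilities for a list of volumes."""
    members = [base_models[i] for i in meta.member_config_ids]
    X = extract_features(members, list(volumes), meta.feature_mode)
    return meta_forward(meta, X)
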