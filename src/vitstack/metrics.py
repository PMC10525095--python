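"""Accuracy, confidence and calibration metrics for binary lesion grading.

Beyond the usual discrimination metrics (specificity, sensitivity, balanced
accuracy, AUROC, AUPRC), two hybrid confidence metrics tie correctness to
the probability with which it was achieved:

* confident specificity (CSP): the fraction of actual negatives that are
  both correctly classified and predicted with probability <= 0.3;
* confident sensitivity (CSE): the fraction of actual positives that are
  both correctly classified and predicted with probability >= 0.7.

CSP can never exceed specificity, nor CSE sensitivity; equality means every
correct prediction was made confidently.  Calibration is summarised by the
Brier score BS = mean (f_i - o_i)^2 and its class-conditional restrictions
BSNC (negatives; mean f^2) and BSPC (positives; mean (f-1)^2), each averaged
over its own record count, so N*BS = n0*BSNC + n1*BSPC exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Sequence

import numpy as np
from sklearn.metrics import average_precision_score, roc_auc_score

__all__ = [
    "PredictionRecord", "ConfusionCounts", "MetricsReport", "UndefinedMetricError",
    "confusion", "specificity", "sensitivity", "balanced_accuracy",
    "csp", "cse", "brier", "brier_negative", "brier_positive",
    "auroc", "auprc", "compute_report",
]

#: Inclusive confidence-band boundaries for CSP / CSE.
CONFIDENT_LOW = 0.3
CONFIDENT_HIGH = 0.7


class UndefinedMetricError(ValueError):
    """A metric's defining class subset is empty for this input."""


@dataclass(frozen=True)
class PredictionRecord:
    """One case: predicted positive-class probability f and true label o."""

    f: float
    o: int

    def __post_init__(self) -> None:
        if not (np.isfinite(self.f) and 0.0 <= self.f <= 1.0):
            raise ValueError("probability f must be finite in [0, 1]")
        if self.o not in (0, 1):
            raise ValueError("label o must be 0 or 1")


def _split(records: Sequence[PredictionRecord]) -> tuple[np.ndarray, np.ndarray]:
    if not len(records):
        raise ValueError("no prediction records")
    f = np.array([r.f for r in records], dtype=np.float64)
    o = np.array([r.o for r in records], dtype=np.int64)
    return f, o


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    TN: int
    FP: int
    FN: int

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN


def confusion(records: Sequence[PredictionRecord],
              threshold: float = 0.5) -> ConfusionCounts:
    """Strict-threshold classification (positive iff f > threshold), tabulated."""
    f, o = _split(records)
    pred = f > threshold
    return ConfusionCounts(
        TP=int(np.sum(pred & (o == 1))),
        TN=int(np.sum(~pred & (o == 0))),
        FP=int(np.sum(pred & (o == 0))),
        FN=int(np.sum(~pred & (o == 1))),
    )


def _require(cond: bool, what: str) -> None:
    if not cond:
        raise UndefinedMetricError(what)


def specificity(records, threshold: float = 0.5) -> float:
    c = confusion(records, threshold)
    _require(c.TN + c.FP > 0, "specificity needs at least one negative record")
    return c.TN / (c.TN + c.FP)


def sensitivity(records, threshold: float = 0.5) -> float:
    c = confusion(records, threshold)
    _require(c.TP + c.FN > 0, "sensitivity needs at least one positive record")
    return c.TP / (c.TP + c.FN)


def balanced_accuracy(records, threshold: float = 0.5) -> float:
    return 0.5 * (specificity(records, threshold) + sensitivity(records, threshold))


def csp(records, low: float = CONFIDENT_LOW, threshold: float = 0.5) -> float:
    """Confident specificity: true negatives predicted with f <= ``low``,
    over all actual negatives."""
    f, o = _split(records)
    neg = o == 0
    _require(neg.any(), "CSP needs at least one negative record")
    confident_tn = np.sum(neg & (f <= threshold) & (f <= low))
    return float(confident_tn / neg.sum())


def cse(records, high: float = CONFIDENT_HIGH, threshold: float = 0.5) -> float:
    """Confident sensitivity: true positives predicted with f >= ``high``,
    over all actual positives."""
    f, o = _split(records)
    pos = o == 1
    _require(pos.any(), "CSE needs at least one positive record")
    confident_tp = np.sum(pos & (f > threshold) & (f >= high))
    return float(confident_tp / pos.sum())


def brier(records) -> float:
    f, o = _split(records)
    return float(np.mean((f - o) ** 2))


def brier_negative(records) -> float:
    """Brier score over actual negatives only (mean f^2)."""
    f, o = _split(records)
    _require((o == 0).any(), "BSNC needs at least one negative record")
    return float(np.mean(f[o == 0] ** 2))


def brier_positive(records) -> float:
    """Brier score over actual positives only (mean (f-1)^2)."""
    f, o = _split(records)
    _require((o == 1).any(), "BSPC needs at least one positive record")
    return float(np.mean((f[o == 1] - 1.0) ** 2))


def auroc(records) -> float:
    """Probability a random positive outscores a random negative (ties half)."""
    f, o = _split(records)
    _require(len(np.unique(o)) == 2, "AUROC needs both classes present")
    return float(roc_auc_score(o, f))


def auprc(records) -> float:
    """Area under the precision-recall curve by the average-precision
    convention (no optimistic interpolation; the constant-score baseline
    equals the positive prevalence)."""
    f, o = _split(records)
    _require(len(np.unique(o)) == 2, "AUPRC needs both classes present")
    return float(average_precision_score(o, f))


@dataclass(frozen=True)
class MetricsReport:
    """The ten evaluation quantities for one set of predictions."""

    specificity: float
    sensitivity: float
    balanced_accuracy: float
    auroc: float
    auprc: float
    csp: float
    cse: float
    bs: float
    bsnc: float
    bspc: float

    def as_dict(self) -> dict[str, float]:
        return asdict(self)

    METRIC_NAMES = ("specificity", "sensitivity", "balanced_accuracy",
                    "auroc", "auprc", "csp", "cse", "bs", "bsnc", "bspc")


def compute_report(records: Sequence[PredictionRecord]) -> MetricsReport:
    """All ten metrics for one evaluation (both classes must be present)."""
    return MetricsReport(
        specificity=specificity(records),
        sensitivity=sensitivity(records),
        balanced_accuracy=balanced_accuracy(records),
        auroc=auroc(records),
        auprc=auprc(records),
        csp=csp(records),
        cse=cse(records),
        bs=brier(records),
        bsnc=brier_negative(records),
        bspc=brier_positive(records),
    )


def records_from_arrays(probabilities, labels) -> list[PredictionRecord]:
    """Build records from parallel probability / label arrays."""
    return [PredictionRecord(float(f), int(o))
            for f, o in zip(np.asarray(probabilities), np.asarray(labels),
                            strict=True)]
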