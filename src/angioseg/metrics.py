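"""Pixelwise confusion-matrix rates and overlap metrics.

Note on the false positive rate: the formula implemented as ``fpr`` is
FP/(FP+FN), reproduced verbatim from the method this package follows;
the conventional definition FP/(FP+TN) is exposed separately as
``fpr_conventional`` and both appear in reports.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass

import numpy as np

from .errors import ValidationError
from .image_io import BinaryMask

__all__ = [
    "ConfusionCounts",
    "Rates",
    "EvalReport",
    "confusion_counts",
    "rates",
    "dice",
    "voe",
    "rvd",
    "evaluate",
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValidationError("confusion counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass(frozen=True)
class Rates:
    sensitivity: float
    specificity: float
    precision: float
    fpr: float
    accuracy: float


@dataclass(frozen=True)
class EvalReport:
    """The eight evaluation metrics plus the raw counts.

    Rates are in [0, 1]; dice and voe are percentages in [0, 100]; rvd is
    a signed percentage (negative = undersegmentation).
    """

    tp: int
    tn: int
    fp: int
    fn: int
    sensitivity: float
    specificity: float
    precision: float
    fpr: float
    fpr_conventional: float
    accuracy: float
    dice: float
    voe: float
    rvd: float

    def as_dict(self) -> dict:
        return asdict(self)


def _mask_pair(pred, truth) -> tuple[np.ndarray, np.ndarray]:
    a = pred.data if isinstance(pred, BinaryMask) else np.asarray(pred, dtype=bool)
    b = truth.data if isinstance(truth, BinaryMask) else np.asarray(truth, dtype=bool)
    if a.shape != b.shape:
        raise ValidationError(f"shape mismatch: {a.shape} vs {b.shape}")
    return a, b


def _ratio(num: float, den: float) -> float:
    """num/den with an undefined-flag (NaN) instead of a crash at den=0."""
    return num / den if den else math.nan


def confusion_counts(pred, truth) -> ConfusionCounts:
    """Pixelwise tally with in-region = positive."""
    a, b = _mask_pair(pred, truth)
    return ConfusionCounts(
        tp=int(np.sum(a & b)),
        tn=int(np.sum(~a & ~b)),
        fp=int(np.sum(a & ~b)),
        fn=int(np.sum(~a & b)),
    )


def rates(counts: ConfusionCounts) -> Rates:
    """Sensitivity, specificity, precision, FPR (as FP/(FP+FN)), accuracy."""
    return Rates(
        sensitivity=_ratio(counts.tp, counts.fn + counts.tp),
        specificity=_ratio(counts.tn, counts.fp + counts.tn),
        precision=_ratio(counts.tp, counts.fp + counts.tp),
        fpr=_ratio(counts.fp, counts.fp + counts.fn),
        accuracy=_ratio(counts.tp + counts.tn, counts.total),
    )


def dice(set1, set2) -> float:
    """100 * 2|A∩B| / (|A| + |B|); two empty masks agree perfectly (100)."""
    a, b = _mask_pair(set1, set2)
    na, nb = int(a.sum()), int(b.sum())
    if na + nb == 0:
        return 100.0
    return 100.0 * 2.0 * int(np.sum(a & b)) / (na + nb)


def voe(set1, set2) -> float:
    """100 * (1 - |A∩B| / |A∪B|); two empty masks → 0."""
    a, b = _mask_pair(set1, set2)
    union = int(np.sum(a | b))
    if union == 0:
        return 0.0
    return 100.0 * (1.0 - int(np.sum(a & b)) / union)


def rvd(set1, set2) -> float:
    """100 * (|A| - |B|) / |B| with B the ground truth (must be nonempty)."""
    a, b = _mask_pair(set1, set2)
    nb = int(b.sum())
    if nb == 0:
        raise ValidationError("rvd undefined for empty ground truth")
    return 100.0 * (int(a.sum()) - nb) / nb


def evaluate(pred, truth) -> EvalReport:
    """All eight metrics assembled from one confusion-count pass."""
    counts = confusion_counts(pred, truth)
    r = rates(counts)
    return EvalReport(
        tp=counts.tp,
        tn=counts.tn,
        fp=counts.fp,
        fn=counts.fn,
        sensitivity=r.sensitivity,
        specificity=r.specificity,
        precision=r.precision,
        fpr=r.fpr,
        fpr_conventional=_ratio(counts.fp, counts.fp + counts.tn),
        accuracy=r.accuracy,
        dice=dice(pred, truth),
        voe=voe(pred, truth),
        rvd=rvd(pred, truth),
    )
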