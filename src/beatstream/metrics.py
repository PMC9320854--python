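"""Confusion matrices and support-weighted evaluation metrics.

The confusion matrix is 5x5 in the fixed class order (N, SVEB, VEB, F, Q),
rows = actual class, columns = predicted class.  The four summary metrics
are accuracy (trace / total), and support-weighted precision, recall and
F1, where a class that is never predicted contributes precision 0 and a
class with precision + recall = 0 contributes F1 0.  Support-weighted
recall is algebraically identical to accuracy, which the report asserts.

Percentages are rounded half-up to two decimals at report time only; all
internal arithmetic is exact fractions of counts.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Sequence

import numpy as np
import pandas as pd

from beatstream.wfdb_io import AAMI_CLASSES

__all__ = ["ConfusionMatrix", "MetricsReport", "confusion_matrix", "evaluate", "percent"]


def percent(fraction: float, decimals: int = 2) -> float:
    """Fraction -> percentage, rounded half-up (91.245 % prints as 91.25)."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(fraction * 100.0)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ConfusionMatrix:
    """5x5 counts; rows = actual, columns = predicted, order (N, SVEB, VEB, F, Q).

    Entries may be real-valued for matrices averaged over repeated runs.
    """

    counts: np.ndarray
    classes: tuple[str, ...] = AAMI_CLASSES

    def __post_init__(self) -> None:
        arr = np.asarray(self.counts, dtype=float)
        k = len(self.classes)
        if arr.shape != (k, k):
            raise ValueError(f"expected a {k}x{k} matrix, got shape {arr.shape}")
        if np.any(arr < 0):
            raise ValueError("confusion matrix entries must be non-negative")
        object.__setattr__(self, "counts", arr)

    @property
    def supports(self) -> np.ndarray:
        """Per-class actual counts (row sums)."""
        return self.counts.sum(axis=1)

    @property
    def total(self) -> float:
        return float(self.counts.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=list(self.classes), columns=list(self.classes))


def confusion_matrix(
    actual: Sequence[str], predicted: Sequence[str], classes: Sequence[str] = AAMI_CLASSES
) -> ConfusionMatrix:
    """Count matrix with entry (i, j) = beats of actual class i predicted as j."""
    actual = list(actual)
    predicted = list(predicted)
    if len(actual) != len(predicted):
        raise ValueError(f"length mismatch: {len(actual)} actual vs {len(predicted)} predicted")
    index = {c: i for i, c in enumerate(classes)}
    counts = np.zeros((len(classes), len(classes)))
    for a, p in zip(actual, predicted):
        if a not in index or p not in index:
            raise ValueError(f"label outside the class set: {(a, p)}")
        counts[index[a], index[p]] += 1
    return ConfusionMatrix(counts, tuple(classes))


@dataclass(frozen=True)
class MetricsReport:
    """Summary and per-class metrics, stored as exact fractions in [0, 1]."""

    accuracy: float
    weighted_precision: float
    weighted_recall: float
    weighted_f1: float
    per_class: pd.DataFrame  # columns: precision, recall, f1, support

    def as_percent(self) -> dict[str, float]:
        """The four summary metrics as percentages, two decimals, half-up."""
        return {
            "accuracy": percent(self.accuracy),
            "precision": percent(self.weighted_precision),
            "recall": percent(self.weighted_recall),
            "f1": percent(self.weighted_f1),
        }

    def __str__(self) -> str:
        p = self.as_percent()
        head = (
            f"accuracy {p['accuracy']:.2f}%  precision {p['precision']:.2f}%  "
            f"recall {p['recall']:.2f}%  f1 {p['f1']:.2f}%"
        )
        return head + "\n" + self.per_class.to_string(float_format=lambda v: f"{v:.4f}")


def evaluate(cm: ConfusionMatrix) -> MetricsReport:
    """Summary metrics from a confusion matrix.

    Accuracy is trace / total.  Per-class precision and recall use the
    zero-division -> 0 convention; weighted aggregates are
    ``sum(support_c * metric_c) / total``.
    """
    counts = cm.counts
    total = cm.total
    if total <= 0:
        raise ValueError("confusion matrix is empty")
    tp = np.diag(counts)
    col = counts.sum(axis=0)
    row = counts.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        precision = np.where(col > 0, tp / np.where(col > 0, col, 1.0), 0.0)
        recall = np.where(row > 0, tp / np.where(row > 0, row, 1.0), 0.0)
        pr = precision + recall
        f1 = np.where(pr > 0, 2.0 * precision * recall / np.where(pr > 0, pr, 1.0), 0.0)
    accuracy = float(tp.sum() / total)
    w = row / total
    per_class = pd.DataFrame(
        {"precision": precision, "recall": recall, "f1": f1, "support": row},
        index=list(cm.classes),
    )
    return MetricsReport(
        accuracy=accuracy,
        weighted_precision=float(np.dot(w, precision)),
        weighted_recall=float(np.dot(w, recall)),
        weighted_f1=float(np.dot(w, f1)),
        per_class=per_class,
    )
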