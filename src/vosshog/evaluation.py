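"""Confusion matrices, accuracy/MSE metrics, reports, and the summary grid.

Accuracy is 100 * trace / total of a confusion matrix whose rows are true
classes and columns predicted classes, in the fixed six-class order.  MSE is
the mean over samples and output units of the squared difference between
output vectors and one-hot targets — the same metric for ANN outputs and
one-hot-coded SVM predictions, so the final summary grid is coherent across
model families.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import confusion_matrix as _sk_confusion

from .encoding import CLASS_NAMES

#: Row order of the summary grid: classifier x descriptor combinations.
GRID_ORDER = (
    "ann/hog", "ann-ensemble/hog", "ann/lbp", "ann-ensemble/lbp",
    "svm/hog", "svm-ensemble/hog", "svm/lbp", "svm-ensemble/lbp",
)


class LabelError(ValueError):
    """Label outside the declared class order."""


class ReportError(ValueError):
    """Malformed or duplicated experiment report."""


@dataclass
class ConfusionMatrix:
    """6x6 (or k x k) count grid: rows = true class, columns = predicted."""

    counts: np.ndarray
    class_order: tuple = CLASS_NAMES

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        k = len(self.class_order)
        if self.counts.shape != (k, k):
            raise LabelError(
                f"counts shape {self.counts.shape} != ({k}, {k})")
        if np.any(self.counts < 0):
            raise LabelError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=list(self.class_order),
                            columns=list(self.class_order))


def confusion_matrix(y_true, y_pred, class_order=CLASS_NAMES) -> ConfusionMatrix:
    """Count (true, predicted) pairs into the fixed class order."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if len(y_true) != len(y_pred):
        raise LabelError("true and predicted label sequences differ in length")
    order = list(class_order)
    for arr, which in ((y_true, "true"), (y_pred, "predicted")):
        unknown = set(arr.tolist()) - set(order)
        if unknown:
            raise LabelError(f"unknown {which} labels: {sorted(map(str, unknown))}")
    counts = _sk_confusion(y_true, y_pred, labels=order)
    return ConfusionMatrix(counts=counts, class_order=tuple(order))


def accuracy(cm: ConfusionMatrix | np.ndarray) -> float:
    """Percent accuracy: 100 * trace / total."""
    counts = cm.counts if isinstance(cm, ConfusionMatrix) else np.asarray(cm)
    total = counts.sum()
    if total == 0:
        raise ZeroDivisionError("empty confusion matrix has no accuracy")
    return 100.0 * float(np.trace(counts)) / float(total)


def mse_metric(outputs, targets) -> float:
    """Mean over samples and output units of the squared error."""
    outputs = np.asarray(outputs, dtype=float)
    targets = np.asarray(targets, dtype=float)
    if outputs.shape != targets.shape:
        raise ValueError(
            f"outputs shape {outputs.shape} != targets shape {targets.shape}")
    return float(np.mean((outputs - targets) ** 2))


def member_table_summary(accuracies, mses) -> dict:
    """Totals and averages of per-member ensemble metrics (a total row,
    then average = total / n)."""
    accuracies = np.asarray(accuracies, dtype=float)
    mses = np.asarray(mses, dtype=float)
    if len(accuracies) != len(mses) or len(accuracies) == 0:
        raise ReportError("need matching non-empty accuracy and MSE columns")
    return {
        "n": len(accuracies),
        "total_accuracy": float(accuracies.sum()),
        "total_mse": float(mses.sum()),
        "average_accuracy": float(accuracies.mean()),
        "average_mse": float(mses.mean()),
    }


def column_total(values) -> float:
    """Sum of a printed table column (e.g. per-class sample counts)."""
    return float(np.sum(np.asarray(values, dtype=float)))


@dataclass
class ExperimentReport:
    """One classifier x descriptor result with its provenance."""

    combo: str  # e.g. "ann-ensemble/hog"
    confusion: ConfusionMatrix
    mse: float
    seeds: list = field(default_factory=list)
    config: dict = field(default_factory=dict)
    evaluation_set: str = "test"

    @property
    def accuracy(self) -> float:
        return accuracy(self.confusion)


def summarize_grid(reports) -> pd.DataFrame:
    """One row per combo with accuracy and MSE; canonical order when all
    eight combos are present, otherwise input order."""
    reports = list(reports)
    if not reports:
        raise ReportError("no reports to summarize")
    combos = [r.combo for r in reports]
    if len(set(combos)) != len(combos):
        dupes = sorted({c for c in combos if combos.count(c) > 1})
        raise ReportError(f"duplicate combo tags: {dupes}")
    if set(combos) >= set(GRID_ORDER):
        reports = sorted(reports, key=lambda r: GRID_ORDER.index(r.combo)
                         if r.combo in GRID_ORDER else len(GRID_ORDER))
    return pd.DataFrame([
        {"combo": r.combo, "accuracy": round(r.accuracy, 1), "mse": r.mse,
         "evaluation_set": r.evaluation_set}
        for r in reports
    ])
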