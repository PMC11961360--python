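"""Confusion-matrix performance metrics.

Binders are the positive class. Five metrics summarize a confusion matrix:
accuracy, sensitivity (binder recall), specificity (non-binder recall),
balanced accuracy = (sensitivity + specificity) / 2, and the Matthews
correlation coefficient

    MCC = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN)).

A zero MCC denominator (a degenerate row or column of the matrix) is
reported as MCC = 0 with a flag.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    @classmethod
    def from_predictions(cls, y_true: np.ndarray, y_pred: np.ndarray) -> "ConfusionCounts":
        """Counts from binary vectors (1 = binder = positive)."""
        y_true = np.asarray(y_true, dtype=int)
        y_pred = np.asarray(y_pred, dtype=int)
        if y_true.shape != y_pred.shape:
            raise ValueError("prediction and truth vectors differ in length")
        return cls(
            tp=int(np.sum((y_true == 1) & (y_pred == 1))),
            tn=int(np.sum((y_true == 0) & (y_pred == 0))),
            fp=int(np.sum((y_true == 0) & (y_pred == 1))),
            fn=int(np.sum((y_true == 1) & (y_pred == 0))),
        )

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(self.tp + other.tp, self.tn + other.tn,
                               self.fp + other.fp, self.fn + other.fn)


@dataclass(frozen=True)
class MetricsReport:
    accuracy: float
    sensitivity: float
    specificity: float
    balanced_accuracy: float
    mcc: float
    counts: ConfusionCounts
    mcc_undefined: bool = False

    def as_dict(self) -> dict[str, float]:
        return {
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "balanced_accuracy": self.balanced_accuracy,
            "mcc": self.mcc,
        }


def compute_metrics(counts: ConfusionCounts) -> MetricsReport:
    """Evaluate the five metrics on one confusion matrix."""
    tp, tn, fp, fn = counts.tp, counts.tn, counts.fp, counts.fn
    if counts.total == 0:
        raise ValueError("metrics are undefined with zero evaluated compounds")
    accuracy = (tp + tn) / counts.total
    sensitivity = tp / (tp + fn) if tp + fn else 0.0
    specificity = tn / (tn + fp) if tn + fp else 0.0
    balanced = (sensitivity + specificity) / 2
    denom = math.sqrt(float(tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    undefined = denom == 0.0
    mcc = 0.0 if undefined else (tp * tn - fp * fn) / denom
    return MetricsReport(accuracy, sensitivity, specificity, balanced, mcc,
                         counts, mcc_undefined=undefined)
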