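"""Prediction-confidence and applicability-domain (AD) reliability analysis.

Confidence of a prediction is |prob - 0.5| / 0.5, mapping the binder
probability to [0, 1]: 0 at the decision boundary, 1 at certainty.
Predictions are allocated to ten equal-width confidence bins and metrics
are computed per bin (skipped below a minimum count, where they would not
be statistically meaningful).

The AD of a model is the per-descriptor min-max bounding box of its
training compounds. A compound's distance to the box is the Euclidean norm
of the per-descriptor out-of-range distances (0 for in-range descriptors),
so the distance is zero exactly when the compound is inside the box.
Metrics are compared between the inside (distance == 0) and outside
(distance > 0) groups.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .metrics import ConfusionCounts, MetricsReport, compute_metrics
from .preprocessing import DescriptorTable

DEFAULT_CONFIDENCE_BINS = 10
DEFAULT_MIN_COUNT = 5

_LABEL_TO_INT = {"binder": 1, "nonbinder": 0}


@dataclass
class PredictionRecord:
    """Per-compound prediction with its reliability annotations."""

    compound_id: str
    true_label: str
    predicted_label: str
    prob: float
    confidence: float
    ad_distance: float = 0.0


@dataclass
class ADBounds:
    """Training bounding box: per retained descriptor, [lower, upper]."""

    descriptor_names: list[str]
    lower: np.ndarray
    upper: np.ndarray

    def __post_init__(self) -> None:
        self.lower = np.asarray(self.lower, dtype=float)
        self.upper = np.asarray(self.upper, dtype=float)
        if np.any(self.lower > self.upper):
            raise ValueError("AD lower bound exceeds upper bound")


@dataclass
class ConfidenceBin:
    low: float
    high: float
    count: int
    metrics: MetricsReport | None  # None when count < min_count


@dataclass
class ConfidenceBinReport:
    bins: list[ConfidenceBin]
    min_count: int

    @property
    def total(self) -> int:
        return sum(b.count for b in self.bins)


def prediction_confidence(prob: float) -> float:
    """Confidence |prob - 0.5| / 0.5 of a binder probability."""
    if not 0.0 <= prob <= 1.0:
        raise ValueError(f"probability {prob} outside [0, 1]")
    return abs(prob - 0.5) / 0.5


def _records_metrics(records: list[PredictionRecord]) -> MetricsReport:
    y_true = np.array([_LABEL_TO_INT[r.true_label] for r in records])
    y_pred = np.array([_LABEL_TO_INT[r.predicted_label] for r in records])
    return compute_metrics(ConfusionCounts.from_predictions(y_true, y_pred))


def bin_by_confidence(records: list[PredictionRecord],
                      n_bins: int = DEFAULT_CONFIDENCE_BINS,
                      min_count: int = DEFAULT_MIN_COUNT) -> ConfidenceBinReport:
    """Allocate predictions to equal-width confidence bins over [0, 1].

    Bins are half-open [k/n, (k+1)/n) with the final bin closed so that
    confidence 1.0 lands in the top bin. Per-bin metrics are computed only
    when the bin holds at least ``min_count`` predictions.
    """
    if not records:
        raise ValueError("no prediction records to bin")
    buckets: list[list[PredictionRecord]] = [[] for _ in range(n_bins)]
    for rec in records:
        idx = min(int(rec.confidence * n_bins), n_bins - 1)
        buckets[idx].append(rec)
    bins = []
    for k, bucket in enumerate(buckets):
        metrics = _records_metrics(bucket) if len(bucket) >= min_count else None
        bins.append(ConfidenceBin(k / n_bins, (k + 1) / n_bins, len(bucket), metrics))
    return ConfidenceBinReport(bins, min_count)


def fit_ad(training: DescriptorTable) -> ADBounds:
    """Bounding box of the training compounds (per-descriptor min/max)."""
    if training.n_compounds == 0:
        raise ValueError("cannot fit an applicability domain on an empty table")
    return ADBounds(list(training.descriptor_names),
                    training.values.min(axis=0), training.values.max(axis=0))


def ad_distance(row: np.ndarray, bounds: ADBounds) -> float:
    """Euclidean distance of one descriptor vector to the training box."""
    row = np.asarray(row, dtype=float)
    if row.shape[0] != bounds.lower.shape[0]:
        raise ValueError("descriptor vector length does not match AD bounds")
    below = np.maximum(bounds.lower - row, 0.0)
    above = np.maximum(row - bounds.upper, 0.0)
    return float(np.sqrt(np.sum((below + above) ** 2)))


def ad_distances(table: DescriptorTable, bounds: ADBounds) -> np.ndarray:
    """Vectorized box distances for every compound in *table*."""
    if list(table.descriptor_names) != list(bounds.descriptor_names):
        raise ValueError("table columns do not match AD bounds schema")
    below = np.maximum(bounds.lower - table.values, 0.0)
    above = np.maximum(table.values - bounds.upper, 0.0)
    return np.sqrt(np.sum((below + above) ** 2, axis=1))


@dataclass
class ADSplitReport:
    inside: MetricsReport | None
    outside: MetricsReport | None
    n_inside: int
    n_outside: int


def split_by_ad(records: list[PredictionRecord],
                min_count: int = DEFAULT_MIN_COUNT) -> ADSplitReport:
    """Compare metrics between in-AD (distance 0) and out-of-AD predictions.

    A group smaller than ``min_count`` is reported with its count only.
    """
    inside = [r for r in records if r.ad_distance == 0.0]
    outside = [r for r in records if r.ad_distance > 0.0]
    return ADSplitReport(
        inside=_records_metrics(inside) if len(inside) >= min_count else None,
        outside=_records_metrics(outside) if len(outside) >= min_count else None,
        n_inside=len(inside),
        n_outside=len(outside),
    )


def make_records(compound_ids: list[str], y_true: np.ndarray, probs: np.ndarray,
                 distances: np.ndarray | None = None,
                 threshold: float = 0.5) -> list[PredictionRecord]:
    """Assemble PredictionRecords from aligned arrays."""
    if distances is None:
        distances = np.zeros(len(compound_ids))
    recs = []
    for cid, yt, p, d in zip(compound_ids, y_true, probs, distances):
        p = float(p)
        recs.append(PredictionRecord(
            compound_id=cid,
            true_label="binder" if yt == 1 else "nonbinder",
            predicted_label="binder" if p >= threshold else "nonbinder",
            prob=p,
            confidence=prediction_confidence(p),
            ad_distance=float(d),
        ))
    return recs
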