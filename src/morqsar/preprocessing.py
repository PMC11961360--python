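"""Descriptor-table preprocessing.

The pipeline works on a compounds x descriptors matrix of continuous values
(Mold2-style 2D descriptors). Three transforms are fitted on the training
table and applied verbatim to external data:

1. near-constant removal — a descriptor whose single most frequent value
   covers strictly more than 90% of compounds is dropped;
2. Shannon-entropy filtering — each surviving descriptor's value range is
   split into 20 equal-width bins, H = -sum p_i log2 p_i is computed over
   the bin occupancies, and descriptors with H < 2.0 bits are dropped;
3. min-max scaling — V = (V_o - Min_train) / (Max_train - Min_train) with
   training-set bounds, so external values may legitimately fall outside
   [0, 1].
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

DEFAULT_CONSTANT_FRACTION = 0.90
DEFAULT_N_BINS = 20
DEFAULT_ENTROPY_CUTOFF = 2.0


@dataclass
class DescriptorTable:
    """Ordered compounds x descriptors matrix with optional activity labels."""

    compound_ids: list[str]
    descriptor_names: list[str]
    values: np.ndarray  # shape (n_compounds, n_descriptors), float
    labels: np.ndarray | None = None  # per-compound "binder"/"nonbinder"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.compound_ids), len(self.descriptor_names)):
            raise ValueError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.compound_ids)} ids x {len(self.descriptor_names)} names"
            )
        if np.isnan(self.values).any():
            r, c = np.argwhere(np.isnan(self.values))[0]
            raise ValueError(
                f"missing value at compound {self.compound_ids[r]!r}, "
                f"descriptor {self.descriptor_names[c]!r}"
            )
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=object)
            if self.labels.shape[0] != len(self.compound_ids):
                raise ValueError("label vector length does not match compound count")

    @property
    def n_compounds(self) -> int:
        return len(self.compound_ids)

    @property
    def n_descriptors(self) -> int:
        return len(self.descriptor_names)

    def select_columns(self, names: list[str]) -> "DescriptorTable":
        idx = [self.descriptor_names.index(n) for n in names]
        return DescriptorTable(
            list(self.compound_ids), list(names), self.values[:, idx],
            None if self.labels is None else self.labels.copy(),
        )

    def select_rows(self, row_idx: np.ndarray) -> "DescriptorTable":
        row_idx = np.asarray(row_idx)
        return DescriptorTable(
            [self.compound_ids[i] for i in row_idx],
            list(self.descriptor_names),
            self.values[row_idx],
            None if self.labels is None else self.labels[row_idx],
        )

    def label_array(self) -> np.ndarray:
        """Binary y vector: 1 = binder, 0 = nonbinder."""
        if self.labels is None:
            raise ValueError("table carries no labels")
        return (np.asarray(self.labels) == "binder").astype(int)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, index=pd.Index(self.compound_ids, name="compound_id"),
                          columns=self.descriptor_names)
        if self.labels is not None:
            df.insert(0, "label", self.labels)
        return df


@dataclass
class FilterReport:
    """Outcome of the two-stage descriptor filter; partitions the input names."""

    removed_constant: list[str]
    entropy_values: dict[str, float]
    removed_low_entropy: list[str]
    retained: list[str]
    n_bins: int = DEFAULT_N_BINS
    cutoff: float = DEFAULT_ENTROPY_CUTOFF
    constant_fraction_threshold: float = DEFAULT_CONSTANT_FRACTION

    def to_json(self) -> str:
        return json.dumps(self.__dict__, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "FilterReport":
        return cls(**json.loads(text))


@dataclass
class ScalingParams:
    """Per-descriptor training-set min/max for the affine rescale."""

    descriptor_names: list[str]
    minimum: np.ndarray
    maximum: np.ndarray

    def __post_init__(self) -> None:
        self.minimum = np.asarray(self.minimum, dtype=float)
        self.maximum = np.asarray(self.maximum, dtype=float)
        if np.any(self.minimum > self.maximum):
            raise ValueError("scaling minimum exceeds maximum")

    def to_json(self) -> str:
        return json.dumps(
            {"descriptor_names": self.descriptor_names,
             "minimum": self.minimum.tolist(), "maximum": self.maximum.tolist()})

    @classmethod
    def from_json(cls, text: str) -> "ScalingParams":
        d = json.loads(text)
        return cls(d["descriptor_names"], np.array(d["minimum"]), np.array(d["maximum"]))


def remove_near_constant(
    table: DescriptorTable, threshold: float = DEFAULT_CONSTANT_FRACTION
) -> tuple[DescriptorTable, list[str]]:
    """Drop descriptors whose modal value covers > *threshold* of compounds.

    The rule is a strict inequality: a modal fraction of exactly the
    threshold is retained. Column order of survivors is preserved.
    """
    if table.n_compounds == 0 or table.n_descriptors == 0:
        raise ValueError("cannot filter an empty descriptor table")
    removed: list[str] = []
    keep: list[str] = []
    n = table.n_compounds
    for j, name in enumerate(table.descriptor_names):
        _, counts = np.unique(table.values[:, j], return_counts=True)
        if counts.max() > threshold * n:
            removed.append(name)
        else:
            keep.append(name)
    return table.select_columns(keep), removed


def shannon_entropy(values: np.ndarray, n_bins: int = DEFAULT_N_BINS) -> float:
    """Shannon entropy (bits) of the equal-width histogram of *values*.

    The range [min, max] is split into ``n_bins`` half-open intervals
    [low, high) with the final bin closed so the maximum is counted once.
    A constant vector has zero range; all mass sits in one group and H = 0.
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("entropy of an empty vector is undefined")
    lo, hi = v.min(), v.max()
    if lo == hi:
        return 0.0
    edges = lo + (hi - lo) * np.arange(1, n_bins) / n_bins
    counts = np.bincount(np.searchsorted(edges, v, side="right"), minlength=n_bins)
    p = counts[counts > 0] / v.size
    return float(-(p * np.log2(p)).sum())


def filter_by_entropy(
    table: DescriptorTable,
    cutoff: float = DEFAULT_ENTROPY_CUTOFF,
    n_bins: int = DEFAULT_N_BINS,
    removed_constant: list[str] | None = None,
    constant_threshold: float = DEFAULT_CONSTANT_FRACTION,
) -> tuple[DescriptorTable, FilterReport]:
    """Drop descriptors with entropy below *cutoff* bits (H >= cutoff retained).

    Expects the near-constant filter to have run already (pass its removal
    list through ``removed_constant`` so the report partitions the original
    descriptor set).
    """
    entropies = {
        name: shannon_entropy(table.values[:, j], n_bins)
        for j, name in enumerate(table.descriptor_names)
    }
    retained = [n for n in table.descriptor_names if entropies[n] >= cutoff]
    removed = [n for n in table.descriptor_names if entropies[n] < cutoff]
    report = FilterReport(
        removed_constant=list(removed_constant or []),
        entropy_values=entropies,
        removed_low_entropy=removed,
        retained=retained,
        n_bins=n_bins,
        cutoff=cutoff,
        constant_fraction_threshold=constant_threshold,
    )
    if not retained:
        raise ValueError(f"entropy filter removed every descriptor; report: {report.to_json()}")
    return table.select_columns(retained), report


def apply_filters(
    table: DescriptorTable,
    constant_threshold: float = DEFAULT_CONSTANT_FRACTION,
    cutoff: float = DEFAULT_ENTROPY_CUTOFF,
    n_bins: int = DEFAULT_N_BINS,
) -> tuple[DescriptorTable, FilterReport]:
    """Run the full two-stage filter (near-constant, then entropy)."""
    reduced, removed_const = remove_near_constant(table, constant_threshold)
    return filter_by_entropy(
        reduced, cutoff, n_bins,
        removed_constant=removed_const, constant_threshold=constant_threshold,
    )


def apply_retained(table: DescriptorTable, retained: list[str]) -> DescriptorTable:
    """Reduce *table* to exactly the training-retained columns, training order."""
    missing = [n for n in retained if n not in table.descriptor_names]
    if missing:
        raise KeyError(f"descriptor(s) missing from table: {missing}")
    return table.select_columns(list(retained))


def fit_scaler(training: DescriptorTable) -> ScalingParams:
    """Record per-descriptor min/max over the training rows only."""
    if training.n_compounds == 0:
        raise ValueError("cannot fit a scaler on an empty table")
    mins = training.values.min(axis=0)
    maxs = training.values.max(axis=0)
    for j, name in enumerate(training.descriptor_names):
        if mins[j] == maxs[j]:
            log.info("descriptor %s is constant in training: degenerate scaling", name)
    return ScalingParams(list(training.descriptor_names), mins, maxs)


def apply_scaler(table: DescriptorTable, params: ScalingParams) -> DescriptorTable:
    """Affine rescale with training bounds; degenerate columns map to 0.

    External values outside the training range map outside [0, 1] — by
    design, since the applicability-domain distance reads these directly.
    """
    if list(table.descriptor_names) != list(params.descriptor_names):
        raise ValueError("scaler schema does not match table columns")
    span = params.maximum - params.minimum
    safe = np.where(span == 0, 1.0, span)
    scaled = (table.values - params.minimum) / safe
    scaled[:, span == 0] = 0.0
    return DescriptorTable(
        list(table.compound_ids), list(table.descriptor_names), scaled,
        None if table.labels is None else table.labels.copy(),
    )
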