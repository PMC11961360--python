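"""Synthetic descriptor tables with the statistical structure the pipeline assumes.

The generator emulates what an upstream 2D-descriptor calculator (Mold2-style)
would produce for a curated compound set, without any chemistry: a continuous
compounds x descriptors matrix containing

* *informative* columns — class-conditional unit-variance normals whose means
  differ by ``effect_size`` between binders and non-binders;
* *noise* columns — class-independent standard normals;
* *constant* columns — one modal value on 95% of compounds (removed by the
  near-constant filter, whose rule is "modal fraction strictly above 90%");
* *low-entropy* columns — mass concentrated on three spike values, hence at
  most three occupied bins of twenty and entropy <= log2(3) < 2 bits.

The external split emulates the qHTS-vs-traditional-assay discordance of the
study: its descriptors are covariate-shifted by ``shift_magnitude``, a
fraction ``label_flip_rate`` of its labels is flipped, and ``n_out_of_ad``
rows are pushed outside the training descriptor box. All remaining external
values are clipped into the training box so that the planted rows are
exactly the out-of-domain set. Class imbalance defaults to ~5:1
binders:non-binders, mirroring curated receptor-binding datasets where
binders dominate the literature.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_curation import RawRecord, SourceKind
from .preprocessing import DescriptorTable

#: spike probabilities of planted low-entropy columns (3 occupied bins,
#: H = 1.5589... bits < 2, modal fraction 0.40 < 0.90)
_SPIKE_PROBS = (0.40, 0.35, 0.25)
_SPIKE_VALUES = (0.0, 10.0, 20.0)
_CONSTANT_MODAL_FRACTION = 0.95


@dataclass
class SyntheticConfig:
    """Study-shaped generator settings (desk scale: 2,000 x 100 by default)."""

    n_binders: int = 1667
    n_nonbinders: int = 333
    n_informative: int = 10
    n_noise: int = 78
    n_constant: int = 5
    n_lowentropy: int = 7
    effect_size: float = 1.0
    external_fraction: float = 0.30
    shift_magnitude: float = 0.5
    label_flip_rate: float = 0.15
    n_out_of_ad: int = 40
    seed: int = 0

    def __post_init__(self) -> None:
        counts = (self.n_binders, self.n_nonbinders, self.n_informative,
                  self.n_noise, self.n_constant, self.n_lowentropy, self.n_out_of_ad)
        if any(c < 0 for c in counts):
            raise ValueError("all counts must be non-negative")
        for frac in (self.external_fraction, self.label_flip_rate):
            if not 0.0 <= frac <= 1.0:
                raise ValueError("fractions must lie in [0, 1]")
        if self.n_out_of_ad > self.n_external_total:
            raise ValueError("n_out_of_ad exceeds the external split size")

    @property
    def n_descriptors(self) -> int:
        return self.n_informative + self.n_noise + self.n_constant + self.n_lowentropy

    @property
    def n_external_total(self) -> int:
        return (int(round(self.external_fraction * self.n_binders))
                + int(round(self.external_fraction * self.n_nonbinders)))


def full_scale_config(**overrides) -> SyntheticConfig:
    """A 777-descriptor preset whose planted filter counts mirror the reference
    descriptor bookkeeping (263 near-constant + 226 low-entropy + 288 kept)."""
    base = dict(n_informative=20, n_noise=268, n_constant=263, n_lowentropy=226)
    base.update(overrides)
    return SyntheticConfig(**base)


@dataclass
class TruthBookkeeping:
    """Which planted structure went where; verifiable against the tables."""

    informative: list[str]
    noise: list[str]
    constant: list[str]
    lowentropy: list[str]
    out_of_ad_ids: list[str]
    flipped_ids: list[str]

    def to_json(self) -> str:
        return json.dumps(self.__dict__, sort_keys=True)


@dataclass
class SyntheticDataset:
    training: DescriptorTable
    external: DescriptorTable
    truth: TruthBookkeeping


def _pick_balanced(y: np.ndarray, n: int, rng: np.random.Generator) -> np.ndarray:
    """Sample *n* row indices, as close to class-balanced as the labels allow."""
    if n == 0:
        return np.array([], dtype=int)
    ones, zeros = np.flatnonzero(y == 1), np.flatnonzero(y == 0)
    n_one = min(n // 2 + n % 2, len(ones))
    n_zero = min(n - n_one, len(zeros))
    n_one = min(n - n_zero, len(ones))  # refill if a class ran short
    picked = np.concatenate([rng.choice(ones, size=n_one, replace=False),
                             rng.choice(zeros, size=n_zero, replace=False)])
    return np.sort(picked)


def _planted_column(kind: str, y: np.ndarray, effect_size: float,
                    col_seed_rng: np.random.Generator) -> np.ndarray:
    n = y.shape[0]
    if kind == "informative":
        return col_seed_rng.normal(0.0, 1.0, n) + effect_size * y
    if kind == "noise":
        return col_seed_rng.normal(0.0, 1.0, n)
    if kind == "constant":
        # exact modal fraction above the 90% removal threshold
        n_modal = max(int(np.ceil(_CONSTANT_MODAL_FRACTION * n)), int(0.9 * n) + 1)
        v0 = float(col_seed_rng.uniform(-5, 5))
        rest = v0 + 1.0 + col_seed_rng.uniform(0.0, 1.0, n - n_modal)
        vals = np.concatenate([np.full(n_modal, v0), rest])
        return vals[col_seed_rng.permutation(n)]
    if kind == "lowentropy":
        # exact spike counts: three occupied bins whatever the sample
        counts = [int(round(p * n)) for p in _SPIKE_PROBS[:-1]]
        counts.append(n - sum(counts))
        vals = np.concatenate([np.full(c, v) for c, v in zip(counts, _SPIKE_VALUES)])
        return vals[col_seed_rng.permutation(n)]
    raise ValueError(kind)


def generate(config: SyntheticConfig) -> SyntheticDataset:
    """Generate the training/external descriptor tables plus bookkeeping.

    Fully determined by ``config`` (including its seed): the same config
    yields byte-identical tables.
    """
    rng = np.random.default_rng(config.seed)
    roles = (["informative"] * config.n_informative + ["noise"] * config.n_noise
             + ["constant"] * config.n_constant + ["lowentropy"] * config.n_lowentropy)
    roles = [roles[i] for i in rng.permutation(len(roles))]
    width = len(str(config.n_descriptors))
    names = [f"D{i + 1:0{width}d}" for i in range(config.n_descriptors)]

    def make_split(n_b: int, n_n: int, prefix: str) -> tuple[np.ndarray, np.ndarray, list[str]]:
        y = np.concatenate([np.ones(n_b, dtype=int), np.zeros(n_n, dtype=int)])
        y = y[rng.permutation(y.size)]
        cols = [_planted_column(role, y, config.effect_size, rng) for role in roles]
        ids = [f"{prefix}{i + 1:05d}" for i in range(y.size)]
        return np.column_stack(cols) if cols else np.empty((y.size, 0)), y, ids

    X_tr, y_tr, ids_tr = make_split(config.n_binders, config.n_nonbinders, "T")
    n_ext_b = int(round(config.external_fraction * config.n_binders))
    n_ext_n = int(round(config.external_fraction * config.n_nonbinders))
    X_ex, y_ex, ids_ex = make_split(n_ext_b, n_ext_n, "E")

    shifted = [i for i, r in enumerate(roles) if r in ("informative", "noise")]
    X_ex[:, shifted] += config.shift_magnitude

    # non-planted external rows are clipped into the training box so that
    # "outside AD" is exactly the planted set
    lo, hi = X_tr.min(axis=0), X_tr.max(axis=0)
    X_ex = np.clip(X_ex, lo, hi)

    n_flip = int(round(config.label_flip_rate * X_ex.shape[0]))
    flip_rows = rng.choice(X_ex.shape[0], size=n_flip, replace=False) \
        if n_flip else np.array([], dtype=int)
    y_ex[flip_rows] = 1 - y_ex[flip_rows]

    # planted out-of-domain rows emulate structurally alien compounds:
    # class-balanced, their informative signal mirrored into the opposite
    # class, and noise descriptors pushed beyond the training box
    out_rows = _pick_balanced(y_ex, config.n_out_of_ad, rng)
    informative_idx = [i for i, r in enumerate(roles) if r == "informative"]
    noise_idx = [i for i, r in enumerate(roles) if r == "noise"]
    for row in out_rows:
        for col in informative_idx:
            mirrored = config.effect_size + config.shift_magnitude - X_ex[row, col]
            X_ex[row, col] = np.clip(mirrored, lo[col], hi[col])
        push = rng.choice(noise_idx, size=min(2, len(noise_idx)), replace=False) \
            if noise_idx else [int(rng.integers(X_ex.shape[1]))]
        for col in push:
            span = max(hi[col] - lo[col], 1.0)
            sign = 1.0 if rng.random() < 0.5 else -1.0
            bound = hi[col] if sign > 0 else lo[col]
            X_ex[row, col] = bound + sign * (1.0 + rng.random()) * span

    to_label = np.vectorize(lambda v: "binder" if v else "nonbinder")
    truth = TruthBookkeeping(
        informative=[names[i] for i, r in enumerate(roles) if r == "informative"],
        noise=[names[i] for i, r in enumerate(roles) if r == "noise"],
        constant=[names[i] for i, r in enumerate(roles) if r == "constant"],
        lowentropy=[names[i] for i, r in enumerate(roles) if r == "lowentropy"],
        out_of_ad_ids=sorted(ids_ex[i] for i in out_rows),
        flipped_ids=sorted(ids_ex[i] for i in flip_rows),
    )
    return SyntheticDataset(
        training=DescriptorTable(ids_tr, names, X_tr, to_label(y_tr)),
        external=DescriptorTable(ids_ex, names, X_ex, to_label(y_ex)),
        truth=truth,
    )


def generate_qhts_outcomes(n: int, p_agonist: float, p_antagonist: float,
                           seed: int = 0) -> pd.DataFrame:
    """Simulated agonist/antagonist qHTS outcome table.

    Outcomes are independent Bernoulli draws per assay; applying the qHTS
    labeling rule yields a binder fraction near
    1 - (1 - p_agonist)(1 - p_antagonist).
    """
    for p in (p_agonist, p_antagonist):
        if not 0.0 <= p <= 1.0:
            raise ValueError("assay hit probabilities must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    ago = np.where(rng.random(n) < p_agonist, "active", "inactive")
    anta = np.where(rng.random(n) < p_antagonist, "active", "inactive")
    return pd.DataFrame({
        "id": [f"Q{i + 1:05d}" for i in range(n)],
        "agonist_outcome": ago,
        "antagonist_outcome": anta,
    })


def toy_smiles_fixture() -> list[RawRecord]:
    """Small fixed record set exercising every curation branch.

    Contains structural duplicates written as different SMILES ("CCO"/"OCC",
    same label -> one survivor), a benzene label-conflict pair (both
    dropped), an unparsable string (record-level error), and records for
    every qualitative-label and qHTS-outcome branch.
    """
    db = SourceKind.DATABASE
    qhts = SourceKind.QHTS
    return [
        RawRecord("db1", "CCO", db, quantitative_activity=True),
        RawRecord("db2", "OCC", db, quantitative_activity=True),
        RawRecord("db3", "c1ccccc1", db, qualitative_label="active"),
        RawRecord("db4", "C1=CC=CC=C1", db, qualitative_label="inactive"),
        RawRecord("db5", "CC(=O)O", db, qualitative_label="negative"),
        RawRecord("db6", "CCN", db, qualitative_label="inconclusive"),
        RawRecord("db7", "CCCl", db, qualitative_label="not determined"),
        RawRecord("db8", "not_a_smiles", db, qualitative_label="active"),
        RawRecord("db9", "CCC", db, qualitative_label="positive"),
        RawRecord("q1", "CCBr", qhts, agonist_outcome="inactive", antagonist_outcome="inactive"),
        RawRecord("q2", "CCI", qhts, agonist_outcome="active", antagonist_outcome="inactive"),
        RawRecord("q3", "CC=C", qhts, agonist_outcome="inactive", antagonist_outcome="active"),
        RawRecord("q4", "C#N", qhts, agonist_outcome="active", antagonist_outcome="active"),
        RawRecord("q5", "CCCC", qhts, agonist_outcome=None, antagonist_outcome="inactive"),
    ]
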