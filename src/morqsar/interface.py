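"""Run configuration, table I/O, and end-to-end pipeline orchestration.

A :class:`RunConfig` bundles every stage parameter of the workflow with the
study's printed defaults (90% near-constant threshold, 2.0-bit entropy
cutoff over 20 bins, 1,727 transferred non-binders, 5-fold splits, 5 inner
repeats, 50 outer iterations, 10 confidence bins). All randomness flows
from one master seed via named sub-streams. ``run_pipeline`` executes
generate/load -> filter -> scale -> tune/train -> cross-validation ->
external validation -> confidence and AD reports, and writes a manifest
with a checksum for every emitted file.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .evaluation import CVResult, ExternalResult, external_validate, outer_cv
from .modeling import ALGORITHMS, LearnerSpec, REFERENCE_FIXED, REFERENCE_GRIDS
from .preprocessing import DescriptorTable, apply_filters, fit_scaler
from .reliability import (ADSplitReport, ConfidenceBinReport, PredictionRecord,
                          bin_by_confidence, split_by_ad)
from .synthetic_data import SyntheticConfig, SyntheticDataset, generate

log = logging.getLogger(__name__)

#: grids/settings shrunk so the full nested protocol runs in minutes on one CPU
DESK_GRIDS: dict[str, dict[str, list]] = {
    "rf": {"n_estimators": [100], "min_samples_leaf": [10], "max_chemical": [1000]},
    "knn": {"n_neighbors": [3, 7], "weights": ["uniform"]},
    "svm": {"C": [1]},
    "mlp": {"alpha": [0.0001], "hidden_layer_sizes": [100]},
    "lstm": {},
}
DESK_FIXED: dict[str, dict] = {
    "rf": {"max_chemical_mode": "max_samples"},
    "knn": {},
    "svm": {"kernel": "linear"},
    "mlp": {"max_iter": 150},
    "lstm": {"n_layers": 1, "hidden_size": 16, "batch_size": 64,
             "learning_rate": 0.003, "max_epochs": 60, "checkpoint_every": 20,
             "seq_len": 4},
}


@dataclass
class RunConfig:
    """All stage parameters; defaults are the reference protocol values."""

    constant_threshold: float = 0.90
    entropy_cutoff: float = 2.0
    entropy_bins: int = 20
    transfer_count: int = 1727
    n_folds: int = 5
    inner_repeats: int = 5
    outer_iterations: int = 50
    confidence_bins: int = 10
    min_count: int = 5
    decision_threshold: float = 0.5
    prefit_preprocessing: bool = False
    ad_space: str = "scaled"  # "scaled" | "raw"
    seed: int = 0
    grids: dict = field(default_factory=lambda: {a: {k: list(v) for k, v in REFERENCE_GRIDS[a].items()}
                                                 for a in ALGORITHMS})
    fixed: dict = field(default_factory=lambda: {a: dict(REFERENCE_FIXED[a]) for a in ALGORITHMS})
    training_table: str | None = None
    external_table: str | None = None
    synthetic: dict | None = None  # SyntheticConfig fields; used when no tables

    def learner_specs(self) -> list[LearnerSpec]:
        return [LearnerSpec(a, {k: list(v) for k, v in self.grids.get(a, {}).items()},
                            dict(self.fixed.get(a, {}))) for a in ALGORITHMS]

    def to_yaml(self) -> str:
        return yaml.safe_dump(dataclasses.asdict(self), sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "RunConfig":
        return cls(**yaml.safe_load(text))

    def validate(self) -> None:
        if self.training_table is None and self.synthetic is None:
            raise ValueError("config needs either input table paths or a synthetic block")
        for path in (self.training_table, self.external_table):
            if path is not None and not Path(path).exists():
                raise FileNotFoundError(f"input table not found: {path}")
        if self.ad_space not in ("scaled", "raw"):
            raise ValueError(f"ad_space must be 'scaled' or 'raw', got {self.ad_space!r}")


def desk_scale_config(seed: int = 0, **synthetic_overrides) -> RunConfig:
    """The reduced-size end-to-end preset (2,000 x 100, 5 outer iterations)."""
    synth = dataclasses.asdict(SyntheticConfig(seed=seed, **synthetic_overrides))
    return RunConfig(
        outer_iterations=5, inner_repeats=2, seed=seed,
        grids={a: {k: list(v) for k, v in DESK_GRIDS[a].items()} for a in ALGORITHMS},
        fixed={a: dict(DESK_FIXED[a]) for a in ALGORITHMS},
        synthetic=synth,
    )


# ---------------------------------------------------------------------------
# table I/O
# ---------------------------------------------------------------------------

def _sep_for(path: Path) -> str:
    return "\t" if path.suffix.lower() in (".tsv", ".tab") else ","


def read_descriptor_table(path: str | Path) -> DescriptorTable:
    """Read a CSV/TSV descriptor table (first column compound id, optional
    'label' column). Duplicate ids, missing and non-numeric cells are fatal
    with their coordinates."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path), index_col=0, dtype=str)
    dup = df.index[df.index.duplicated()]
    if len(dup):
        raise ValueError(f"duplicated compound id {dup[0]!r} in {path}")
    labels = None
    if "label" in df.columns:
        labels = df.pop("label").to_numpy()
        bad = set(labels) - {"binder", "nonbinder"}
        if bad:
            raise ValueError(f"unknown label value(s) {sorted(bad)} in {path}")
    values = np.empty(df.shape, dtype=float)
    for j, col in enumerate(df.columns):
        converted = pd.to_numeric(df[col], errors="coerce")
        bad_mask = converted.isna()
        if bad_mask.any():
            row = df.index[bad_mask.to_numpy().argmax()]
            cell = df.loc[row, col]
            kind = "missing" if pd.isna(cell) else f"non-numeric ({cell!r})"
            raise ValueError(f"{kind} value at compound {row!r}, descriptor {col!r} in {path}")
        values[:, j] = converted.to_numpy()
    return DescriptorTable(list(df.index.astype(str)), list(df.columns), values, labels)


def write_descriptor_table(table: DescriptorTable, path: str | Path) -> None:
    path = Path(path)
    table.to_frame().to_csv(path, sep=_sep_for(path))


def records_to_frame(records: list[PredictionRecord]) -> pd.DataFrame:
    return pd.DataFrame([dataclasses.asdict(r) for r in records]).set_index("compound_id")


def confidence_report_to_frame(report: ConfidenceBinReport) -> pd.DataFrame:
    rows = []
    for b in report.bins:
        row = {"bin_low": b.low, "bin_high": b.high, "count": b.count}
        row.update(b.metrics.as_dict() if b.metrics else
                   {k: np.nan for k in ("accuracy", "sensitivity", "specificity",
                                        "balanced_accuracy", "mcc")})
        rows.append(row)
    return pd.DataFrame(rows)


def ad_report_to_dict(report: ADSplitReport) -> dict:
    return {
        "n_inside": report.n_inside,
        "n_outside": report.n_outside,
        "inside": report.inside.as_dict() if report.inside else None,
        "outside": report.outside.as_dict() if report.outside else None,
    }


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------

@dataclass
class PipelineResult:
    cv: CVResult
    external: ExternalResult
    confidence_cv: dict[str, ConfidenceBinReport]
    confidence_external: dict[str, ConfidenceBinReport]
    ad_cv: dict[str, ADSplitReport]
    ad_external: dict[str, ADSplitReport]
    dataset: SyntheticDataset | None
    out_dir: Path | None


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig, out_dir: str | Path | None = None) -> PipelineResult:
    """Execute the full workflow and (optionally) write all report files."""
    config.validate()
    dataset = None
    if config.training_table is not None:
        training = read_descriptor_table(config.training_table)
        if config.external_table is None:
            raise ValueError("an external table is required when reading tables from disk")
        external = read_descriptor_table(config.external_table)
    else:
        dataset = generate(SyntheticConfig(**config.synthetic))
        training, external = dataset.training, dataset.external

    specs = config.learner_specs()
    common = dict(n_folds=config.n_folds, inner_repeats=config.inner_repeats,
                  constant_threshold=config.constant_threshold,
                  entropy_cutoff=config.entropy_cutoff,
                  entropy_bins=config.entropy_bins, ad_space=config.ad_space)
    log.info("outer cross-validation: %d iterations x %d folds",
             config.outer_iterations, config.n_folds)
    cv = outer_cv(training, specs, n_iterations=config.outer_iterations,
                  seed=config.seed, prefit_preprocessing=config.prefit_preprocessing, **common)
    log.info("external validation on %d compounds", external.n_compounds)
    ext = external_validate(training, external, specs, seed=config.seed,
                            **{k: v for k, v in common.items() if k != "ad_space"},
                            ad_space=config.ad_space)

    conf_cv = {m: bin_by_confidence(recs, config.confidence_bins, config.min_count)
               for m, recs in cv.records.items() if recs}
    conf_ext = {m: bin_by_confidence(recs, config.confidence_bins, config.min_count)
                for m, recs in ext.records.items() if recs}
    ad_cv = {m: split_by_ad(recs, config.min_count) for m, recs in cv.records.items() if recs}
    ad_ext = {m: split_by_ad(recs, config.min_count) for m, recs in ext.records.items() if recs}

    out_path = None
    if out_dir is not None:
        out_path = Path(out_dir)
        out_path.mkdir(parents=True, exist_ok=True)
        _write_reports(config, training, cv, ext, conf_cv, conf_ext, ad_cv, ad_ext,
                       dataset, out_path)
    return PipelineResult(cv, ext, conf_cv, conf_ext, ad_cv, ad_ext, dataset, out_path)


def _write_reports(config: RunConfig, training: DescriptorTable, cv: CVResult,
                   ext: ExternalResult, conf_cv, conf_ext, ad_cv, ad_ext,
                   dataset: SyntheticDataset | None, out: Path) -> None:
    cv.summary().to_csv(out / "cv_summary.tsv", sep="\t")
    ext.summary().to_csv(out / "external_summary.tsv", sep="\t")
    iterations = {m: [r.as_dict() for r in reps] for m, reps in cv.metrics.items()}
    (out / "cv_iterations.json").write_text(json.dumps(iterations, indent=1))
    for name, reports in (("confidence_cv", conf_cv), ("confidence_external", conf_ext)):
        frames = {m: confidence_report_to_frame(r).to_dict(orient="records")
                  for m, r in reports.items()}
        (out / f"{name}.json").write_text(json.dumps(frames, indent=1))
    for name, reports in (("ad_cv", ad_cv), ("ad_external", ad_ext)):
        (out / f"{name}.json").write_text(
            json.dumps({m: ad_report_to_dict(r) for m, r in reports.items()}, indent=1))
    for model, recs in ext.records.items():
        records_to_frame(recs).to_csv(out / f"predictions_external_{model}.tsv", sep="\t")
    filt, report = apply_filters(training, config.constant_threshold,
                                 config.entropy_cutoff, config.entropy_bins)
    (out / "filter_report.json").write_text(report.to_json())
    (out / "scaling_params.json").write_text(fit_scaler(filt).to_json())
    if dataset is not None:
        (out / "synthetic_truth.json").write_text(dataset.truth.to_json())
    (out / "config.yaml").write_text(config.to_yaml())
    import sklearn
    files = sorted(p for p in out.iterdir() if p.is_file() and p.name != "manifest.json")
    manifest = {
        "seed": config.seed,
        "versions": {"morqsar": __version__, "numpy": np.__version__,
                     "pandas": pd.__version__, "sklearn": sklearn.__version__},
        "files": {p.name: _sha256(p) for p in files},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
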