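"""Model evaluation: repeated outer cross-validation and external validation.

The outer loop repeats a random 5-fold cross-validation ``n_iterations``
times. Within each iteration every fold is held out exactly once; the
preprocessing chain (near-constant filter, entropy filter, min-max scaler)
and the inner hyperparameter tuning see only the four training folds
(default; a *prefit* switch instead fits the filters and scaler
once on the full training table before splitting, matching protocols that
filter before cross-validating). Held-out predictions are pooled across
the five folds into one metrics report per model and iteration.

External validation tunes on the entire training set, applies the
training-fitted filters and scaler verbatim to the external table, and
emits per-compound prediction records (probability, confidence, AD
distance) for the downstream reliability analysis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .metrics import ConfusionCounts, MetricsReport, compute_metrics
from .modeling import (LearnerSpec, TunedLearner, consensus_mean_probability,
                       consensus_vote, draw_folds, inner_tune, N_MEMBERS)
from .preprocessing import (DescriptorTable, apply_filters, apply_retained,
                            apply_scaler, fit_scaler,
                            DEFAULT_CONSTANT_FRACTION, DEFAULT_ENTROPY_CUTOFF,
                            DEFAULT_N_BINS)
from .reliability import PredictionRecord, ad_distances, fit_ad, make_records

log = logging.getLogger(__name__)

CONSENSUS_VOTE = "consensus_vote"
CONSENSUS_MEANPROB = "consensus_meanprob"


@dataclass
class CVResult:
    """Per-iteration metrics and pooled prediction records per model."""

    metrics: dict[str, list[MetricsReport]]
    records: dict[str, list[PredictionRecord]]
    n_iterations: int

    def mean(self, model: str, metric: str = "mcc") -> float:
        return float(np.mean([getattr(m, metric) for m in self.metrics[model]]))

    def std(self, model: str, metric: str = "mcc") -> float:
        return float(np.std([getattr(m, metric) for m in self.metrics[model]]))

    def summary(self) -> pd.DataFrame:
        """Mean +/- std of each metric over the iterations, one row per model."""
        rows = []
        for model, reports in self.metrics.items():
            row: dict[str, float | str] = {"model": model}
            for metric in ("sensitivity", "specificity", "balanced_accuracy",
                           "accuracy", "mcc"):
                vals = [getattr(r, metric) for r in reports]
                row[f"{metric}_mean"] = float(np.mean(vals))
                row[f"{metric}_std"] = float(np.std(vals))
            rows.append(row)
        return pd.DataFrame(rows).set_index("model")


@dataclass
class ExternalResult:
    metrics: dict[str, MetricsReport]
    records: dict[str, list[PredictionRecord]]
    tuned: dict[str, TunedLearner]

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {model: rep.as_dict() for model, rep in self.metrics.items()}
        ).T


def _preprocess_split(train: DescriptorTable, test: DescriptorTable,
                      constant_threshold: float, cutoff: float, n_bins: int):
    """Fit filters + scaler on *train*; transform both splits."""
    train_f, report = apply_filters(train, constant_threshold, cutoff, n_bins)
    scaler = fit_scaler(train_f)
    train_s = apply_scaler(train_f, scaler)
    test_s = apply_scaler(apply_retained(test, report.retained), scaler)
    return train_s, test_s, report, scaler


def _consensus_rows(member_probs: dict[str, np.ndarray],
                    order: Sequence[str]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vote labels, mean-prob labels and mean probabilities per compound."""
    stacked = np.column_stack([member_probs[name] for name in order])
    member_labels = stacked >= 0.5
    votes = member_labels.sum(axis=1) >= 3
    means = stacked.mean(axis=1)
    return votes.astype(int), (means >= 0.5).astype(int), means


def outer_cv(train: DescriptorTable, specs: Sequence[LearnerSpec],
             n_folds: int = 5, n_iterations: int = 50, seed: int = 0,
             inner_repeats: int = 5, prefit_preprocessing: bool = False,
             constant_threshold: float = DEFAULT_CONSTANT_FRACTION,
             entropy_cutoff: float = DEFAULT_ENTROPY_CUTOFF,
             entropy_bins: int = DEFAULT_N_BINS,
             collect_records: bool = True,
             ad_space: str = "scaled") -> CVResult:
    """Repeated outer k-fold cross-validation with nested tuning.

    Every compound is predicted exactly once per iteration; per-iteration
    metrics are computed on the predictions pooled over the ``n_folds``
    held-out folds. Iteration seeds derive deterministically from the
    master seed.
    """
    y_all = train.label_array()
    names = [s.algorithm for s in specs]
    if len(set(names)) != len(names):
        raise ValueError("duplicate learner algorithms in specs")
    with_consensus = len(specs) == N_MEMBERS
    model_names = list(names)
    if with_consensus:
        model_names += [CONSENSUS_VOTE, CONSENSUS_MEANPROB]
    metrics: dict[str, list[MetricsReport]] = {m: [] for m in model_names}
    records: dict[str, list[PredictionRecord]] = {m: [] for m in model_names}

    pre_table = None
    if prefit_preprocessing:
        pre_f, _ = apply_filters(train, constant_threshold, entropy_cutoff, entropy_bins)
        pre_table = apply_scaler(pre_f, fit_scaler(pre_f))

    for it in range(n_iterations):
        rng = np.random.default_rng([seed, it])
        folds = draw_folds(y_all, n_folds, rng)
        probs = {name: np.full(train.n_compounds, np.nan) for name in names}
        dists = np.zeros(train.n_compounds)
        for f in range(n_folds):
            tr_idx = np.flatnonzero(folds != f)
            te_idx = np.flatnonzero(folds == f)
            if prefit_preprocessing:
                tr_s = pre_table.select_rows(tr_idx)
                te_s = pre_table.select_rows(te_idx)
            else:
                tr_s, te_s, _, _ = _preprocess_split(
                    train.select_rows(tr_idx), train.select_rows(te_idx),
                    constant_threshold, entropy_cutoff, entropy_bins)
            if collect_records:
                box_table = tr_s if ad_space == "scaled" else train.select_rows(tr_idx)
                probe = te_s if ad_space == "scaled" else train.select_rows(te_idx)
                dists[te_idx] = ad_distances(probe, fit_ad(box_table))
            for spec in specs:
                sub = int(rng.integers(2**31))
                tuned = inner_tune(tr_s, spec, n_folds, inner_repeats, seed=sub)
                probs[spec.algorithm][te_idx] = tuned.predict_probability(te_s.values)

        preds = {name: (probs[name] >= 0.5).astype(int) for name in names}
        mean_probs = None
        if with_consensus:
            vote, meanlab, mean_probs = _consensus_rows(probs, names)
            preds[CONSENSUS_VOTE] = vote
            preds[CONSENSUS_MEANPROB] = meanlab
        for model, pred in preds.items():
            metrics[model].append(
                compute_metrics(ConfusionCounts.from_predictions(y_all, pred)))
        if collect_records:
            for name in names:
                records[name].extend(make_records(
                    train.compound_ids, y_all, probs[name], dists))
            if with_consensus:
                # consensus confidence derives from the mean member probability
                records[CONSENSUS_MEANPROB].extend(make_records(
                    train.compound_ids, y_all, mean_probs, dists))
                vote_recs = make_records(train.compound_ids, y_all, mean_probs, dists)
                for rec, v in zip(vote_recs, preds[CONSENSUS_VOTE]):
                    rec.predicted_label = "binder" if v else "nonbinder"
                records[CONSENSUS_VOTE].extend(vote_recs)
    return CVResult(metrics, records, n_iterations)


def external_validate(train: DescriptorTable, external: DescriptorTable,
                      specs: Sequence[LearnerSpec], seed: int = 0,
                      n_folds: int = 5, inner_repeats: int = 5,
                      constant_threshold: float = DEFAULT_CONSTANT_FRACTION,
                      entropy_cutoff: float = DEFAULT_ENTROPY_CUTOFF,
                      entropy_bins: int = DEFAULT_N_BINS,
                      ad_space: str = "scaled") -> ExternalResult:
    """Tune on the whole training set, then predict the external table."""
    if external.n_compounds == 0:
        raise ValueError("external validation table is empty")
    names = [s.algorithm for s in specs]
    train_s, ext_s, report, _ = _preprocess_split(
        train, external, constant_threshold, entropy_cutoff, entropy_bins)
    if ad_space == "scaled":
        bounds = fit_ad(train_s)
        dists = ad_distances(ext_s, bounds)
    else:
        train_f = apply_retained(train, report.retained)
        bounds = fit_ad(train_f)
        dists = ad_distances(apply_retained(external, report.retained), bounds)

    y_ext = external.label_array()
    rng = np.random.default_rng([seed, 999])
    tuned: dict[str, TunedLearner] = {}
    probs: dict[str, np.ndarray] = {}
    for spec in specs:
        sub = int(rng.integers(2**31))
        tuned[spec.algorithm] = inner_tune(train_s, spec, n_folds, inner_repeats, seed=sub)
        probs[spec.algorithm] = tuned[spec.algorithm].predict_probability(ext_s.values)

    metrics: dict[str, MetricsReport] = {}
    records: dict[str, list[PredictionRecord]] = {}
    preds = {name: (probs[name] >= 0.5).astype(int) for name in names}
    if len(specs) == N_MEMBERS:
        vote, meanlab, means = _consensus_rows(probs, names)
        preds[CONSENSUS_VOTE] = vote
        preds[CONSENSUS_MEANPROB] = meanlab
        records[CONSENSUS_MEANPROB] = make_records(external.compound_ids, y_ext, means, dists)
        vote_recs = make_records(external.compound_ids, y_ext, means, dists)
        for rec, v in zip(vote_recs, vote):
            rec.predicted_label = "binder" if v else "nonbinder"
        records[CONSENSUS_VOTE] = vote_recs
    for name in names:
        records[name] = make_records(external.compound_ids, y_ext, probs[name], dists)
    for model, pred in preds.items():
        metrics[model] = compute_metrics(ConfusionCounts.from_predictions(y_ext, pred))
    return ExternalResult(metrics, records, tuned)


def concordance_table(labels_a: Sequence[str], labels_b: Sequence[str]) -> pd.DataFrame:
    """2x2 cross-tabulation of two labelings of the same compound set.

    Rows are labeling A, columns labeling B; the diagonal counts agreements
    per class (e.g., traditional-assay vs qHTS-assay calls).
    """
    if len(labels_a) != len(labels_b):
        raise ValueError("labelings cover different compound sets")
    classes = ["binder", "nonbinder"]
    table = pd.DataFrame(0, index=classes, columns=classes)
    for a, b in zip(labels_a, labels_b):
        if a not in classes or b not in classes:
            raise ValueError(f"unknown label in pair ({a!r}, {b!r})")
        table.loc[a, b] += 1
    return table
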