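# Methods

## Problem and model

The package treats MOR binding prediction as binary classification on
continuous 2D molecular descriptors (Mold2-style tables; descriptor
computation itself is upstream of this package). Binders are the positive
class. The pipeline is deliberately conventional QSAR practice — the value
is in the *combination* and in its reliability analysis: entropy-based
descriptor triage, five heterogeneous learners tuned by nested repeated
cross-validation on MCC, consensus combination, and two per-compound
reliability annotations (prediction confidence and bounding-box
applicability domain).

Assumptions worth stating explicitly:

* labels are binary and trusted per source; conflicting labels for the same
  canonical structure are treated as irreconcilable and removed rather than
  arbitrated;
* descriptors are continuous and complete — missing values are rejected at
  ingestion, not imputed;
* the training and external sets may come from different assay families, so
  external performance is interpreted as generalization across both
  chemistry and measurement process.

## Data curation rules

Database-style records: a quantitative binding value (IC50/Ki/Kd, any
magnitude) marks a binder; otherwise qualitative "active"/"positive" →
binder, "inactive"/"negative" → non-binder, "not determined"/
"inconclusive"/absent/unrecognized → excluded. When a quantitative value
coexists with a conflicting qualitative call, the quantitative value wins;
this is a package rule for an ambiguous case, flagged here rather than
silently assumed. qHTS records: non-binder only if inactive in both the
agonist and antagonist assays; active in at least one assay → binder
(including active in both); a missing outcome excludes the record.

Deduplication keys on RDKit canonical SMILES (no salt stripping, charge or
tautomer standardization — the curation contract is canonicalization only).
"Keep one" keeps the first occurrence in input order, which makes outputs
deterministic and testable. Dataset assembly removes qHTS compounds whose
canonical SMILES already occurs in the database set, then transfers a
seeded random sample of qHTS non-binders (default 1,727) into training.

## Preprocessing

* Near-constant filter: a descriptor is dropped iff its single most
  frequent value covers **strictly more than** 90% of training compounds.
* Shannon entropy: the training range [min, max] of each surviving
  descriptor is split into 20 equal-width bins, half-open [lo, hi) with the
  last bin closed (every value is counted exactly once; the maximum lands
  in the top bin). H = −Σ pᵢ log₂ pᵢ in bits; a zero-range descriptor gets
  H = 0 (single occupied group). Descriptors with H < 2.0 bits are dropped;
  H = 2.0 exactly is retained. Entropy is computed on raw values; the
  equal-width binning makes it invariant to the affine rescale that
  follows, so the ordering of the two steps relative to scaling is inert.
* Scaling: V = (V₀ − Min_train)/(Max_train − Min_train) per descriptor,
  bounds from training rows only. Degenerate columns (Max = Min) map to 0
  instead of erroring, because externally supplied tables may legitimately
  contain columns that are constant in training. External values may fall
  outside [0, 1]; the AD analysis depends on exactly that.

## Learners and tuning

Default grids (the workflow's reference configuration):

| family | tuned | fixed |
|---|---|---|
| rf | n_estimators {100, 200}, min_samples_leaf {10, 20}, max_chemical {1000, 2000} | max_chemical interpreted as max_samples (see below) |
| knn | n_neighbors {3, 5, 7}, weights {uniform, distance} | — |
| svm | C {0.1, 1, 10} | linear kernel; sigmoid (Platt) probability calibration on internal folds |
| mlp | alpha {1e-4, 0.1}, hidden_layer_sizes {100, 300} (single hidden layer) | scikit-learn defaults |
| lstm | effective epoch count, selected at checkpoints | 4 recurrent layers, hidden size 200, batch 32, learning rate 1e-4, 5,000-epoch budget, 500-epoch checkpoints |

Untuned settings are toolkit defaults. Two knobs required interpretation:

* **max_chemical** (rf) is not a standard scikit-learn parameter; its
  candidate values (1,000 and 2,000) look like compound counts, so the
  default reading is `max_samples` (bootstrap size per tree), clipped to
  the actual training size when smaller. A `max_features` reading is
  selectable via `max_chemical_mode` for users who read it as a feature
  cap.
* **LSTM input**: a descriptor vector has no sequence structure. The vector
  is zero-padded and reshaped into `seq_len` equal-width chunks (default 8)
  fed as a sequence to the recurrent stack; the top layer's final hidden
  state feeds a sigmoid readout. This is an explicit convention, not a
  claim about how recurrent models "should" see descriptors. The LSTM is
  implemented in numpy (forward, backpropagation through time, Adam) and
  its gradients are verified against numerical differentiation in the test
  suite. Epoch selection keeps the checkpoint with the best training
  accuracy (ties broken by lower loss), mirroring budget-with-checkpoints
  training.

Inner tuning: for each grid point, `inner_repeats` (default 5) independent
random 5-fold partitions are evaluated; within a repeat the held-out
predictions of the five folds are **pooled into one MCC** (not averaged per
fold), repeats are averaged, and the best mean wins with ties broken by
grid order. The same partitions are reused across grid points, which makes
the comparison paired and lets tests replay the loop independently from
the recorded diagnostics. The winner is refitted on the full split. A
single-point grid skips the inner loop entirely.

Individual models classify at probability ≥ 0.5, consistent with the
mean-probability consensus rule. Consensus: majority vote (binder iff ≥ 3
of 5) and mean probability (binder iff ≥ 0.5 — the boundary case is a
binder by definition).

## Evaluation protocol

Outer loop: `n_iterations` (default 50) random 5-fold partitions of the
training set; each fold held out once; per-iteration metrics computed on
predictions pooled over the five folds. Folds are equal-or-close in size
(difference ≤ 1) and redrawn if any fold lacks a class. Iteration seeds
derive deterministically from the master seed, so runs are reproducible
bit-for-bit.

By default the preprocessing chain (both filters and the scaler) is
re-fitted inside each outer training split, so no information from the
held-out fold can leak into descriptor selection or scaling. A
`prefit_preprocessing` switch instead fits preprocessing once on the full
training table before splitting, reproducing the common published protocol
of filtering before cross-validating; the two modes are both tested, and
the default is the leakage-free one.

External validation tunes on the whole training set (same inner protocol),
applies the training-fitted filters/scaler verbatim, and emits per-compound
prediction records for the reliability analyses.

MCC with a zero denominator (degenerate confusion row/column) is reported
as 0 with an explicit flag.

## Reliability analyses

Confidence = |prob − 0.5| / 0.5. The transform is sometimes written
without the absolute value, which would be negative for non-binder
predictions; the absolute value realizes the intended [0, 1] range and
makes confidence symmetric between the two predicted classes. Predictions are allocated to ten bins of width 0.1
(last bin closed); per-bin metrics are suppressed below `min_count`
(default 5) predictions, because metrics on 1–3 predictions are not
statistically meaningful. The consensus model's confidence uses the mean
member probability (a majority vote yields no probability).

AD = per-descriptor min/max box of the training compounds, computed on
scaled descriptors by default so that the Euclidean distance
√(Σ dᵢ²) adds commensurable per-descriptor terms; a raw-value mode is
selectable (`ad_space="raw"`). dᵢ is the distance to the nearer bound, 0
inside. Distance 0 ⇔ inside the AD. Inside/outside groups are compared on
the same metrics, with the same `min_count` suppression.

## Synthetic data: what it emulates, and what it does not

The generator plants the exact structures the pipeline's claims rest on:
class-informative columns (unit-variance normals, mean shift =
`effect_size`), class-independent noise, near-constant columns (modal value
on 95% of rows — strictly above the 90% removal threshold), and
low-entropy columns (all mass on three spike values, hence at most three
occupied bins and H ≤ log₂3 < 2 bits, whatever the sample). Spike and
modal counts are set by exact composition, not sampling, so filter recovery
is deterministic. Class imbalance defaults to ~5:1 binders:non-binders,
mirroring curated binding datasets where binders dominate.

The external split adds a covariate shift (`shift_magnitude`, default 0.5)
on informative and noise columns and flips `label_flip_rate` (default
0.15) of external labels, emulating qHTS-versus-traditional-assay
discordance. Non-planted external rows are clipped into the training box so
the out-of-AD set is exactly the planted one; the planted out-of-domain
rows (default 40, class-balanced) have their informative signal mirrored
into the opposite class and noise descriptors pushed beyond the box —
emulating structurally alien chemistry that models mispredict.

What passing tests on this generator show: the filters recover planted
structure exactly; every learner family detects a standardized effect of
1.0 with CV MCC well above chance; confidence is informative (accuracy
rises with bin); AD separates reliable from unreliable predictions; and
shifted, discordant external data degrades all models. What they do not
show: performance on real Mold2 marginals, inter-descriptor correlation,
activity cliffs, or scaffold-clustered chemistry — real descriptor tables
are correlated and heavy-tailed in ways this generator intentionally does
not mimic.

## Problem sizes and presets

The desk-scale preset (`desk_scale_config`) is the package's reference
end-to-end configuration: 2,000 compounds × 100 descriptors (10
informative, 78 noise, 5 constant, 7 low-entropy), 5 outer iterations, 2
inner repeats, reduced grids (kNN keeps a 2-point grid so tuning is
exercised; the others run their reference single point), and a shrunk LSTM
(1 layer, hidden 16, 60 epochs, 20-epoch checkpoints, sequence length 4).
These sizes keep a full nested run at minutes on a single CPU while
preserving every structural property of the full protocol (nesting,
pooling, consensus, reliability analyses). The full-size defaults
(50 iterations, full grids, 4-layer LSTM) remain the `RunConfig` defaults
for real studies.

## Known limitations

* No chemical standardization beyond canonicalization (salts, tautomers,
  charges); compounds differing only by salt form are distinct structures
  here.
* The bounding-box AD ignores correlation between descriptors; a compound
  can be inside every marginal range yet far from the training manifold.
  Box AD only is implemented, by design.
* The numpy LSTM is CPU-oriented and single-threaded; at the full 5,000
  epoch × hidden-200 × 4-layer setting it is slow, and it exists to make
  the recurrent family runnable and testable, not to be fast.
* Per-bin confidence metrics and outside-AD metrics can rest on few
  predictions; the `min_count` suppression reports counts instead of
  unstable metrics, but interpretation should still respect the group
  sizes.
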