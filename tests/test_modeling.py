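"""Learner construction, inner tuning, consensus rules, and the LSTM."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from sklearn.metrics import matthews_corrcoef
from sklearn.neighbors import KNeighborsClassifier

from conftest import make_table, separable_table
from morqsar.modeling import (LearnerSpec, LSTMClassifier, build_learner,
                              consensus_mean_probability, consensus_vote,
                              inner_tune)

B, N = "binder", "nonbinder"

FAST_SPECS = {
    "rf": LearnerSpec("rf", {"n_estimators": [30], "min_samples_leaf": [2]}),
    "knn": LearnerSpec("knn", {"n_neighbors": [3], "weights": ["uniform"]}),
    "svm": LearnerSpec("svm", {"C": [1]}, {"kernel": "linear"}),
    "mlp": LearnerSpec("mlp", {"alpha": [0.0001], "hidden_layer_sizes": [30]},
                       {"max_iter": 300}),
    "lstm": LearnerSpec("lstm", {}, {"n_layers": 1, "hidden_size": 8,
                                     "batch_size": 32, "learning_rate": 0.005,
                                     "max_epochs": 40, "checkpoint_every": 10,
                                     "seq_len": 2}),
}


class TestBuildLearner:
    def test_valid_rf_and_knn_handles(self):
        spec = LearnerSpec("rf", {"n_estimators": [100, 200],
                                  "min_samples_leaf": [10, 20],
                                  "max_chemical": [1000, 2000]},
                           {"max_chemical_mode": "max_samples"})
        handle = build_learner(spec, {"n_estimators": 100, "min_samples_leaf": 10,
                                      "max_chemical": 1000})
        assert handle.algorithm == "rf"
        knn = build_learner(LearnerSpec("knn", {"n_neighbors": [3, 5, 7],
                                                "weights": ["uniform", "distance"]}),
                            {"n_neighbors": 3, "weights": "uniform"})
        assert knn.estimator.get_params()["n_neighbors"] == 3

    def test_off_grid_value_is_configuration_error(self):
        spec = LearnerSpec("svm", {"C": [0.1, 1, 10]})
        with pytest.raises(ValueError, match="not in the grid"):
            build_learner(spec, {"C": 5})

    def test_unknown_hyperparameter_is_fatal(self):
        with pytest.raises(ValueError, match="unknown hyperparameter"):
            build_learner(LearnerSpec("knn", {"n_neighbors": [3]}),
                          {"n_neighbors": 3, "bogus": 1})

    def test_unknown_algorithm_is_fatal(self):
        with pytest.raises(ValueError, match="unknown algorithm"):
            LearnerSpec("gbm", {"x": [1]})

    def test_missing_grid_key_is_fatal(self):
        with pytest.raises(ValueError, match="not supplied"):
            build_learner(LearnerSpec("knn", {"n_neighbors": [3]}), {})

    def test_rf_max_chemical_as_max_features(self):
        spec = LearnerSpec("rf", {"n_estimators": [10], "min_samples_leaf": [1],
                                  "max_chemical": [2]},
                           {"max_chemical_mode": "max_features"})
        handle = build_learner(spec, {"n_estimators": 10, "min_samples_leaf": 1,
                                      "max_chemical": 2})
        assert handle.estimator.get_params()["max_features"] == 2


class TestProbabilityContract:
    @pytest.mark.parametrize("name", list(FAST_SPECS))
    def test_probabilities_in_unit_interval(self, name, rng):
        table = separable_table(n_per_class=30, n_desc=6, gap=1.0, seed=4)
        handle = build_learner(FAST_SPECS[name], FAST_SPECS[name].grid_points()[0],
                               seed=0)
        handle.fit(table.values, table.label_array())
        probe = rng.normal(size=(40, 6)) * 3
        p = handle.predict_probability(probe)
        assert p.shape == (40,)
        assert np.all(p >= 0.0) and np.all(p <= 1.0)

    @pytest.mark.parametrize("name", list(FAST_SPECS))
    def test_resubstitution_on_separable_data_is_perfect(self, name):
        """Sanity floor: every family separates well-separated classes."""
        table = separable_table(n_per_class=60, n_desc=10, gap=4.0, seed=1)
        y = table.label_array()
        handle = build_learner(FAST_SPECS[name], FAST_SPECS[name].grid_points()[0],
                               seed=0)
        handle.fit(table.values, y)
        assert matthews_corrcoef(y, handle.predict_label(table.values)) == 1.0


class TestInnerTune:
    def test_single_grid_point_reduces_to_refit(self):
        table = separable_table(30, 5, 3.0, seed=2)
        tuned = inner_tune(table, FAST_SPECS["knn"], seed=0)
        assert tuned.selected == {"n_neighbors": 3, "weights": "uniform"}
        assert tuned.diagnostics is None
        assert np.all(tuned.predict_probability(table.values) >= 0)

    def test_seed_determinism(self):
        table = separable_table(25, 4, 1.0, seed=3)
        spec = LearnerSpec("knn", {"n_neighbors": [3, 5], "weights": ["uniform"]})
        t1 = inner_tune(table, spec, n_folds=3, n_repeats=2, seed=9)
        t2 = inner_tune(table, spec, n_folds=3, n_repeats=2, seed=9)
        assert t1.selected == t2.selected
        assert t1.tuning_score == t2.tuning_score
        assert t1.diagnostics.grid_scores == t2.diagnostics.grid_scores

    def test_single_class_training_is_fatal(self):
        table = make_table(np.random.default_rng(0).normal(size=(10, 3)),
                           labels=np.array([B] * 10, dtype=object))
        with pytest.raises(ValueError, match="both classes"):
            inner_tune(table, FAST_SPECS["knn"])

    def _triplet_blobs(self, n_clusters=20, seed=0):
        """Tight same-class triplets: 3-NN is perfect, 7-NN mixes clusters."""
        rng = np.random.default_rng(seed)
        centers = rng.uniform(-10, 10, size=(n_clusters, 2))
        X, labels = [], []
        for k, c in enumerate(centers):
            X.append(c + rng.normal(0, 0.01, size=(3, 2)))
            labels += [B if k % 2 == 0 else N] * 3
        return make_table(np.vstack(X), labels=np.array(labels, dtype=object))

    def test_blobs_select_small_k_and_scores_match_bruteforce(self):
        """The tuner's grid scores must agree with an independent replay of
        its partitions, and k=3 must beat k=7 on triplet-structured blobs."""
        table = self._triplet_blobs()
        spec = LearnerSpec("knn", {"n_neighbors": [3, 7], "weights": ["uniform"]})
        tuned = inner_tune(table, spec, n_folds=5, n_repeats=3, seed=21)
        assert tuned.selected["n_neighbors"] == 3

        X, y = table.values, table.label_array()
        diag = tuned.diagnostics
        for gi, gp in enumerate(diag.grid_points):
            repeat_mccs = []
            for folds in diag.partitions:
                pred = np.empty_like(y)
                for f in np.unique(folds):
                    est = KNeighborsClassifier(**gp)
                    est.fit(X[folds != f], y[folds != f])
                    pred[folds == f] = est.predict(X[folds == f])
                repeat_mccs.append(matthews_corrcoef(y, pred))
            assert diag.grid_scores[gi] == pytest.approx(np.mean(repeat_mccs),
                                                         abs=1e-12)


class TestConsensus:
    @pytest.mark.parametrize("labels, expected", [
        ([B, B, B, N, N], B),
        ([B, B, N, N, N], N),
        ([N, N, N, N, N], N),
        ([B] * 5, B),
    ])
    def test_majority_vote(self, labels, expected):
        assert consensus_vote(labels) == expected

    def test_vote_arity_checked(self):
        with pytest.raises(ValueError, match="5 member"):
            consensus_vote([B, N])

    def test_mean_probability_examples(self):
        mean, label = consensus_mean_probability([0.9, 0.9, 0.9, 0.1, 0.1])
        assert mean == pytest.approx(0.58)
        assert label == B
        assert consensus_mean_probability([0.5] * 5) == (0.5, B)  # boundary: >= 0.5
        assert consensus_mean_probability([0.0] * 5) == (0.0, N)

    def test_out_of_range_probability_fatal(self):
        with pytest.raises(ValueError):
            consensus_mean_probability([0.2, 0.3, 0.4, 0.5, 1.2])

    @settings(max_examples=80, deadline=None)
    @given(st.lists(st.floats(0, 1), min_size=5, max_size=5),
           st.booleans())
    def test_unanimous_members_agree_across_combiners(self, probs, high):
        probs = [0.5 + p / 2 if high else p * 0.499 for p in probs]
        labels = [B if p >= 0.5 else N for p in probs]
        if len(set(labels)) == 1:
            _, mean_label = consensus_mean_probability(probs)
            assert consensus_vote(labels) == mean_label


class TestLSTM:
    def test_analytic_gradients_match_numerical(self):
        clf = LSTMClassifier(n_layers=2, hidden_size=3, seq_len=3, seed=1)
        rng = np.random.default_rng(0)
        X = rng.normal(size=(5, 7))
        y = rng.integers(0, 2, 5).astype(float)
        seq = clf._shape_input(X)
        params = clf._init_params(seq.shape[2], rng)
        probs, cache = clf._forward(seq, params, keep_cache=True)
        grads = clf._backward(probs, y, cache, params)
        eps = 1e-6
        for key in params:
            flat, gflat = params[key].reshape(-1), grads[key].reshape(-1)
            for idx in range(0, flat.size, max(1, flat.size // 4)):
                orig = flat[idx]
                flat[idx] = orig + eps
                up = clf._bce(clf._forward(seq, params), y)
                flat[idx] = orig - eps
                down = clf._bce(clf._forward(seq, params), y)
                flat[idx] = orig
                numeric = (up - down) / (2 * eps)
                assert gflat[idx] == pytest.approx(numeric, rel=1e-3, abs=1e-8)

    def test_input_chunking_pads_to_sequence(self):
        clf = LSTMClassifier(seq_len=4)
        seq = clf._shape_input(np.ones((2, 10)))
        assert seq.shape == (2, 4, 3)  # ceil(10/4) = 3 with zero padding
        assert seq[0, 3, 2] == 0.0

    def test_unfitted_predict_raises(self):
        with pytest.raises(RuntimeError):
            LSTMClassifier().predict_proba_binder(np.zeros((1, 4)))
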