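"""Learner families, nested hyperparameter tuning, and consensus combiners.

Five binary classifiers predict the probability that a compound binds the
receptor: random forest, k-nearest neighbors, linear-kernel SVM,
multi-layer perceptron (scikit-learn), and a recurrent LSTM classifier
implemented in numpy. Hyperparameters are selected by repeated inner 5-fold
cross-validation: for each candidate grid point the held-out predictions of
each repeat are pooled into one Matthews correlation coefficient, the
repeat MCCs are averaged, and the grid point with the highest mean wins
(ties broken by grid order). The winning settings are refitted on the full
training split.

Two consensus combiners operate on the five member models: majority vote
(binder iff >= 3 of 5 members say binder) and mean predicted probability
(binder iff the mean binder probability >= 0.5).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Any, Sequence

import numpy as np
from sklearn.calibration import CalibratedClassifierCV
from sklearn.ensemble import RandomForestClassifier
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC

from .preprocessing import DescriptorTable

log = logging.getLogger(__name__)

ALGORITHMS = ("rf", "knn", "svm", "mlp", "lstm")

#: reference hyperparameter grids of the workflow, in grid order
REFERENCE_GRIDS: dict[str, dict[str, list]] = {
    "rf": {"n_estimators": [100, 200], "min_samples_leaf": [10, 20],
           "max_chemical": [1000, 2000]},
    "knn": {"n_neighbors": [3, 5, 7], "weights": ["uniform", "distance"]},
    "svm": {"C": [0.1, 1, 10]},
    "mlp": {"alpha": [0.0001, 0.1], "hidden_layer_sizes": [100, 300]},
    "lstm": {},  # tuned internally over the epoch schedule, not over a grid
}

#: reference non-tuned settings (toolkit defaults elsewhere)
REFERENCE_FIXED: dict[str, dict[str, Any]] = {
    "rf": {"max_chemical_mode": "max_samples"},
    "knn": {},
    "svm": {"kernel": "linear"},
    "mlp": {},
    "lstm": {"n_layers": 4, "hidden_size": 200, "batch_size": 32,
             "learning_rate": 0.0001, "max_epochs": 5000,
             "checkpoint_every": 500, "seq_len": 8},
}


@dataclass
class LearnerSpec:
    """One algorithm family with its candidate grid and fixed settings."""

    algorithm: str
    grid: dict[str, list] = field(default_factory=dict)
    fixed: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.algorithm not in ALGORITHMS:
            raise ValueError(f"unknown algorithm {self.algorithm!r}; expected one of {ALGORITHMS}")

    def grid_points(self) -> list[dict[str, Any]]:
        """Cross-product of the grid in insertion order; [{}] if grid empty."""
        if not self.grid:
            return [{}]
        keys = list(self.grid)
        return [dict(zip(keys, combo)) for combo in itertools.product(*self.grid.values())]


def reference_learner_specs() -> list[LearnerSpec]:
    """The five learner families with the reference grids and fixed settings."""
    return [LearnerSpec(a, {k: list(v) for k, v in REFERENCE_GRIDS[a].items()},
                        dict(REFERENCE_FIXED[a])) for a in ALGORITHMS]


# ---------------------------------------------------------------------------
# numpy LSTM classifier
# ---------------------------------------------------------------------------

def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


class LSTMClassifier:
    """Stacked-LSTM binary classifier on chunked descriptor vectors.

    A descriptor vector has no sequential structure, so it is zero-padded
    and reshaped into ``seq_len`` equal-width chunks which are fed to the
    recurrent stack as a sequence; the top layer's final hidden state feeds
    a sigmoid readout. Trained with Adam on binary cross-entropy; every
    ``checkpoint_every`` epochs the training loss/accuracy are evaluated and
    the best checkpoint's weights are restored at the end, which selects the
    effective epoch count on the training signal.
    """

    def __init__(self, n_layers: int = 4, hidden_size: int = 200,
                 batch_size: int = 32, learning_rate: float = 1e-4,
                 max_epochs: int = 5000, checkpoint_every: int = 500,
                 seq_len: int = 8, seed: int = 0) -> None:
        self.n_layers = int(n_layers)
        self.hidden_size = int(hidden_size)
        self.batch_size = int(batch_size)
        self.learning_rate = float(learning_rate)
        self.max_epochs = int(max_epochs)
        self.checkpoint_every = int(checkpoint_every)
        self.seq_len = int(seq_len)
        self.seed = int(seed)
        self.params_: dict[str, np.ndarray] | None = None
        self._chunk: int | None = None

    # -- parameter handling -------------------------------------------------

    def _init_params(self, chunk: int, rng: np.random.Generator) -> dict[str, np.ndarray]:
        H = self.hidden_size
        params: dict[str, np.ndarray] = {}
        for layer in range(self.n_layers):
            d_in = chunk if layer == 0 else H
            scale_x = 1.0 / np.sqrt(d_in)
            scale_h = 1.0 / np.sqrt(H)
            params[f"Wx{layer}"] = rng.normal(0.0, scale_x, size=(d_in, 4 * H))
            params[f"Wh{layer}"] = rng.normal(0.0, scale_h, size=(H, 4 * H))
            b = np.zeros(4 * H)
            b[H:2 * H] = 1.0  # forget-gate bias: remember by default
            params[f"b{layer}"] = b
        params["w_out"] = rng.normal(0.0, 1.0 / np.sqrt(H), size=H)
        params["b_out"] = np.zeros(1)
        return params

    def _shape_input(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        n, d = X.shape
        chunk = -(-d // self.seq_len)  # ceil
        padded = np.zeros((n, self.seq_len * chunk))
        padded[:, :d] = X
        return padded.reshape(n, self.seq_len, chunk)

    # -- forward / backward -------------------------------------------------

    def _forward(self, seq: np.ndarray, params: dict[str, np.ndarray],
                 keep_cache: bool = False):
        """Run the stack; returns binder probabilities (and a cache for BPTT)."""
        n, T, _ = seq.shape
        H = self.hidden_size
        cache: list[list[dict[str, np.ndarray]]] = []
        x = seq
        last_h = None
        for layer in range(self.n_layers):
            Wx, Wh, b = params[f"Wx{layer}"], params[f"Wh{layer}"], params[f"b{layer}"]
            h = np.zeros((n, H))
            c = np.zeros((n, H))
            outs = np.empty((n, T, H))
            steps: list[dict[str, np.ndarray]] = []
            for t in range(T):
                xt = x[:, t, :]
                z = xt @ Wx + h @ Wh + b
                i = _sigmoid(z[:, :H])
                f = _sigmoid(z[:, H:2 * H])
                g = np.tanh(z[:, 2 * H:3 * H])
                o = _sigmoid(z[:, 3 * H:])
                c_new = f * c + i * g
                tanh_c = np.tanh(c_new)
                h_new = o * tanh_c
                if keep_cache:
                    steps.append({"x": xt, "h_prev": h, "c_prev": c, "i": i,
                                  "f": f, "g": g, "o": o, "tanh_c": tanh_c})
                outs[:, t, :] = h_new
                h, c = h_new, c_new
            if keep_cache:
                cache.append(steps)
            x = outs
            last_h = h
        logits = last_h @ params["w_out"] + params["b_out"][0]
        probs = _sigmoid(logits)
        if keep_cache:
            return probs, {"layers": cache, "last_h": last_h, "seq": seq}
        return probs

    def _backward(self, probs: np.ndarray, y: np.ndarray, cache: dict,
                  params: dict[str, np.ndarray]) -> dict[str, np.ndarray]:
        """Gradient of mean binary cross-entropy w.r.t. every parameter."""
        n = y.shape[0]
        H = self.hidden_size
        T = cache["seq"].shape[1]
        grads = {k: np.zeros_like(v) for k, v in params.items()}
        dlogit = (probs - y) / n  # d(mean BCE)/dlogit for sigmoid output
        grads["w_out"] = cache["last_h"].T @ dlogit
        grads["b_out"] = np.array([dlogit.sum()])

        # gradient flowing into each layer's output sequence
        d_out = np.zeros((n, T, H))
        d_out[:, T - 1, :] = np.outer(dlogit, params["w_out"])
        for layer in range(self.n_layers - 1, -1, -1):
            Wx, Wh = params[f"Wx{layer}"], params[f"Wh{layer}"]
            steps = cache["layers"][layer]
            d_in = np.zeros((n, T, Wx.shape[0]))
            dh_next = np.zeros((n, H))
            dc_next = np.zeros((n, H))
            for t in range(T - 1, -1, -1):
                s = steps[t]
                dh = d_out[:, t, :] + dh_next
                do = dh * s["tanh_c"]
                dc = dh * s["o"] * (1.0 - s["tanh_c"] ** 2) + dc_next
                di = dc * s["g"]
                df = dc * s["c_prev"]
                dg = dc * s["i"]
                dc_next = dc * s["f"]
                dz = np.concatenate([
                    di * s["i"] * (1.0 - s["i"]),
                    df * s["f"] * (1.0 - s["f"]),
                    dg * (1.0 - s["g"] ** 2),
                    do * s["o"] * (1.0 - s["o"]),
                ], axis=1)
                grads[f"Wx{layer}"] += s["x"].T @ dz
                grads[f"Wh{layer}"] += s["h_prev"].T @ dz
                grads[f"b{layer}"] += dz.sum(axis=0)
                d_in[:, t, :] = dz @ Wx.T
                dh_next = dz @ Wh.T
            d_out = d_in  # becomes the output-gradient of the layer below
        return grads

    @staticmethod
    def _bce(probs: np.ndarray, y: np.ndarray) -> float:
        eps = 1e-12
        return float(-np.mean(y * np.log(probs + eps) + (1 - y) * np.log(1 - probs + eps)))

    # -- public API ----------------------------------------------------------

    def fit(self, X: np.ndarray, y: np.ndarray) -> "LSTMClassifier":
        rng = np.random.default_rng(self.seed)
        seq = self._shape_input(X)
        self._chunk = seq.shape[2]
        y = np.asarray(y, dtype=float)
        params = self._init_params(self._chunk, rng)
        m = {k: np.zeros_like(v) for k, v in params.items()}
        v = {k: np.zeros_like(vv) for k, vv in params.items()}
        beta1, beta2, eps = 0.9, 0.999, 1e-8
        step = 0
        n = seq.shape[0]
        best: tuple[float, float, dict[str, np.ndarray]] | None = None  # (-acc, loss, params)
        for epoch in range(1, self.max_epochs + 1):
            order = rng.permutation(n)
            for start in range(0, n, self.batch_size):
                idx = order[start:start + self.batch_size]
                probs, cache = self._forward(seq[idx], params, keep_cache=True)
                grads = self._backward(probs, y[idx], cache, params)
                step += 1
                for k in params:
                    m[k] = beta1 * m[k] + (1 - beta1) * grads[k]
                    v[k] = beta2 * v[k] + (1 - beta2) * grads[k] ** 2
                    mhat = m[k] / (1 - beta1 ** step)
                    vhat = v[k] / (1 - beta2 ** step)
                    params[k] -= self.learning_rate * mhat / (np.sqrt(vhat) + eps)
            if epoch % self.checkpoint_every == 0 or epoch == self.max_epochs:
                probs = self._forward(seq, params)
                acc = float(np.mean((probs >= 0.5) == (y == 1)))
                loss = self._bce(probs, y)
                key = (-acc, loss)
                if best is None or key < (best[0], best[1]):
                    best = (-acc, loss, {k: p.copy() for k, p in params.items()})
        assert best is not None
        self.params_ = best[2]
        return self

    def predict_proba_binder(self, X: np.ndarray) -> np.ndarray:
        if self.params_ is None:
            raise RuntimeError("LSTMClassifier is not fitted")
        return np.clip(self._forward(self._shape_input(X), self.params_), 0.0, 1.0)


# ---------------------------------------------------------------------------
# learner handles
# ---------------------------------------------------------------------------

class LearnerHandle:
    """Uniform fit/predict_probability wrapper over the five families."""

    def __init__(self, algorithm: str, estimator: Any, rf_max_samples: int | None = None):
        self.algorithm = algorithm
        self.estimator = estimator
        self._rf_max_samples = rf_max_samples

    def fit(self, X: np.ndarray, y: np.ndarray) -> "LearnerHandle":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=int)
        if self.algorithm == "lstm":
            self.estimator.fit(X, y)
            return self
        if self._rf_max_samples is not None:
            # full-scale sample counts may exceed a small training split
            self.estimator.set_params(max_samples=min(self._rf_max_samples, X.shape[0]))
        if self.algorithm == "knn":
            k = self.estimator.get_params()["n_neighbors"]
            if k > X.shape[0]:
                self.estimator.set_params(n_neighbors=X.shape[0])
        self.estimator.fit(X, y)
        return self

    def predict_probability(self, X: np.ndarray) -> np.ndarray:
        """Probability of the binder class, in [0, 1], per row of X."""
        X = np.asarray(X, dtype=float)
        if self.algorithm == "lstm":
            return self.estimator.predict_proba_binder(X)
        proba = self.estimator.predict_proba(X)
        classes = list(self.estimator.classes_)
        if 1 not in classes:  # degenerate single-class fit
            return np.zeros(X.shape[0])
        return np.clip(proba[:, classes.index(1)], 0.0, 1.0)

    def predict_label(self, X: np.ndarray, threshold: float = 0.5) -> np.ndarray:
        return (self.predict_probability(X) >= threshold).astype(int)


def build_learner(spec: LearnerSpec, hyperparams: dict[str, Any],
                  seed: int = 0) -> LearnerHandle:
    """Instantiate an untrained learner for one grid point.

    ``hyperparams`` must cover every grid key with a value drawn from the
    grid; fixed settings may be overridden by name. Unknown names or
    off-grid values are configuration errors.
    """
    for key, value in hyperparams.items():
        if key in spec.grid:
            if value not in spec.grid[key]:
                raise ValueError(
                    f"{spec.algorithm}: value {value!r} for {key!r} is not in the grid "
                    f"{spec.grid[key]}")
        elif key not in spec.fixed:
            raise ValueError(f"{spec.algorithm}: unknown hyperparameter {key!r}")
    missing = [k for k in spec.grid if k not in hyperparams]
    if missing:
        raise ValueError(f"{spec.algorithm}: grid hyperparameter(s) {missing} not supplied")

    settings = {**spec.fixed, **hyperparams}
    alg = spec.algorithm
    if alg == "rf":
        mode = settings.pop("max_chemical_mode", "max_samples")
        max_chem = settings.pop("max_chemical", None)
        kwargs = dict(settings)
        rf_max_samples = None
        if max_chem is not None:
            if mode == "max_samples":
                rf_max_samples = int(max_chem)
            elif mode == "max_features":
                kwargs["max_features"] = int(max_chem)
            else:
                raise ValueError(f"rf: unknown max_chemical_mode {mode!r}")
        est = RandomForestClassifier(random_state=seed, **kwargs)
        return LearnerHandle("rf", est, rf_max_samples=rf_max_samples)
    if alg == "knn":
        return LearnerHandle("knn", KNeighborsClassifier(**settings))
    if alg == "svm":
        settings.setdefault("kernel", "linear")
        # sigmoid (Platt) calibration on internal training folds gives the
        # probability output the confidence analysis needs
        est = CalibratedClassifierCV(SVC(random_state=seed, **settings),
                                     method="sigmoid", ensemble=False)
        return LearnerHandle("svm", est)
    if alg == "mlp":
        if "hidden_layer_sizes" in settings and isinstance(settings["hidden_layer_sizes"], int):
            settings["hidden_layer_sizes"] = (settings["hidden_layer_sizes"],)
        return LearnerHandle("mlp", MLPClassifier(random_state=seed, **settings))
    if alg == "lstm":
        return LearnerHandle("lstm", LSTMClassifier(seed=seed, **settings))
    raise ValueError(f"unknown algorithm {alg!r}")


# ---------------------------------------------------------------------------
# inner tuning
# ---------------------------------------------------------------------------

@dataclass
class TuningDiagnostics:
    """Everything needed to replay the tuning loop independently."""

    partitions: list[np.ndarray]  # per repeat: fold id (0..n_folds-1) per row
    grid_points: list[dict[str, Any]]
    grid_scores: list[float]  # mean pooled MCC per grid point, grid order


@dataclass
class TunedLearner:
    spec: LearnerSpec
    selected: dict[str, Any]
    model: LearnerHandle
    tuning_score: float
    diagnostics: TuningDiagnostics | None = None

    def predict_probability(self, X: np.ndarray) -> np.ndarray:
        return self.model.predict_probability(X)


def draw_folds(y: np.ndarray, n_folds: int, rng: np.random.Generator,
               max_retries: int = 100) -> np.ndarray:
    """Random equal-or-close fold assignment; redrawn until every fold has
    both classes (logged)."""
    n = y.shape[0]
    sizes = [n // n_folds + (1 if f < n % n_folds else 0) for f in range(n_folds)]
    base = np.concatenate([np.full(size, f, dtype=int) for f, size in enumerate(sizes)])
    for attempt in range(max_retries):
        folds = base[rng.permutation(n)]
        ok = all(len(np.unique(y[folds == f])) == 2 for f in range(n_folds))
        if ok:
            if attempt:
                log.info("fold partition redrawn %d time(s)", attempt)
            return folds
    raise RuntimeError(f"could not draw a {n_folds}-fold partition with both classes per fold")


def _pooled_mcc(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    from .metrics import ConfusionCounts, compute_metrics

    return compute_metrics(ConfusionCounts.from_predictions(y_true, y_pred)).mcc


def inner_tune(train: DescriptorTable, spec: LearnerSpec, n_folds: int = 5,
               n_repeats: int = 5, seed: int = 0) -> TunedLearner:
    """Repeated inner k-fold hyperparameter selection on mean pooled MCC.

    The same ``n_repeats`` random partitions are used for every grid point.
    Within a repeat, each fold is held out once, its predictions are pooled
    over the folds, and one MCC is computed; the repeat MCCs are averaged.
    A single-point grid skips the inner loop and reduces to a refit.
    """
    X, y = train.values, train.label_array()
    if len(np.unique(y)) < 2:
        raise ValueError("inner tuning requires both classes in the training split")
    points = spec.grid_points()
    rng = np.random.default_rng(seed)
    diagnostics = None
    if len(points) == 1:
        selected, score = points[0], float("nan")
    else:
        partitions = [draw_folds(y, n_folds, rng) for _ in range(n_repeats)]
        scores: list[float] = []
        for gp in points:
            repeat_mccs = []
            for folds in partitions:
                pred = np.empty_like(y)
                for f in range(n_folds):
                    tr, te = folds != f, folds == f
                    handle = build_learner(spec, gp, seed=seed)
                    handle.fit(X[tr], y[tr])
                    pred[te] = handle.predict_label(X[te])
                repeat_mccs.append(_pooled_mcc(y, pred))
            scores.append(float(np.mean(repeat_mccs)))
        best = int(np.argmax(scores))  # argmax keeps the first of tied maxima
        selected, score = points[best], scores[best]
        diagnostics = TuningDiagnostics(partitions, points, scores)
    final = build_learner(spec, selected, seed=seed).fit(X, y)
    return TunedLearner(spec, selected, final, score, diagnostics)


# ---------------------------------------------------------------------------
# consensus combiners
# ---------------------------------------------------------------------------

N_MEMBERS = 5


def consensus_vote(member_labels: Sequence[str]) -> str:
    """Majority vote of the five member models: binder iff >= 3 vote binder."""
    if len(member_labels) != N_MEMBERS:
        raise ValueError(f"consensus expects {N_MEMBERS} member labels, got {len(member_labels)}")
    n_binder = sum(1 for lab in member_labels if lab == "binder")
    return "binder" if n_binder >= 3 else "nonbinder"


def consensus_mean_probability(member_probs: Sequence[float]) -> tuple[float, str]:
    """Mean member binder probability; binder iff the mean is >= 0.5."""
    if len(member_probs) != N_MEMBERS:
        raise ValueError(f"consensus expects {N_MEMBERS} member probabilities, got {len(member_probs)}")
    probs = np.asarray(member_probs, dtype=float)
    if np.any(probs < 0) or np.any(probs > 1):
        raise ValueError("member probabilities must lie in [0, 1]")
    mean = float(probs.mean())
    return mean, ("binder" if mean >= 0.5 else "nonbinder")


@dataclass
class EnsemblePrediction:
    member_labels: list[str]
    member_probs: list[float]
    consensus_label_vote: str = field(init=False)
    consensus_label_meanprob: str = field(init=False)
    mean_prob: float = field(init=False)

    def __post_init__(self) -> None:
        self.consensus_label_vote = consensus_vote(self.member_labels)
        self.mean_prob, self.consensus_label_meanprob = consensus_mean_probability(self.member_probs)
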