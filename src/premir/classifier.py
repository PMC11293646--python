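"""The dense-network discriminator and its evaluation protocols.

The model is a feed-forward network with seven SELU dense layers, alpha
dropout and batch normalization, closed by a 2-way softmax that yields a
probability per class.  It is implemented in plain numerics and exposed as
a scikit-learn estimator (:class:`DenseHairpinClassifier`), so it composes
with sklearn pipelines and model selection.  Features are z-scored with
statistics of the training data only; training is deterministic given the
seed, uses adaptive-moment updates, and early-stops on an internal
validation split.

Evaluation follows the paired-partition protocol: positives and negatives
are split into k folds separately, per-fold metrics are aggregated as
mean +/- std; the versatility harness trains on all groups but one and
tests on the held-out group.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

__all__ = [
    "ModelSpec",
    "MetricsReport",
    "DenseHairpinClassifier",
    "train",
    "predict_proba",
    "compute_metrics",
    "kfold_cv",
    "leave_one_group_out",
]

_SELU_SCALE = 1.0507009873554805
_SELU_ALPHA = 1.6732632423543772

_DEFAULT_WIDTHS = (256, 144, 81, 45, 25, 14, 8)  # geometric 256 -> 8 over 7 layers

METRIC_NAMES = ("accuracy", "sensitivity", "specificity", "precision", "f1", "mcc", "auc")


@dataclass(frozen=True)
class ModelSpec:
    """Architecture and training settings of the discriminator."""

    hidden_layers: tuple[int, ...] = _DEFAULT_WIDTHS
    dropout_rate: float = 0.1
    batch_norm: bool = True
    epochs: int = 100
    batch_size: int = 128
    learning_rate: float = 1e-3
    weight_decay: float = 1e-3
    val_fraction: float = 0.1
    patience: int = 12
    threshold: float = 0.5

    def __post_init__(self):
        if len(self.hidden_layers) == 0:
            raise ValueError("at least one hidden layer is required")


@dataclass(frozen=True)
class MetricsReport:
    """The seven correctness metrics, optionally aggregated over folds."""

    accuracy: float
    sensitivity: float
    specificity: float
    precision: float
    f1: float
    mcc: float
    auc: float
    per_fold: pd.DataFrame | None = None
    std: dict | None = None

    def as_dict(self) -> dict:
        return {m: getattr(self, m) for m in METRIC_NAMES}

    def __str__(self) -> str:
        if self.std:
            return ", ".join(
                f"{m}={getattr(self, m):.4f}±{self.std[m]:.4f}" for m in METRIC_NAMES
            )
        return ", ".join(f"{m}={getattr(self, m):.4f}" for m in METRIC_NAMES)


# ---------------------------------------------------------------------------
# numerics


def _selu(x):
    return _SELU_SCALE * np.where(x > 0, x, _SELU_ALPHA * (np.exp(np.minimum(x, 0.0)) - 1))


def _selu_grad(x):
    return _SELU_SCALE * np.where(x > 0, 1.0, _SELU_ALPHA * np.exp(np.minimum(x, 0.0)))


def _alpha_dropout_mask(rng, shape, rate):
    """SELU-preserving dropout: dropped units are set to -scale*alpha, then
    the activations are affinely rescaled to keep zero mean / unit variance."""
    keep = 1.0 - rate
    alpha_p = -_SELU_SCALE * _SELU_ALPHA
    mask = rng.random(shape) < keep
    a = (keep + alpha_p**2 * keep * (1 - keep)) ** -0.5
    b = -a * (1 - keep) * alpha_p
    return mask, a, b, alpha_p


def _softmax(z):
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


class DenseHairpinClassifier(ClassifierMixin, BaseEstimator):
    """Seven-layer SELU dense network for pre-miRNA vs decoy discrimination.

    Parameters mirror :class:`ModelSpec`; ``random_state`` seeds weight
    initialization, batching, the dropout masks and the validation split,
    making training deterministic.
    """

    def __init__(
        self,
        hidden_layers=_DEFAULT_WIDTHS,
        dropout_rate=0.1,
        batch_norm=True,
        epochs=100,
        batch_size=128,
        learning_rate=1e-3,
        weight_decay=1e-3,
        val_fraction=0.1,
        patience=12,
        threshold=0.5,
        random_state=0,
    ):
        self.hidden_layers = hidden_layers
        self.dropout_rate = dropout_rate
        self.batch_norm = batch_norm
        self.epochs = epochs
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.weight_decay = weight_decay
        self.val_fraction = val_fraction
        self.patience = patience
        self.threshold = threshold
        self.random_state = random_state

    # -- internals ---------------------------------------------------------

    def _init_params(self, rng, d_in):
        widths = list(self.hidden_layers) + [2]
        params = []
        prev = d_in
        for w in widths:
            # LeCun normal initialization (SELU-appropriate)
            W = rng.normal(0.0, 1.0 / np.sqrt(prev), size=(prev, w))
            b = np.zeros(w)
            gamma = np.ones(w)
            beta = np.zeros(w)
            params.append(
                {
                    "W": W,
                    "b": b,
                    "gamma": gamma,
                    "beta": beta,
                    "run_mean": np.zeros(w),
                    "run_var": np.ones(w),
                }
            )
            prev = w
        return params

    def _forward(self, params, X, rng=None, training=False):
        cache = []
        h = X
        n_hidden = len(params) - 1
        momentum = 0.9
        for li, p in enumerate(params):
            z = h @ p["W"] + p["b"]
            layer = {"h_in": h, "z": z}
            if li < n_hidden:
                if self.batch_norm:
                    if training:
                        mu = z.mean(axis=0)
                        var = z.var(axis=0)
                        p["run_mean"] = momentum * p["run_mean"] + (1 - momentum) * mu
                        p["run_var"] = momentum * p["run_var"] + (1 - momentum) * var
                    else:
                        mu, var = p["run_mean"], p["run_var"]
                    zhat = (z - mu) / np.sqrt(var + 1e-5)
                    zn = p["gamma"] * zhat + p["beta"]
                    layer.update(mu=mu, var=var, zhat=zhat)
                else:
                    zn = z
                a = _selu(zn)
                layer["zn"] = zn
                if training and self.dropout_rate > 0:
                    mask, sa, sb, alpha_p = _alpha_dropout_mask(
                        rng, a.shape, self.dropout_rate
                    )
                    a = sa * (np.where(mask, a, alpha_p)) + sb
                    layer.update(mask=mask, sa=sa)
                h = a
            else:
                h = z
            cache.append(layer)
        return h, cache

    def _backward(self, params, cache, probs, y_onehot):
        n = probs.shape[0]
        grads = [dict() for _ in params]
        delta = (probs - y_onehot) / n
        n_hidden = len(params) - 1
        for li in range(len(params) - 1, -1, -1):
            layer = cache[li]
            p = params[li]
            if li < n_hidden:
                # through dropout
                if "mask" in layer:
                    delta = delta * layer["sa"] * layer["mask"]
                delta = delta * _selu_grad(layer["zn"])
                if self.batch_norm:
                    zhat, var = layer["zhat"], layer["var"]
                    grads[li]["gamma"] = (delta * zhat).sum(axis=0)
                    grads[li]["beta"] = delta.sum(axis=0)
                    dzhat = delta * p["gamma"]
                    m = delta.shape[0]
                    inv = 1.0 / np.sqrt(var + 1e-5)
                    delta = (
                        inv
                        / m
                        * (
                            m * dzhat
                            - dzhat.sum(axis=0)
                            - zhat * (dzhat * zhat).sum(axis=0)
                        )
                    )
            grads[li]["W"] = layer["h_in"].T @ delta
            grads[li]["b"] = delta.sum(axis=0)
            if li > 0:
                delta = delta @ p["W"].T
        return grads

    def _standardize(self, X):
        """Training-statistics z-score, clipped to +/-6 against
        out-of-distribution saturation; zero-variance features are zeroed."""
        Xs = (X - self.mean_) / self.scale_
        Xs[:, self.zero_var_] = 0.0
        return np.clip(Xs, -6.0, 6.0)

    # -- estimator API -----------------------------------------------------

    def fit(self, X, y):
        X, y = check_X_y(X, y, dtype=float)
        classes = np.unique(y)
        if len(classes) < 2:
            raise ValueError("training labels contain a single class")
        if len(classes) > 2:
            raise ValueError("only binary classification is supported")
        self.classes_ = classes
        y01 = (y == classes[1]).astype(int)
        self.n_features_in_ = X.shape[1]

        self.mean_ = X.mean(axis=0)
        self.scale_ = X.std(axis=0)
        # features constant in training carry no signal; they are zeroed at
        # train and predict time so unseen values cannot saturate the net
        self.zero_var_ = self.scale_ == 0
        self.scale_[self.zero_var_] = 1.0
        Xs = self._standardize(X)

        rng = np.random.default_rng(self.random_state)
        params = self._init_params(rng, X.shape[1])

        # internal validation split for early stopping
        n = len(y01)
        idx = rng.permutation(n)
        n_val = max(1, int(round(self.val_fraction * n))) if n > 20 else 0
        val_idx, tr_idx = idx[:n_val], idx[n_val:]
        if n_val and (len(np.unique(y01[tr_idx])) < 2):
            tr_idx, val_idx = idx, idx[:0]
            n_val = 0
        Xtr, ytr = Xs[tr_idx], y01[tr_idx]
        Xval, yval = Xs[val_idx], y01[val_idx]

        # adaptive-moment optimizer state
        mstate = [
            {k: np.zeros_like(p[k]) for k in ("W", "b", "gamma", "beta")}
            for p in params
        ]
        vstate = [
            {k: np.zeros_like(p[k]) for k in ("W", "b", "gamma", "beta")}
            for p in params
        ]
        beta1, beta2, eps = 0.9, 0.999, 1e-8
        t = 0
        best_loss = np.inf
        best_params = None
        stall = 0
        history = []
        for epoch in range(self.epochs):
            order = rng.permutation(len(ytr))
            for start in range(0, len(ytr), self.batch_size):
                batch = order[start : start + self.batch_size]
                if len(batch) < 2:
                    continue
                xb, yb = Xtr[batch], ytr[batch]
                logits, cache = self._forward(params, xb, rng=rng, training=True)
                probs = _softmax(logits)
                onehot = np.eye(2)[yb]
                grads = self._backward(params, cache, probs, onehot)
                t += 1
                for p, g, ms, vs in zip(params, grads, mstate, vstate):
                    for k, gk in g.items():
                        ms[k] = beta1 * ms[k] + (1 - beta1) * gk
                        vs[k] = beta2 * vs[k] + (1 - beta2) * gk**2
                        mhat = ms[k] / (1 - beta1**t)
                        vhat = vs[k] / (1 - beta2**t)
                        p[k] = p[k] - self.learning_rate * mhat / (np.sqrt(vhat) + eps)
                        if k == "W" and self.weight_decay:
                            # decoupled decay drives no-signal weights to zero
                            p[k] = p[k] * (1 - self.learning_rate * self.weight_decay)
            # early stopping on the validation split
            if n_val:
                logits, _ = self._forward(params, Xval, training=False)
                probs = _softmax(logits)
                loss = -np.mean(
                    np.log(np.clip(probs[np.arange(len(yval)), yval], 1e-12, 1))
                )
            else:
                logits, _ = self._forward(params, Xtr, training=False)
                probs = _softmax(logits)
                loss = -np.mean(
                    np.log(np.clip(probs[np.arange(len(ytr)), ytr], 1e-12, 1))
                )
            history.append(loss)
            if loss < best_loss - 1e-5:
                best_loss = loss
                best_params = [
                    {k: np.copy(v) for k, v in p.items()} for p in params
                ]
                stall = 0
            else:
                stall += 1
                if stall >= self.patience:
                    break
        self.params_ = best_params if best_params is not None else params
        self.loss_history_ = history
        self.n_iter_ = len(history)
        return self

    def predict_proba(self, X):
        check_is_fitted(self, "params_")
        X = check_array(X, dtype=float, ensure_min_samples=0)
        if X.shape[0] == 0:
            return np.zeros((0, 2))
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"feature width {X.shape[1]} != training width {self.n_features_in_}"
            )
        Xs = self._standardize(X)
        logits, _ = self._forward(self.params_, Xs, training=False)
        return _softmax(logits)

    def predict(self, X):
        proba = self.predict_proba(X)
        if proba.shape[0] == 0:
            return np.array([])
        return self.classes_[(proba[:, 1] >= self.threshold).astype(int)]

    def decision_scores(self, X):
        """Probability of the positive (second) class per row."""
        return self.predict_proba(X)[:, 1]


# ---------------------------------------------------------------------------
# functional facade


def _estimator_from_spec(spec: ModelSpec | None, seed: int) -> DenseHairpinClassifier:
    spec = spec or ModelSpec()
    return DenseHairpinClassifier(
        hidden_layers=tuple(spec.hidden_layers),
        dropout_rate=spec.dropout_rate,
        batch_norm=spec.batch_norm,
        epochs=spec.epochs,
        batch_size=spec.batch_size,
        learning_rate=spec.learning_rate,
        weight_decay=spec.weight_decay,
        val_fraction=spec.val_fraction,
        patience=spec.patience,
        threshold=spec.threshold,
        random_state=seed,
    )


def train(features, labels, spec: ModelSpec | None = None, seed: int = 0):
    """Fit the discriminator; deterministic given the seed."""
    est = _estimator_from_spec(spec, seed)
    return est.fit(np.asarray(features, dtype=float), np.asarray(labels))


def predict_proba(model: DenseHairpinClassifier, features) -> np.ndarray:
    """Positive-class probability per row."""
    features = np.asarray(features, dtype=float)
    if features.ndim != 2:
        raise ValueError("features must be 2-dimensional")
    return model.decision_scores(features)


# ---------------------------------------------------------------------------
# metrics


def compute_metrics(labels, scores, threshold: float = 0.5) -> MetricsReport:
    """Accuracy, sensitivity, specificity, precision, F1, MCC and AUC.

    AUC uses the rank (Mann-Whitney) statistic with average-rank tie
    correction.  With one class absent, AUC and MCC are NaN (with a
    warning); ratio metrics with empty denominators are 0.
    """
    y = np.asarray(labels).astype(int)
    s = np.asarray(scores, dtype=float)
    if y.shape != s.shape:
        raise ValueError("labels and scores must have the same shape")
    pred = (s >= threshold).astype(int)
    tp = int(np.sum((pred == 1) & (y == 1)))
    tn = int(np.sum((pred == 0) & (y == 0)))
    fp = int(np.sum((pred == 1) & (y == 0)))
    fn = int(np.sum((pred == 0) & (y == 1)))
    n1, n0 = tp + fn, tn + fp

    def ratio(a, b):
        return a / b if b else 0.0

    accuracy = ratio(tp + tn, len(y))
    sensitivity = ratio(tp, tp + fn)
    specificity = ratio(tn, tn + fp)
    precision = ratio(tp, tp + fp)
    f1 = ratio(2 * precision * sensitivity, precision + sensitivity)
    if n1 == 0 or n0 == 0:
        warnings.warn("one class absent: AUC and MCC are undefined", stacklevel=2)
        mcc = float("nan")
        auc = float("nan")
    else:
        denom = np.sqrt(
            float(tp + fp) * float(tp + fn) * float(tn + fp) * float(tn + fn)
        )
        mcc = ((tp * tn) - (fp * fn)) / denom if denom else 0.0
        ranks = rankdata(s)
        auc = (ranks[y == 1].sum() - n1 * (n1 + 1) / 2) / (n1 * n0)
    return MetricsReport(
        accuracy=accuracy,
        sensitivity=sensitivity,
        specificity=specificity,
        precision=precision,
        f1=f1,
        mcc=mcc,
        auc=float(auc),
    )


def _aggregate(fold_reports: list[MetricsReport]) -> MetricsReport:
    table = pd.DataFrame([r.as_dict() for r in fold_reports])
    mean = table.mean()
    std = table.std(ddof=1) if len(table) > 1 else table.iloc[0] * 0.0
    return MetricsReport(
        **{m: float(mean[m]) for m in METRIC_NAMES},
        per_fold=table,
        std={m: float(std[m]) for m in METRIC_NAMES},
    )


def paired_folds(y, k: int, seed: int) -> list[np.ndarray]:
    """Positives and negatives partitioned into k folds separately."""
    y = np.asarray(y).astype(int)
    rng = np.random.default_rng(seed)
    pos = np.flatnonzero(y == 1)
    neg = np.flatnonzero(y == 0)
    if k < 2:
        raise ValueError("k must be at least 2")
    if k > min(len(pos), len(neg)):
        raise ValueError(f"k={k} exceeds the size of a class")
    rng.shuffle(pos)
    rng.shuffle(neg)
    folds = []
    for pchunk, nchunk in zip(np.array_split(pos, k), np.array_split(neg, k)):
        folds.append(np.sort(np.concatenate([pchunk, nchunk])))
    return folds


def kfold_cv(
    features,
    labels,
    k: int = 10,
    spec: ModelSpec | None = None,
    seed: int = 0,
    threshold: float = 0.5,
) -> MetricsReport:
    """k-fold cross-validation with paired positive/negative partitioning."""
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels).astype(int)
    folds = paired_folds(y, k, seed)
    reports = []
    for i, test_idx in enumerate(folds):
        mask = np.ones(len(y), dtype=bool)
        mask[test_idx] = False
        model = train(X[mask], y[mask], spec, seed=seed + i + 1)
        scores = predict_proba(model, X[test_idx])
        reports.append(compute_metrics(y[test_idx], scores, threshold))
    return _aggregate(reports)


def leave_one_group_out(
    datasets: dict[str, tuple[np.ndarray, np.ndarray]],
    spec: ModelSpec | None = None,
    seed: int = 0,
    threshold: float = 0.5,
) -> dict[str, MetricsReport]:
    """Versatility analysis: train on all groups but one, test on it."""
    if len(datasets) < 2:
        raise ValueError("at least two groups are required")
    out: dict[str, MetricsReport] = {}
    for gi, held_out in enumerate(sorted(datasets)):
        X_tr = np.vstack(
            [np.asarray(datasets[g][0], dtype=float) for g in sorted(datasets) if g != held_out]
        )
        y_tr = np.concatenate(
            [np.asarray(datasets[g][1]) for g in sorted(datasets) if g != held_out]
        )
        X_te, y_te = datasets[held_out]
        model = train(X_tr, y_tr, spec, seed=seed + gi)
        scores = predict_proba(model, np.asarray(X_te, dtype=float))
        out[held_out] = compute_metrics(np.asarray(y_te).astype(int), scores, threshold)
    return out
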