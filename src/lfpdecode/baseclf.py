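"""The three base neural-network classifiers, written from their defining math.

* FBANN — a one-hidden-layer feedforward network with logistic-sigmoid
  activations throughout, trained by full-batch steepest descent on the
  mean-squared error.  The forward pass is exactly
  ``phi = f(sum_p w2_p f(sum_q W1_pq x_q + b1_p) + b2)``.
* RBFNN — Gaussian radial-basis hidden layer (centers by k-means, shared
  width = median inter-center distance) with a linear output layer solved in
  closed form by regularized least squares — the global minimum of the
  output-layer problem.
* PNN — a Parzen-window density classifier: class score proportional to
  prior times the mean isotropic Gaussian kernel over that class's stored
  patterns; decision by the Bayes rule (argmax posterior).

Distance-based models need commensurate feature scales, so training fronts
every classifier with a z-score normalizer fitted on the training fold.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import KMeans

from .errors import ConfigurationError, DegenerateTrainingError, ModelStateError

log = logging.getLogger(__name__)


def sigmoid(z):
    return 1.0 / (1.0 + np.exp(-np.asarray(z, dtype=float)))


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------


@dataclass
class ZScore:
    """Per-dimension standardization with training-fold statistics."""

    mean: np.ndarray | None = None
    std: np.ndarray | None = None

    def fit(self, X: np.ndarray) -> "ZScore":
        X = np.asarray(X, dtype=float)
        self.mean = X.mean(axis=0)
        sd = X.std(axis=0)
        sd[sd == 0] = 1.0  # constant feature: pass through centred
        self.std = sd
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        if self.mean is None:
            raise ModelStateError("ZScore used before fit")
        return (np.asarray(X, dtype=float) - self.mean) / self.std

    def to_dict(self) -> dict:
        return {"mean": self.mean.tolist(), "std": self.std.tolist()}

    @classmethod
    def from_dict(cls, d: dict) -> "ZScore":
        return cls(mean=np.asarray(d["mean"]), std=np.asarray(d["std"]))


# ---------------------------------------------------------------------------
# FBANN
# ---------------------------------------------------------------------------


@dataclass
class FbannModel:
    """Weights of the one-hidden-layer sigmoid network."""

    W1: np.ndarray  # (n_hidden, m)
    b1: np.ndarray  # (n_hidden,)
    w2: np.ndarray  # (n_hidden,)
    b2: float

    def __post_init__(self):
        self.W1 = np.atleast_2d(np.asarray(self.W1, dtype=float))
        self.b1 = np.asarray(self.b1, dtype=float).ravel()
        self.w2 = np.asarray(self.w2, dtype=float).ravel()
        self.b2 = float(self.b2)
        n, m = self.W1.shape
        if n < 1 or self.b1.shape != (n,) or self.w2.shape != (n,):
            raise ConfigurationError("FbannModel: inconsistent layer shapes")
        if not all(np.all(np.isfinite(a)) for a in (self.W1, self.b1, self.w2, [self.b2])):
            raise ConfigurationError("FbannModel: parameters must be finite")

    @property
    def n_inputs(self) -> int:
        return self.W1.shape[1]

    def to_dict(self) -> dict:
        return {"kind": "fbann", "W1": self.W1.tolist(), "b1": self.b1.tolist(),
                "w2": self.w2.tolist(), "b2": self.b2}

    @classmethod
    def from_dict(cls, d: dict) -> "FbannModel":
        return cls(W1=d["W1"], b1=d["b1"], w2=d["w2"], b2=d["b2"])

    def predict_score(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.n_inputs:
            raise ConfigurationError(
                f"fbann_forward: expected {self.n_inputs} inputs, got {X.shape[1]}"
            )
        H = sigmoid(X @ self.W1.T + self.b1)
        return sigmoid(H @ self.w2 + self.b2)


def fbann_forward(model: FbannModel, x: np.ndarray) -> float:
    """Network output for one input vector (a probability-like score in (0,1))."""
    return float(model.predict_score(np.atleast_2d(x))[0])


@dataclass(frozen=True)
class FbannHyper:
    n_hidden: int = 10
    learning_rate: float = 0.5
    max_epochs: int = 500
    patience: int = 25  # early-stopping checks on the validation split
    val_fraction: float = 0.0  # 0 disables early stopping
    seed: int = 0


def fbann_train(X: np.ndarray, y: np.ndarray, hyper: FbannHyper = FbannHyper()) -> FbannModel:
    """Full-batch steepest-descent training on the MSE loss.

    Returns the trained model; the MSE trajectory is available on the model
    as ``model.history`` (non-increasing to within gradient-step noise).
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    if len(X) != len(y) or len(y) < 2:
        raise DegenerateTrainingError("fbann_train needs >= 2 labelled samples")
    if len(np.unique(y)) < 2:
        raise DegenerateTrainingError("fbann_train: both classes must be present")
    rng = np.random.default_rng(hyper.seed)
    n_val = int(round(hyper.val_fraction * len(y))) if hyper.val_fraction > 0 else 0
    order = rng.permutation(len(y))
    val_idx, tr_idx = order[:n_val], order[n_val:]
    Xt, yt = X[tr_idx], y[tr_idx]
    Xv, yv = X[val_idx], y[val_idx]

    m = X.shape[1]
    W1 = rng.normal(0.0, 1.0 / np.sqrt(m), size=(hyper.n_hidden, m))
    b1 = np.zeros(hyper.n_hidden)
    w2 = rng.normal(0.0, 1.0 / np.sqrt(hyper.n_hidden), size=hyper.n_hidden)
    b2 = 0.0

    history = []
    best_val, best_params, stale = np.inf, None, 0
    lr = hyper.learning_rate
    for _epoch in range(hyper.max_epochs):
        H = sigmoid(Xt @ W1.T + b1)  # (N, n_hidden)
        out = sigmoid(H @ w2 + b2)  # (N,)
        err = out - yt
        history.append(float(np.mean(err**2)))
        # backprop of the mean-squared error
        d_out = 2.0 * err * out * (1.0 - out) / len(yt)
        g_w2 = H.T @ d_out
        g_b2 = d_out.sum()
        d_hid = np.outer(d_out, w2) * H * (1.0 - H)
        g_W1 = d_hid.T @ Xt
        g_b1 = d_hid.sum(axis=0)
        W1 -= lr * g_W1
        b1 -= lr * g_b1
        w2 -= lr * g_w2
        b2 -= lr * g_b2
        if n_val:
            val_mse = float(np.mean((sigmoid(sigmoid(Xv @ W1.T + b1) @ w2 + b2) - yv) ** 2))
            if val_mse < best_val - 1e-9:
                best_val, stale = val_mse, 0
                best_params = (W1.copy(), b1.copy(), w2.copy(), b2)
            else:
                stale += 1
                if stale >= hyper.patience:
                    W1, b1, w2, b2 = best_params
                    break
    model = FbannModel(W1=W1, b1=b1, w2=w2, b2=b2)
    model.history = history
    return model


# ---------------------------------------------------------------------------
# RBFNN
# ---------------------------------------------------------------------------


@dataclass
class RbfnnModel:
    """Gaussian RBF hidden layer + linear output layer (clipped to [0, 1])."""

    centers: np.ndarray  # (k, m)
    widths: np.ndarray  # (k,)
    weights: np.ndarray  # (k,)
    bias: float

    def __post_init__(self):
        self.centers = np.atleast_2d(np.asarray(self.centers, dtype=float))
        self.widths = np.asarray(self.widths, dtype=float).ravel()
        self.weights = np.asarray(self.weights, dtype=float).ravel()
        self.bias = float(self.bias)
        if len(self.centers) < 1:
            raise ConfigurationError("RbfnnModel needs >= 1 center")
        if np.any(self.widths <= 0):
            raise ConfigurationError("RbfnnModel widths must be > 0")

    def to_dict(self) -> dict:
        return {"kind": "rbfnn", "centers": self.centers.tolist(),
                "widths": self.widths.tolist(), "weights": self.weights.tolist(),
                "bias": self.bias}

    @classmethod
    def from_dict(cls, d: dict) -> "RbfnnModel":
        return cls(centers=d["centers"], widths=d["widths"], weights=d["weights"],
                   bias=d["bias"])

    def hidden(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        d2 = ((X[:, None, :] - self.centers[None, :, :]) ** 2).sum(axis=2)
        return np.exp(-d2 / (2.0 * self.widths**2))

    def predict_score(self, X: np.ndarray) -> np.ndarray:
        raw = self.hidden(X) @ self.weights + self.bias
        return np.clip(raw, 0.0, 1.0)


def rbfnn_predict(model: RbfnnModel, x: np.ndarray) -> float:
    return float(model.predict_score(np.atleast_2d(x))[0])


@dataclass(frozen=True)
class RbfnnHyper:
    n_centers: int = 20
    ridge: float = 1e-6
    seed: int = 0


def rbfnn_train(X: np.ndarray, y: np.ndarray, hyper: RbfnnHyper = RbfnnHyper()) -> RbfnnModel:
    """Centers by k-means; output weights by regularized least squares."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    if len(X) < hyper.n_centers:
        raise ConfigurationError(
            f"rbfnn_train: {len(X)} samples < {hyper.n_centers} centers"
        )
    if len(np.unique(y)) < 2:
        raise DegenerateTrainingError("rbfnn_train: both classes must be present")
    km = KMeans(n_clusters=hyper.n_centers, n_init=10, random_state=hyper.seed)
    km.fit(X)
    centers = km.cluster_centers_
    if len(centers) > 1:
        d = np.sqrt(((centers[:, None] - centers[None, :]) ** 2).sum(axis=2))
        sigma = float(np.median(d[np.triu_indices(len(centers), k=1)]))
    else:
        sigma = float(np.median(np.sqrt(((X - centers[0]) ** 2).sum(axis=1)))) or 1.0
    if sigma <= 0:
        sigma = 1.0
    widths = np.full(len(centers), sigma)
    model = RbfnnModel(centers=centers, widths=widths, weights=np.zeros(len(centers)), bias=0.0)
    Phi = np.column_stack([model.hidden(X), np.ones(len(X))])
    A = Phi.T @ Phi + hyper.ridge * np.eye(Phi.shape[1])
    coef = np.linalg.solve(A, Phi.T @ y)
    model.weights, model.bias = coef[:-1], float(coef[-1])
    return model


# ---------------------------------------------------------------------------
# PNN
# ---------------------------------------------------------------------------


@dataclass
class PnnModel:
    """Stored patterns per class + Parzen smoothing parameter + priors."""

    classes: list  # canonical (sorted) class order
    patterns: list[np.ndarray]  # one (N_j, m) array per class
    sigma: float
    priors: np.ndarray

    def __post_init__(self):
        self.priors = np.asarray(self.priors, dtype=float).ravel()
        if self.sigma <= 0:
            raise ConfigurationError(f"PnnModel sigma must be > 0, got {self.sigma}")
        if abs(self.priors.sum() - 1.0) > 1e-9:
            raise ConfigurationError("PnnModel priors must sum to 1")
        if any(len(p) < 1 for p in self.patterns):
            raise ConfigurationError("PnnModel needs >= 1 pattern per class")

    def to_dict(self) -> dict:
        return {"kind": "pnn", "classes": list(self.classes),
                "patterns": [p.tolist() for p in self.patterns],
                "sigma": self.sigma, "priors": self.priors.tolist()}

    @classmethod
    def from_dict(cls, d: dict) -> "PnnModel":
        return cls(classes=d["classes"], patterns=[np.asarray(p) for p in d["patterns"]],
                   sigma=d["sigma"], priors=d["priors"])

    def posteriors(self, X: np.ndarray) -> np.ndarray:
        """Normalized class posteriors, shape (N, n_classes)."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        scores = np.empty((len(X), len(self.classes)))
        for j, P in enumerate(self.patterns):
            d2 = ((X[:, None, :] - P[None, :, :]) ** 2).sum(axis=2)
            # log-sum-exp keeps small-sigma cases finite
            logk = -d2 / (2.0 * self.sigma**2)
            mx = logk.max(axis=1, keepdims=True)
            dens = np.exp(mx).ravel() * np.exp(logk - mx).mean(axis=1)
            scores[:, j] = self.priors[j] * dens
        tot = scores.sum(axis=1, keepdims=True)
        flat = (tot.ravel() == 0) | ~np.isfinite(tot.ravel())
        scores[flat] = 1.0 / len(self.classes)  # kernel underflow far from all data
        tot[flat.nonzero()[0]] = 1.0
        return scores / tot

    def predict_score(self, X: np.ndarray) -> np.ndarray:
        """Binary convenience: posterior of the class encoded 1 (the larger label)."""
        post = self.posteriors(X)
        j = self.classes.index(max(self.classes))
        return post[:, j]

    def predict(self, X: np.ndarray):
        post = self.posteriors(X)
        idx = post.argmax(axis=1)
        ties = np.isclose(post.max(axis=1), post.min(axis=1)) & (post.shape[1] > 1)
        for i in np.nonzero(ties)[0]:
            log.info("pnn: exact posterior tie at sample %d; first canonical class chosen", i)
            idx[i] = 0
        return [self.classes[k] for k in idx]


def pnn_predict(model: PnnModel, x: np.ndarray) -> np.ndarray:
    """Class posterior scores for one sample, in canonical class order."""
    return model.posteriors(np.atleast_2d(x))[0]


@dataclass(frozen=True)
class PnnHyper:
    sigma: float | None = None  # None -> grid search on inner CV folds
    sigma_grid: tuple[float, ...] = (0.05, 0.1, 0.25, 0.5, 1.0, 2.0)
    inner_folds: int = 3
    seed: int = 0


def _pnn_cv_accuracy(X, y, classes, sigma, priors, folds, seed) -> float:
    from sklearn.model_selection import StratifiedKFold

    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    hits = 0
    for tr, te in skf.split(X, y):
        pats = [X[tr][y[tr] == c] for c in classes]
        if any(len(p) == 0 for p in pats):
            return 0.0
        m = PnnModel(classes=list(classes), patterns=pats, sigma=sigma, priors=priors)
        pred = m.predict(X[te])
        hits += sum(p == t for p, t in zip(pred, y[te]))
    return hits / len(y)


def pnn_train(X: np.ndarray, y: np.ndarray, hyper: PnnHyper = PnnHyper(),
              *, select_mask=None, priors=None) -> PnnModel:
    """Store patterns; pick sigma by grid search over inner CV folds.

    ``select_mask`` restricts both the sigma grid search and the stored
    patterns to a subset of samples.  A Parzen density estimate is distorted
    by interpolated (bootstrap) near-duplicates — they shrink the apparent
    class variance and leak across inner CV folds — so when a training set
    mixes original and synthetic samples, the PNN is fitted on the originals
    and the class rebalancing is expressed through ``priors`` instead (the
    Bayes-rule mechanism a probabilistic classifier already has).
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y).ravel()
    if select_mask is not None:
        select_mask = np.asarray(select_mask, dtype=bool)
        if len(np.unique(y[select_mask])) >= 2:
            X, y = X[select_mask], y[select_mask]
        select_mask = None
    classes = sorted(np.unique(y).tolist())
    if len(classes) < 2:
        raise DegenerateTrainingError("pnn_train: both classes must be present")
    if priors is None:
        priors = np.array([(y == c).mean() for c in classes])
    else:
        priors = np.asarray(priors, dtype=float)
    if hyper.sigma is not None:
        if hyper.sigma <= 0:
            raise ConfigurationError(f"pnn sigma must be > 0, got {hyper.sigma}")
        sigma = hyper.sigma
    else:
        Xs, ys = X, y
        sub = Xs if len(Xs) <= 400 else Xs[np.random.default_rng(hyper.seed).choice(len(Xs), 400, replace=False)]
        d = np.sqrt(((sub[:, None] - sub[None, :]) ** 2).sum(axis=2))
        base = float(np.median(d[np.triu_indices(len(sub), k=1)])) or 1.0
        best = (-1.0, base)
        for frac in hyper.sigma_grid:
            acc = _pnn_cv_accuracy(Xs, ys, classes, frac * base, priors,
                                   hyper.inner_folds, hyper.seed)
            if acc > best[0]:
                best = (acc, frac * base)
        sigma = best[1]
    patterns = [X[y == c] for c in classes]
    return PnnModel(classes=classes, patterns=patterns, sigma=sigma, priors=priors)


# ---------------------------------------------------------------------------
# serialization helpers
# ---------------------------------------------------------------------------

_MODEL_KINDS = {"fbann": FbannModel, "rbfnn": RbfnnModel, "pnn": PnnModel}


def model_from_dict(d: dict):
    kind = d.get("kind")
    if kind not in _MODEL_KINDS:
        raise ConfigurationError(f"unknown model kind {kind!r}")
    return _MODEL_KINDS[kind].from_dict(d)
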