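"""Class-balancing bootstrap and cross-validation utilities.

The bootstrap generates synthetic minority-class samples as convex
combinations of a randomly chosen seed point and its r Euclidean nearest
neighbors: weights w_i = c_i / sum_d c_d with the c_i drawn from a Gaussian,
folded non-negative and clipped to [0, r], so every synthetic sample lies in
the convex hull of its neighborhood.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.model_selection import KFold, StratifiedKFold

from .errors import ConfigurationError, SignalLengthError, SizeError


@dataclass(frozen=True)
class BootstrapParams:
    r: int = 5  # neighbor count
    n_target: int = 1  # synthetic samples to generate
    gaussian_mu: float = 0.0
    gaussian_sigma: float = 1.0
    seed: int = 0

    def validate(self):
        if self.r < 1:
            raise ConfigurationError(f"r must be >= 1, got {self.r}")
        if self.n_target < 1:
            raise ConfigurationError(f"n_target must be >= 1, got {self.n_target}")
        if self.gaussian_sigma <= 0:
            raise ConfigurationError(f"gaussian_sigma must be > 0, got {self.gaussian_sigma}")


def _draw_weights(rng: np.random.Generator, params: BootstrapParams) -> np.ndarray:
    """r+1 convex weights (seed point carries index 0 with its own c_0)."""
    while True:
        c = np.abs(rng.normal(params.gaussian_mu, params.gaussian_sigma, size=params.r + 1))
        c = np.clip(c, 0.0, float(params.r))
        s = c.sum()
        if s > 0:
            return c / s


def neighbor_bootstrap(X_class: np.ndarray, params: BootstrapParams,
                       *, return_details: bool = False):
    """Generate ``n_target`` synthetic samples for one class.

    Deterministic under a fixed seed; every output lies in the convex hull
    of the seed point and its r nearest neighbors.  With ``return_details``
    also returns, per sample, the seed index, the neighbor indices and the
    convex weights used.
    """
    params.validate()
    X = np.atleast_2d(np.asarray(X_class, dtype=float))
    n = len(X)
    if n < params.r + 1:
        raise SizeError(f"neighbor_bootstrap needs >= r+1={params.r + 1} samples, got {n}")
    rng = np.random.default_rng(params.seed)
    # full pairwise distances; neighborhoods are stable under ties (argsort is stable)
    d2 = ((X[:, None, :] - X[None, :, :]) ** 2).sum(axis=2)
    np.fill_diagonal(d2, np.inf)
    neighbor_idx = np.argsort(d2, axis=1, kind="stable")[:, : params.r]
    out = np.empty((params.n_target, X.shape[1]))
    details = []
    for i in range(params.n_target):
        k0 = int(rng.integers(n))
        group = np.vstack([X[k0], X[neighbor_idx[k0]]])  # (r+1, m), seed first
        w = _draw_weights(rng, params)
        out[i] = w @ group
        if return_details:
            details.append((k0, neighbor_idx[k0].copy(), w))
    return (out, details) if return_details else out


def balance_with_bootstrap(
    X: np.ndarray, y: np.ndarray, *, r: int = 5, seed: int = 0,
    gaussian_mu: float = 0.0, gaussian_sigma: float = 1.0,
):
    """Augment every minority class up to the majority count.

    Returns ``(X_aug, y_aug, provenance)`` where provenance is
    ``'original'`` or ``'bootstrap'`` per row; original rows come first.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    n_max = counts.max()
    parts_X, parts_y, prov = [X], [y], ["original"] * len(y)
    for j, c in enumerate(classes):
        deficit = int(n_max - counts[j])
        if deficit == 0:
            continue
        Xc = X[y == c]
        r_eff = min(r, len(Xc) - 1)
        if r_eff < 1:
            raise SizeError(f"class {c!r} has too few samples ({len(Xc)}) to bootstrap")
        params = BootstrapParams(r=r_eff, n_target=deficit, seed=seed + j,
                                 gaussian_mu=gaussian_mu, gaussian_sigma=gaussian_sigma)
        parts_X.append(neighbor_bootstrap(Xc, params))
        parts_y.append(np.full(deficit, c, dtype=y.dtype))
        prov += ["bootstrap"] * deficit
    return np.vstack(parts_X), np.concatenate(parts_y), np.array(prov)


def kfold_split(n: int, k: int = 10, labels=None, seed: int = 0):
    """Stratified (when labels given) k-fold partition of range(n).

    Returns a list of (train_idx, test_idx) pairs; test folds are disjoint,
    cover all indices, and per-class counts per fold differ by <= 1.
    """
    if n < k:
        raise SizeError(f"kfold_split: n={n} < k={k}")
    if labels is not None:
        labels = np.asarray(labels)
        if len(labels) != n:
            raise SignalLengthError(f"labels length {len(labels)} != n={n}")
        splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        return list(splitter.split(np.zeros((n, 1)), labels))
    splitter = KFold(n_splits=k, shuffle=True, random_state=seed)
    return list(splitter.split(np.zeros((n, 1))))


def cv_error(desired, predicted) -> float:
    """Mean squared error between desired and realized classifier outputs."""
    d = np.asarray(desired, dtype=float).ravel()
    y = np.asarray(predicted, dtype=float).ravel()
    if d.shape != y.shape or len(d) < 1:
        raise SignalLengthError(f"cv_error: shapes {d.shape} vs {y.shape}")
    return float(np.mean((d - y) ** 2))
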