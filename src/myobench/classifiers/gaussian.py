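"""Gaussian discriminant classifiers: one-vs-one LDA and maximum likelihood.

LDA is realized as one binary linear discriminant per unordered class pair
(pooled covariance of the two classes, equal priors), combined by majority
vote; vote ties are broken by the summed signed discriminant margins, then by
the lowest class index.

MLE fits a full-covariance multivariate Gaussian per class and predicts the
class with the highest log-likelihood (equal priors).  Covariances with
condition number above 1e10 are ridge-regularized by ``(1e-6 * trace/d) * I``;
a failed Cholesky factorization escalates the same ridge until it succeeds, so
singular covariances degrade gracefully instead of crashing.
"""

from __future__ import annotations

import numpy as np

from ..session_io import ConfigError
from .base import register

_COND_LIMIT = 1e10
_RIDGE = 1e-6


def _regularized_cov(X: np.ndarray) -> np.ndarray:
    """Sample covariance (ddof=1 when possible) with the conditioning ridge."""
    d = X.shape[1]
    if X.shape[0] < 2:
        cov = np.zeros((d, d))
    else:
        cov = np.cov(X, rowvar=False, ddof=1)
        cov = np.atleast_2d(cov)
    return _apply_ridge_if_needed(cov)


def _apply_ridge_if_needed(cov: np.ndarray) -> np.ndarray:
    d = cov.shape[0]
    if np.linalg.cond(cov) > _COND_LIMIT:
        tr = np.trace(cov)
        scale = tr / d if tr > 0 else 1.0
        cov = cov + (_RIDGE * scale) * np.eye(d)
    return cov


def _chol_with_escalating_ridge(cov: np.ndarray) -> np.ndarray:
    d = cov.shape[0]
    tr = np.trace(cov)
    scale = tr / d if tr > 0 else 1.0
    ridge = _RIDGE * scale
    for _ in range(40):
        try:
            return np.linalg.cholesky(cov)
        except np.linalg.LinAlgError:
            cov = cov + ridge * np.eye(d)
            ridge *= 10.0
    raise ConfigError("covariance could not be factorized")  # pragma: no cover


@register("LDA")
class LdaOneVsOne:
    """Pairwise linear discriminants with majority voting."""

    def __init__(self, n_classes: int):
        self.n_classes = n_classes
        self.n_features: int | None = None
        self._pairs: list[tuple[int, int]] = []
        self._W: np.ndarray | None = None  # [n_pairs, d]
        self._c: np.ndarray | None = None  # [n_pairs]

    def fit(self, X: np.ndarray, y: np.ndarray, rng=None) -> "LdaOneVsOne":
        d = X.shape[1]
        self.n_features = d
        groups = [X[y == k] for k in range(self.n_classes)]
        for k, g in enumerate(groups):
            if g.shape[0] == 0:
                raise ConfigError(f"class index {k} has no training samples")
        self._pairs = [
            (a, b) for a in range(self.n_classes) for b in range(a + 1, self.n_classes)
        ]
        W = np.empty((len(self._pairs), d))
        c = np.empty(len(self._pairs))
        for p, (a, b) in enumerate(self._pairs):
            Xa, Xb = groups[a], groups[b]
            na, nb = Xa.shape[0], Xb.shape[0]
            mu_a, mu_b = Xa.mean(axis=0), Xb.mean(axis=0)
            Sa = (Xa - mu_a).T @ (Xa - mu_a)
            Sb = (Xb - mu_b).T @ (Xb - mu_b)
            denom = max(na + nb - 2, 1)
            cov = _apply_ridge_if_needed((Sa + Sb) / denom)
            L = _chol_with_escalating_ridge(cov)
            w = _chol_solve(L, mu_a - mu_b)
            W[p] = w
            c[p] = w @ (mu_a + mu_b) / 2.0
        self._W, self._c = W, c
        return self

    def predict_indices(self, X: np.ndarray) -> np.ndarray:
        D = X @ self._W.T - self._c  # [n, n_pairs]; >0 votes for class a
        n = X.shape[0]
        votes = np.zeros((n, self.n_classes))
        margins = np.zeros((n, self.n_classes))
        for p, (a, b) in enumerate(self._pairs):
            d = D[:, p]
            win_a = d > 0
            votes[win_a, a] += 1
            votes[~win_a, b] += 1
            margins[:, a] += d
            margins[:, b] -= d
        return _vote_argmax(votes, margins)

    def pair_discriminants(self) -> tuple[list[tuple[int, int]], np.ndarray, np.ndarray]:
        """Expose the fitted (pairs, W, c) for inspection/testing."""
        return self._pairs, self._W, self._c


def _chol_solve(L: np.ndarray, b: np.ndarray) -> np.ndarray:
    z = np.linalg.solve(L, b)
    return np.linalg.solve(L.T, z)


def _vote_argmax(votes: np.ndarray, margins: np.ndarray) -> np.ndarray:
    """Argmax by votes, ties by summed margins, then lowest class index."""
    n, C = votes.shape
    best = np.max(votes, axis=1, keepdims=True)
    tied = votes == best
    key = np.where(tied, margins, -np.inf)
    return np.argmax(key, axis=1)  # argmax takes the lowest index on ties


@register("MLE")
class GaussianMLE:
    """Per-class full-covariance Gaussian, maximum-likelihood prediction."""

    def __init__(self, n_classes: int):
        self.n_classes = n_classes
        self.n_features: int | None = None
        self.means_: np.ndarray | None = None
        self._chols: list[np.ndarray] = []
        self._logdets: np.ndarray | None = None

    def fit(self, X: np.ndarray, y: np.ndarray, rng=None) -> "GaussianMLE":
        d = X.shape[1]
        self.n_features = d
        means = np.empty((self.n_classes, d))
        self._chols = []
        logdets = np.empty(self.n_classes)
        for k in range(self.n_classes):
            Xk = X[y == k]
            if Xk.shape[0] == 0:
                raise ConfigError(f"class index {k} has no training samples")
            means[k] = Xk.mean(axis=0)
            cov = _regularized_cov(Xk)
            L = _chol_with_escalating_ridge(cov)
            self._chols.append(L)
            logdets[k] = 2.0 * np.sum(np.log(np.diag(L)))
        self.means_ = means
        self._logdets = logdets
        return self

    def log_likelihood(self, X: np.ndarray) -> np.ndarray:
        """Per-class Gaussian log-density for each row, ``[n, n_classes]``."""
        n, d = X.shape
        out = np.empty((n, self.n_classes))
        const = -0.5 * d * np.log(2 * np.pi)
        for k in range(self.n_classes):
            delta = X - self.means_[k]
            z = np.linalg.solve(self._chols[k], delta.T)  # [d, n]
            maha = np.sum(z * z, axis=0)
            out[:, k] = const - 0.5 * self._logdets[k] - 0.5 * maha
        return out

    def predict_indices(self, X: np.ndarray) -> np.ndarray:
        return np.argmax(self.log_likelihood(X), axis=1)
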