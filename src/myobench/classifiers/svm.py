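"""Soft-margin SVM with a polynomial kernel, one-vs-one with majority vote.

Kernel: ``K(u, v) = (gamma * <u, v> + coef0) ** degree`` with degree 3,
coef0 1 and ``gamma = 1/d`` by default.  Each binary subproblem is solved by
sequential minimal optimization (SMO) on the dual with maximal-violating-pair
working-set selection and an exact two-variable update; the stopping rule is
the standard KKT gap ``m - M < tol``.  Vote ties are broken by the summed
signed decision values, then the lowest class index.
"""

from __future__ import annotations

import numpy as np

from ..session_io import ConfigError
from .base import register
from .gaussian import _vote_argmax


def _poly_kernel(A: np.ndarray, B: np.ndarray, gamma: float, coef0: float, degree: int) -> np.ndarray:
    return (gamma * (A @ B.T) + coef0) ** degree


class _BinarySVM:
    """One soft-margin subproblem solved by SMO; labels in {-1, +1}."""

    def __init__(self, C: float, gamma: float, coef0: float, degree: int,
                 tol: float = 1e-3, max_iter: int = 200_000):
        self.C, self.gamma, self.coef0, self.degree = C, gamma, coef0, degree
        self.tol, self.max_iter = tol, max_iter

    def fit(self, X: np.ndarray, y: np.ndarray) -> "_BinarySVM":
        n = X.shape[0]
        K = _poly_kernel(X, X, self.gamma, self.coef0, self.degree)
        alpha = np.zeros(n)
        grad = -np.ones(n)  # G = Q a - e with a = 0
        C = self.C
        yG = None
        for _ in range(self.max_iter):
            yG = -y * grad
            up = ((y > 0) & (alpha < C)) | ((y < 0) & (alpha > 0))
            low = ((y > 0) & (alpha > 0)) | ((y < 0) & (alpha < C))
            if not up.any() or not low.any():
                break
            m_idx = np.flatnonzero(up)[np.argmax(yG[up])]
            M_idx = np.flatnonzero(low)[np.argmin(yG[low])]
            m, M = yG[m_idx], yG[M_idx]
            if m - M < self.tol:
                break
            i, j = m_idx, M_idx
            quad = K[i, i] + K[j, j] - 2.0 * K[i, j]
            quad = max(quad, 1e-12)
            # direction d_i = y_i * t, d_j = -y_j * t
            t = (m - M) / quad
            # box limits on t from both coordinates
            if y[i] > 0:
                t_lo_i, t_hi_i = -alpha[i], C - alpha[i]
            else:
                t_lo_i, t_hi_i = alpha[i] - C, alpha[i]
            if y[j] > 0:
                t_lo_j, t_hi_j = alpha[j] - C, alpha[j]
            else:
                t_lo_j, t_hi_j = -alpha[j], C - alpha[j]
            t = np.clip(t, max(t_lo_i, t_lo_j), min(t_hi_i, t_hi_j))
            if t == 0.0:
                break
            alpha[i] += y[i] * t
            alpha[j] -= y[j] * t
            grad += y * t * (K[:, i] - K[:, j])
        # bias from the final KKT interval
        yG = -y * grad
        up = ((y > 0) & (alpha < C)) | ((y < 0) & (alpha > 0))
        low = ((y > 0) & (alpha > 0)) | ((y < 0) & (alpha < C))
        m = yG[up].max() if up.any() else 0.0
        M = yG[low].min() if low.any() else 0.0
        self.b = (m + M) / 2.0
        sv = alpha > 1e-12
        self.sv_X = X[sv]
        self.sv_coef = (alpha * y)[sv]
        return self

    def decision(self, X: np.ndarray) -> np.ndarray:
        if self.sv_X.shape[0] == 0:
            return np.full(X.shape[0], self.b)
        K = _poly_kernel(X, self.sv_X, self.gamma, self.coef0, self.degree)
        return K @ self.sv_coef + self.b


@register("SVM")
class SvmOneVsOne:
    def __init__(self, n_classes: int, C: float = 1.0, degree: int = 3,
                 coef0: float = 1.0, gamma: float | None = None):
        self.n_classes = n_classes
        self.C, self.degree, self.coef0 = C, degree, coef0
        self.gamma = gamma  # None -> 1/d at fit time
        self.n_features: int | None = None
        self._pairs: list[tuple[int, int]] = []
        self._machines: list[_BinarySVM] = []

    def fit(self, X: np.ndarray, y: np.ndarray, rng=None) -> "SvmOneVsOne":
        self.n_features = X.shape[1]
        gamma = self.gamma if self.gamma is not None else 1.0 / X.shape[1]
        self._gamma_eff = gamma
        self._pairs = [
            (a, b) for a in range(self.n_classes) for b in range(a + 1, self.n_classes)
        ]
        self._machines = []
        for a, b in self._pairs:
            mask = (y == a) | (y == b)
            if not mask.any():
                raise ConfigError(f"no samples for class pair ({a}, {b})")
            Xp = X[mask]
            yp = np.where(y[mask] == a, 1.0, -1.0)
            if np.all(yp > 0) or np.all(yp < 0):
                raise ConfigError(f"class pair ({a}, {b}) lacks one class")
            self._machines.append(
                _BinarySVM(self.C, gamma, self.coef0, self.degree).fit(Xp, yp)
            )
        return self

    def predict_indices(self, X: np.ndarray) -> np.ndarray:
        n = X.shape[0]
        votes = np.zeros((n, self.n_classes))
        margins = np.zeros((n, self.n_classes))
        for (a, b), machine in zip(self._pairs, self._machines):
            d = machine.decision(X)
            win_a = d > 0
            votes[win_a, a] += 1
            votes[~win_a, b] += 1
            margins[:, a] += d
            margins[:, b] -= d
        return _vote_argmax(votes, margins)
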