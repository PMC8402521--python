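"""Supervised self-organizing map on a rectangular grid.

Training vectors are the features concatenated with ``beta * one-hot(label)``
(beta=1).  Stochastic training: 200 epochs, each presenting every training
vector once in a seed-shuffled order; the best-matching unit (BMU) is found on
the full augmented vector and all units are pulled toward the sample with a
Gaussian neighborhood on the grid.  The learning rate decays exponentially
0.5 -> 0.01 and the neighborhood radius from half the larger grid side to 1.

At prediction the BMU is found on the feature part only and the argmax of the
unit's label part is returned.
"""

from __future__ import annotations

import numpy as np

from .base import register


@register("SSOM")
class SupervisedSom:
    def __init__(self, n_classes: int, grid: tuple[int, int] = (8, 8),
                 beta: float = 1.0, epochs: int = 200,
                 lr_start: float = 0.5, lr_end: float = 0.01,
                 radius_end: float = 1.0):
        self.n_classes = n_classes
        self.grid = grid
        self.beta = beta
        self.epochs = epochs
        self.lr_start, self.lr_end = lr_start, lr_end
        self.radius_end = radius_end
        self.n_features: int | None = None
        self.units_: np.ndarray | None = None  # [n_units, d + C]

    def fit(self, X: np.ndarray, y: np.ndarray,
            rng: np.random.Generator | None = None) -> "SupervisedSom":
        rng = rng or np.random.default_rng(0)
        n, d = X.shape
        self.n_features = d
        rows, cols = self.grid
        n_units = rows * cols
        onehot = np.zeros((n, self.n_classes))
        onehot[np.arange(n), y] = self.beta
        V = np.hstack([X, onehot])

        # init units from training samples (deterministic from the seed)
        init_idx = rng.integers(0, n, size=n_units)
        units = V[init_idx].copy()

        gy, gx = np.divmod(np.arange(n_units), cols)
        grid_d2 = (gy[:, None] - gy[None, :]) ** 2 + (gx[:, None] - gx[None, :]) ** 2

        radius_start = max(rows, cols) / 2.0
        E = self.epochs
        for epoch in range(E):
            frac = epoch / max(E - 1, 1)
            lr = self.lr_start * (self.lr_end / self.lr_start) ** frac
            sigma = radius_start * (self.radius_end / radius_start) ** frac
            H = lr * np.exp(-grid_d2 / (2.0 * sigma * sigma))  # [n_units, n_units]
            for i in rng.permutation(n):
                v = V[i]
                diff = v - units
                bmu = int(np.argmin(np.einsum("ij,ij->i", diff, diff)))
                units += H[bmu][:, None] * diff
        self.units_ = units
        return self

    def predict_indices(self, X: np.ndarray) -> np.ndarray:
        feat = self.units_[:, :self.n_features]
        lab = self.units_[:, self.n_features:]
        # BMU on the feature part only
        d2 = (
            np.sum(X * X, axis=1, keepdims=True)
            - 2.0 * X @ feat.T
            + np.sum(feat * feat, axis=1)[None, :]
        )
        bmu = np.argmin(d2, axis=1)
        return np.argmax(lab[bmu], axis=1)
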