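"""Nearest-neighbor classification (K=1, Euclidean metric).

Distance ties are broken by the first training index, which is what a plain
argmin over training order gives.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial.distance import cdist

from ..session_io import ConfigError
from .base import register


@register("KNN")
class NearestNeighbor:
    def __init__(self, n_classes: int, k: int = 1):
        if k != 1:
            raise ConfigError("the benchmark KNN is fixed at K=1")
        self.n_classes = n_classes
        self.n_features: int | None = None
        self._X: np.ndarray | None = None
        self._y: np.ndarray | None = None

    def fit(self, X: np.ndarray, y: np.ndarray, rng=None) -> "NearestNeighbor":
        self.n_features = X.shape[1]
        self._X = X.copy()
        self._y = y.copy()
        return self

    def predict_indices(self, X: np.ndarray) -> np.ndarray:
        out = np.empty(X.shape[0], dtype=np.intp)
        # chunk queries to bound the distance-matrix footprint
        step = 1024
        for i in range(0, X.shape[0], step):
            D = cdist(X[i:i + step], self._X)
            out[i:i + step] = self._y[np.argmin(D, axis=1)]
        return out
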