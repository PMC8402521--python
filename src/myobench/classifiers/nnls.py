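"""Non-negative least-squares classification over training-sample bases.

The training feature vectors form the columns of the basis matrix ``A``.  A
query ``x`` is decomposed as ``min ||A h - x||^2  s.t.  h >= 0``
(Lawson-Hanson active set, via scipy) and labelled with the class of the
training column carrying the largest coefficient — i.e. the sample that
dominates the non-negative reconstruction.  Summing coefficients per class
before the argmax is available behind ``per_class_sum``.

There is no fitting in the traditional sense: the cost is paid at every
prediction, which is exactly why this classifier is the slowest one at test
time.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import nnls

from .base import register


@register("NMF")
class NnlsClassifier:
    def __init__(self, n_classes: int, per_class_sum: bool = False):
        self.n_classes = n_classes
        self.per_class_sum = per_class_sum
        self.n_features: int | None = None
        self._A: np.ndarray | None = None  # [d, n_train]
        self._y: np.ndarray | None = None

    def fit(self, X: np.ndarray, y: np.ndarray, rng=None) -> "NnlsClassifier":
        self.n_features = X.shape[1]
        self._A = np.ascontiguousarray(X.T)
        self._y = y.copy()
        return self

    def coefficients(self, x: np.ndarray) -> np.ndarray:
        h, _ = nnls(self._A, x)
        return h

    def predict_indices(self, X: np.ndarray) -> np.ndarray:
        out = np.empty(X.shape[0], dtype=np.intp)
        for i in range(X.shape[0]):
            h = self.coefficients(X[i])
            if self.per_class_sum:
                sums = np.bincount(self._y, weights=h, minlength=self.n_classes)
                out[i] = int(np.argmax(sums))
            else:
                out[i] = int(self._y[np.argmax(h)])
        return out
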