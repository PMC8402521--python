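"""Regulatory feedback network (negative-feedback / shunting inference).

Training is trivial: the weight matrix holds the per-class mean of the
(unitary-normalized, hence non-negative) training features.  Inference is an
iterative fixed point in which output activations feed back to suppress the
inputs that already "explain" them:

    y_a  <-  (y_a / sum_i w_ai) * sum_i w_ai * x_i / f_i,
    f_i  =   sum_a y_a * w_ai   (floored at eps)

run for T=25 iterations from a uniform start; the predicted class is the
argmax of y.  Inputs are floored at 0 (the shunting ratio form assumes
non-negative drive; unitary normalization guarantees it on training data, and
mild test-time extrapolation below 0 is clamped here, inside the classifier).

With mutually orthogonal class-mean patterns of equal support this update
converges in one step to the normalized pattern match, i.e. nearest-mean
classification.
"""

from __future__ import annotations

import numpy as np

from ..session_io import ConfigError
from .base import register

_EPS = 1e-9


@register("RFN")
class RegulatoryFeedbackNetwork:
    def __init__(self, n_classes: int, n_iterations: int = 25):
        self.n_classes = n_classes
        self.n_iterations = n_iterations
        self.n_features: int | None = None
        self.W_: np.ndarray | None = None  # [n_classes, d]

    def fit(self, X: np.ndarray, y: np.ndarray, rng=None) -> "RegulatoryFeedbackNetwork":
        self.n_features = X.shape[1]
        W = np.empty((self.n_classes, X.shape[1]))
        for k in range(self.n_classes):
            Xk = X[y == k]
            if Xk.shape[0] == 0:
                raise ConfigError(f"class index {k} has no training samples")
            W[k] = Xk.mean(axis=0)
        self.W_ = np.maximum(W, 0.0)
        return self

    def activations(self, X: np.ndarray) -> np.ndarray:
        """Final output activations ``[n, n_classes]`` after T iterations."""
        W = self.W_
        Xc = np.maximum(X, 0.0)
        S = np.maximum(W.sum(axis=1), _EPS)  # [C]
        Y = np.full((X.shape[0], self.n_classes), 1.0 / self.n_classes)
        for _ in range(self.n_iterations):
            F = np.maximum(Y @ W, _EPS)      # [n, d]
            Y = (Y / S[None, :]) * ((Xc / F) @ W.T)
        return Y

    def predict_indices(self, X: np.ndarray) -> np.ndarray:
        return np.argmax(self.activations(X), axis=1)
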