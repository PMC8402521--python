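"""Multilayer perceptron: d -> 16 -> 16 -> C, logistic activations everywhere.

Per-sample ("stochastic") backpropagation on the squared error against one-hot
targets, learning rate 0.1, momentum 0.1, at most 200 epochs with the sample
order reshuffled from the seed each epoch.  Training stops early when the
validation misclassification rate fails to improve for 10 consecutive epochs;
the weights of the best validation epoch are kept.  Weights and biases are
initialized uniform(-0.5, 0.5) from the seed.
"""

from __future__ import annotations

import numpy as np

from .base import register


def _logistic(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-z))


@register("MLP")
class Mlp:
    def __init__(self, n_classes: int, hidden: tuple[int, int] = (16, 16),
                 learning_rate: float = 0.1, momentum: float = 0.1,
                 max_epochs: int = 200, patience: int = 10):
        self.n_classes = n_classes
        self.hidden = hidden
        self.learning_rate = learning_rate
        self.momentum = momentum
        self.max_epochs = max_epochs
        self.patience = patience
        self.n_features: int | None = None
        self.epochs_run_: int = 0

    def _init_weights(self, d: int, rng: np.random.Generator) -> None:
        sizes = [d, *self.hidden, self.n_classes]
        self._W = [rng.uniform(-0.5, 0.5, size=(sizes[i], sizes[i + 1]))
                   for i in range(len(sizes) - 1)]
        self._b = [rng.uniform(-0.5, 0.5, size=sizes[i + 1])
                   for i in range(len(sizes) - 1)]
        self._vW = [np.zeros_like(w) for w in self._W]
        self._vb = [np.zeros_like(b) for b in self._b]

    def _forward(self, X: np.ndarray) -> list[np.ndarray]:
        acts = [X]
        a = X
        for W, b in zip(self._W, self._b):
            a = _logistic(a @ W + b)
            acts.append(a)
        return acts

    def fit(self, X: np.ndarray, y: np.ndarray,
            rng: np.random.Generator | None = None,
            val_X: np.ndarray | None = None,
            val_y: np.ndarray | None = None) -> "Mlp":
        rng = rng or np.random.default_rng(0)
        n, d = X.shape
        self.n_features = d
        self._init_weights(d, rng)
        T = np.zeros((n, self.n_classes))
        T[np.arange(n), y] = 1.0
        lr, mom = self.learning_rate, self.momentum

        best_err = np.inf
        best_weights = None
        stall = 0
        for epoch in range(self.max_epochs):
            self.epochs_run_ = epoch + 1
            order = rng.permutation(n)
            for i in order:
                acts = self._forward(X[i:i + 1])
                delta = (acts[-1] - T[i:i + 1]) * acts[-1] * (1.0 - acts[-1])
                for layer in range(len(self._W) - 1, -1, -1):
                    gW = acts[layer].T @ delta
                    gb = delta[0]
                    if layer > 0:
                        delta = (delta @ self._W[layer].T) * acts[layer] * (1.0 - acts[layer])
                    self._vW[layer] = mom * self._vW[layer] - lr * gW
                    self._vb[layer] = mom * self._vb[layer] - lr * gb
                    self._W[layer] += self._vW[layer]
                    self._b[layer] += self._vb[layer]
            if val_X is not None and val_X.shape[0] > 0:
                err = np.mean(self.predict_indices(val_X) != val_y)
                if err < best_err - 1e-12:
                    best_err = err
                    best_weights = ([w.copy() for w in self._W],
                                    [b.copy() for b in self._b])
                    stall = 0
                else:
                    stall += 1
                    if stall >= self.patience:
                        break
        if best_weights is not None:
            self._W, self._b = best_weights
        return self

    def predict_indices(self, X: np.ndarray) -> np.ndarray:
        return np.argmax(self._forward(X)[-1], axis=1)
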