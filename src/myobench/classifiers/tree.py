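"""CART decision tree: binary axis-aligned splits minimizing Gini impurity.

Grown until every leaf is pure (or no informative split exists), minimum leaf
size 1, no pruning.  Split ties are broken by the lowest feature index, then
the lowest threshold; leaf majorities tie-break to the lowest class index.
Built iteratively (explicit stack) so deep trees cannot hit the recursion
limit.
"""

from __future__ import annotations

import numpy as np

from .base import register


@register("DT")
class CartTree:
    def __init__(self, n_classes: int, min_samples_leaf: int = 1):
        self.n_classes = n_classes
        self.min_samples_leaf = min_samples_leaf
        self.n_features: int | None = None
        # flat node arrays: feature<0 marks a leaf whose class is in self._cls
        self._feature: list[int] = []
        self._threshold: list[float] = []
        self._left: list[int] = []
        self._right: list[int] = []
        self._cls: list[int] = []

    def _new_node(self) -> int:
        self._feature.append(-1)
        self._threshold.append(0.0)
        self._left.append(-1)
        self._right.append(-1)
        self._cls.append(-1)
        return len(self._feature) - 1

    def fit(self, X: np.ndarray, y: np.ndarray, rng=None) -> "CartTree":
        self.n_features = X.shape[1]
        root = self._new_node()
        stack = [(root, np.arange(X.shape[0]))]
        while stack:
            node, idx = stack.pop()
            yk = y[idx]
            counts = np.bincount(yk, minlength=self.n_classes)
            if counts.max() == len(idx):  # pure
                self._cls[node] = int(yk[0])
                continue
            split = self._best_split(X[idx], yk)
            if split is None:
                self._cls[node] = int(np.argmax(counts))  # majority, lowest index wins
                continue
            f, thr = split
            go_left = X[idx, f] <= thr
            self._feature[node] = f
            self._threshold[node] = thr
            left = self._new_node()
            right = self._new_node()
            self._left[node] = left
            self._right[node] = right
            stack.append((left, idx[go_left]))
            stack.append((right, idx[~go_left]))
        self._f_arr = np.asarray(self._feature)
        self._t_arr = np.asarray(self._threshold)
        self._l_arr = np.asarray(self._left)
        self._r_arr = np.asarray(self._right)
        self._c_arr = np.asarray(self._cls)
        return self

    def _best_split(self, X: np.ndarray, y: np.ndarray) -> tuple[int, float] | None:
        """Lowest-weighted-Gini (feature, threshold) or None if uninformative."""
        n, d = X.shape
        onehot = np.zeros((n, self.n_classes))
        onehot[np.arange(n), y] = 1.0
        best = None
        best_score = np.inf
        min_leaf = self.min_samples_leaf
        for f in range(d):
            order = np.argsort(X[:, f], kind="stable")
            xs = X[order, f]
            cum = np.cumsum(onehot[order], axis=0)  # [n, C]
            # candidate split after position i (left = i+1 samples), only where
            # consecutive values differ
            valid = np.nonzero(xs[1:] > xs[:-1])[0]
            if valid.size == 0:
                continue
            left_n = valid + 1
            right_n = n - left_n
            keep = (left_n >= min_leaf) & (right_n >= min_leaf)
            valid, left_n, right_n = valid[keep], left_n[keep], right_n[keep]
            if valid.size == 0:
                continue
            left_counts = cum[valid]
            right_counts = cum[-1] - left_counts
            gini_l = 1.0 - np.sum((left_counts / left_n[:, None]) ** 2, axis=1)
            gini_r = 1.0 - np.sum((right_counts / right_n[:, None]) ** 2, axis=1)
            score = (left_n * gini_l + right_n * gini_r) / n
            j = int(np.argmin(score))
            if score[j] < best_score - 1e-15:
                best_score = score[j]
                thr = 0.5 * (xs[valid[j]] + xs[valid[j] + 1])
                best = (f, float(thr))
        # a node with distinct values always admits an impurity-decreasing
        # split under Gini; best is None only when all usable values tie
        node_gini = 1.0 - np.sum((np.bincount(y, minlength=self.n_classes) / n) ** 2)
        if best is not None and best_score >= node_gini - 1e-15:
            return None
        return best

    def predict_indices(self, X: np.ndarray) -> np.ndarray:
        n = X.shape[0]
        node = np.zeros(n, dtype=np.intp)
        active = self._f_arr[node] >= 0
        while np.any(active):
            idx = np.nonzero(active)[0]
            nd = node[idx]
            f = self._f_arr[nd]
            go_left = X[idx, f] <= self._t_arr[nd]
            node[idx] = np.where(go_left, self._l_arr[nd], self._r_arr[nd])
            active = self._f_arr[node] >= 0
        return self._c_arr[node]
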