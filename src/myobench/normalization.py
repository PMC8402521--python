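"""Classifier-specific feature normalization.

Four schemes, all fitted on training rows only and applied unchanged to
validation/test data (values outside the training range are *not* clipped —
classifiers must tolerate mild extrapolation; clipping would silently distort
e.g. KNN distances):

- ``midrange2`` — 0-midrange with 2-range: maps training extremes to [-1, 1],
  ``x' = 2*(x - (max+min)/2) / (max - min)``
- ``unitary``  — unitary range: maps training extremes to [0, 1],
  ``x' = (x - min) / (max - min)``
- ``normlog``  — norm-log: shift so the minimum sits at 0, log-compress, and
  rescale to [0, 1]: ``x' = log1p(x - min) / log1p(max - min)``.  This
  realization guarantees the argument of the log is >= 0 on training data and
  maps training extremes exactly to 0 and 1; it is a documented design choice
  (see docs/methods.md), as "norm-log" admits several formulations.  Test
  values below the training minimum use the signed-log extension
  ``-log1p(min - x) / log1p(max - min)`` so the transform stays defined and
  strictly monotone without clipping.
- ``none``     — identity.

Columns that are constant on the training data are degenerate and map to 0
under every non-identity scheme.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .session_io import ConfigError

__all__ = [
    "METHODS",
    "NormalizationParams",
    "fit_normalizer",
    "apply_normalizer",
    "default_method_for",
]

METHODS = ("midrange2", "unitary", "normlog", "none")

# Classifier -> normalization scheme mapping used throughout the benchmark.
_METHOD_BY_CLASSIFIER = {
    "MLP": "midrange2",
    "SVM": "midrange2",
    "NMF": "midrange2",
    "RFN": "unitary",
    "SSOM": "normlog",
    "KNN": "normlog",
    "LDA": "none",
    "MLE": "none",
    "DT": "none",
}


@dataclass
class NormalizationParams:
    method: str
    col_min: np.ndarray | None = None
    col_max: np.ndarray | None = None

    @property
    def degenerate(self) -> np.ndarray:
        """Boolean mask of constant training columns."""
        return self.col_max == self.col_min

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "method": self.method,
            "col_min": None if self.col_min is None else self.col_min.tolist(),
            "col_max": None if self.col_max is None else self.col_max.tolist(),
        }
        text = json.dumps(payload)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, text_or_path: str | Path) -> "NormalizationParams":
        p = Path(str(text_or_path))
        text = p.read_text() if p.exists() else str(text_or_path)
        payload = json.loads(text)
        return cls(
            method=payload["method"],
            col_min=None if payload["col_min"] is None else np.asarray(payload["col_min"]),
            col_max=None if payload["col_max"] is None else np.asarray(payload["col_max"]),
        )


def default_method_for(classifier_name: str) -> str:
    """The normalization scheme attached to each classifier."""
    try:
        return _METHOD_BY_CLASSIFIER[classifier_name]
    except KeyError:
        raise ConfigError(f"unknown classifier {classifier_name!r}") from None


def fit_normalizer(train_X: np.ndarray, method: str) -> NormalizationParams:
    """Learn per-column min/max from training rows only."""
    if method not in METHODS:
        raise ConfigError(f"unknown normalization method {method!r}")
    if method == "none":
        return NormalizationParams(method="none")
    X = np.asarray(train_X, dtype=np.float64)
    if X.ndim != 2 or X.shape[0] < 1:
        raise ConfigError("need at least one training row")
    if not np.isfinite(X).all():
        raise ConfigError("training features contain non-finite values")
    return NormalizationParams(method=method, col_min=X.min(axis=0), col_max=X.max(axis=0))


def apply_normalizer(X: np.ndarray, params: NormalizationParams) -> np.ndarray:
    """Apply a fitted scheme; degenerate columns map to 0, no clipping."""
    X = np.asarray(X, dtype=np.float64)
    single = X.ndim == 1
    if single:
        X = X[None, :]
    if params.method == "none":
        return X[0].copy() if single else X.copy()
    lo, hi = params.col_min, params.col_max
    if X.shape[1] != lo.shape[0]:
        raise ConfigError(
            f"feature count {X.shape[1]} does not match fitted {lo.shape[0]}"
        )
    span = hi - lo
    ok = span > 0
    safe_span = np.where(ok, span, 1.0)
    if params.method == "midrange2":
        out = 2.0 * (X - (hi + lo) / 2.0) / safe_span
    elif params.method == "unitary":
        out = (X - lo) / safe_span
    elif params.method == "normlog":
        u = X - lo
        out = np.sign(u) * np.log1p(np.abs(u)) / np.log1p(safe_span)
    else:  # pragma: no cover - guarded in fit
        raise ConfigError(f"unknown normalization method {params.method!r}")
    out = np.where(ok, out, 0.0)
    return out[0] if single else out
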