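"""Common train/predict contract for the nine benchmark classifiers.

Every classifier is trained through :func:`train`, which fits the
classifier-specific normalization on the *training* rows only, applies it to
training and validation rows, fits the model, and returns an opaque
:class:`TrainedClassifier` whose ``predict``/``predict_batch`` run the same
normalization before the model.

The MLP consumes the validation set for early stopping; all other classifiers
fold training and validation rows together for fitting, so both sets inform
the fitted state.  The test set never reaches :func:`train`.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field
from pathlib import Path

import joblib
import numpy as np

from ..normalization import (
    NormalizationParams,
    apply_normalizer,
    default_method_for,
    fit_normalizer,
)
from ..session_io import ConfigError

__all__ = [
    "CLASSIFIER_NAMES",
    "ClassifierSpec",
    "TrainedClassifier",
    "train",
    "predict",
    "save_model",
    "load_model",
]

CLASSIFIER_NAMES = ("MLP", "RFN", "SSOM", "LDA", "SVM", "KNN", "MLE", "DT", "NMF")

#: name -> model factory, filled in by the sibling modules at import time.
_REGISTRY: dict = {}

#: classifiers whose fit consumes the validation set separately.
_USES_VALIDATION = {"MLP"}


def register(name: str):
    def deco(cls):
        _REGISTRY[name] = cls
        return cls
    return deco


@dataclass(frozen=True)
class ClassifierSpec:
    """Which classifier to train, with optional hyperparameter overrides."""

    name: str
    params: dict = field(default_factory=dict)
    seed: int = 0
    normalization: str | None = None  # None -> the classifier's default scheme

    def __post_init__(self) -> None:
        if self.name not in CLASSIFIER_NAMES:
            raise ConfigError(f"unknown classifier {self.name!r}")

    @property
    def norm_method(self) -> str:
        return self.normalization or default_method_for(self.name)


@dataclass
class TrainedClassifier:
    """A fitted model with its normalization and class list attached."""

    name: str
    model: object
    classes: list[str]
    norm: NormalizationParams
    train_time_s: float
    spec: ClassifierSpec
    test_time_ms: float | None = None  # measured externally per prediction

    def predict_batch(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=np.float64)
        if X.ndim != 2:
            raise ConfigError("predict_batch expects a 2-D array")
        if self.norm.col_min is not None and X.shape[1] != self.norm.col_min.shape[0]:
            raise ConfigError("feature dimension does not match training")
        Xn = apply_normalizer(X, self.norm)
        if Xn.shape[1] != self.model.n_features:
            raise ConfigError("feature dimension does not match training")
        idx = self.model.predict_indices(Xn)
        return np.asarray([self.classes[i] for i in idx], dtype=object)

    def predict(self, x: np.ndarray) -> str:
        x = np.asarray(x, dtype=np.float64)
        if x.ndim != 1:
            raise ConfigError("predict expects a 1-D feature vector")
        return str(self.predict_batch(x[None, :])[0])


def _encode(y: np.ndarray, classes: list[str]) -> np.ndarray:
    index = {c: i for i, c in enumerate(classes)}
    try:
        return np.asarray([index[v] for v in y], dtype=np.intp)
    except KeyError as exc:  # pragma: no cover
        raise ConfigError(f"label {exc} missing from training classes") from None


def train(
    spec: ClassifierSpec,
    train_X: np.ndarray,
    train_y: np.ndarray,
    val_X: np.ndarray | None = None,
    val_y: np.ndarray | None = None,
) -> TrainedClassifier:
    """Fit one classifier (and its normalization) on training/validation data."""
    train_X = np.asarray(train_X, dtype=np.float64)
    train_y = np.asarray(train_y, dtype=object)
    if train_X.ndim != 2 or train_X.shape[0] != train_y.shape[0]:
        raise ConfigError("train_X must be [n, d] aligned with train_y")
    if not np.isfinite(train_X).all():
        raise ConfigError("training features contain non-finite values")
    classes = sorted(set(train_y.tolist()))
    if len(classes) < 2:
        raise ConfigError("training data must contain at least 2 classes")
    if val_X is not None and val_y is not None and len(val_y):
        val_X = np.asarray(val_X, dtype=np.float64)
        val_y = np.asarray(val_y, dtype=object)
        if not np.isfinite(val_X).all():
            raise ConfigError("validation features contain non-finite values")
        extra = set(val_y.tolist()) - set(classes)
        if extra:
            raise ConfigError(f"validation labels {extra} unseen in training")
    else:
        val_X = val_y = None

    t0 = time.perf_counter()
    norm = fit_normalizer(train_X, spec.norm_method)
    Xn = apply_normalizer(train_X, norm)
    y_idx = _encode(train_y, classes)
    Xn_val = apply_normalizer(val_X, norm) if val_X is not None else None
    yv_idx = _encode(val_y, classes) if val_y is not None else None

    rng = np.random.default_rng(np.random.SeedSequence([int(spec.seed), 0xC1A55]))
    model = _REGISTRY[spec.name](n_classes=len(classes), **spec.params)
    if spec.name in _USES_VALIDATION:
        model.fit(Xn, y_idx, rng=rng, val_X=Xn_val, val_y=yv_idx)
    else:
        if Xn_val is not None:
            Xn = np.vstack([Xn, Xn_val])
            y_idx = np.concatenate([y_idx, yv_idx])
        model.fit(Xn, y_idx, rng=rng)
    train_time = time.perf_counter() - t0
    return TrainedClassifier(
        name=spec.name,
        model=model,
        classes=classes,
        norm=norm,
        train_time_s=train_time,
        spec=spec,
    )


def predict(model: TrainedClassifier, x: np.ndarray) -> str:
    """Predict the class label of a single feature vector."""
    return model.predict(x)


def save_model(model: TrainedClassifier, path: str | Path) -> None:
    joblib.dump(model, path)


def load_model(path: str | Path) -> TrainedClassifier:
    return joblib.load(path)
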