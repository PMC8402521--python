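"""Offline evaluation: 40/20/40 split, repeated randomized cross-validation.

The feature windows are split per class (stratified) into 40% training, 20%
validation and 40% testing; the whole procedure is repeated (ten times by
default) with fresh seed-derived permutations, and accuracy is computed on
the test rows only.  Confusion counts are pooled across repetitions.

Train and per-prediction test wall-clock times are recorded as metadata; they
are hardware-dependent and never enter any statistical claim here.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .classifiers import ClassifierSpec, TrainedClassifier, train
from .features import FeatureMatrix
from .session_io import ConfigError

__all__ = ["Split", "OfflineResult", "split_data", "cross_validate", "confusion_matrix"]


@dataclass(frozen=True)
class Split:
    train_idx: np.ndarray
    val_idx: np.ndarray
    test_idx: np.ndarray
    fractions: tuple[float, float, float]
    seed: int


def split_data(
    labels: np.ndarray,
    fractions: tuple[float, float, float] = (0.4, 0.2, 0.4),
    seed: int = 0,
    stratified: bool = True,
) -> Split:
    """Random stratified train/validation/test split of window indices.

    Per class: ``n_train = round(f_train * n_c)``, ``n_val = round(f_val *
    n_c)``, remainder to test.  Classes with fewer than 3 windows cannot
    populate all three sets and are rejected.
    """
    labels = np.asarray(labels, dtype=object)
    if not np.isclose(sum(fractions), 1.0):
        raise ConfigError("fractions must sum to 1")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x5D117]))
    n = len(labels)
    if stratified:
        groups = [np.flatnonzero(labels == c) for c in sorted(set(labels.tolist()))]
    else:
        groups = [np.arange(n)]
    tr, va, te = [], [], []
    for idx in groups:
        if stratified and len(idx) < 3:
            raise ConfigError(
                f"class {labels[idx[0]]!r} has only {len(idx)} windows (< 3)"
            )
        perm = rng.permutation(idx)
        n_c = len(perm)
        n_tr = int(round(fractions[0] * n_c))
        n_va = int(round(fractions[1] * n_c))
        tr.append(perm[:n_tr])
        va.append(perm[n_tr:n_tr + n_va])
        te.append(perm[n_tr + n_va:])
    return Split(
        train_idx=np.concatenate(tr),
        val_idx=np.concatenate(va),
        test_idx=np.concatenate(te),
        fractions=tuple(fractions),
        seed=int(seed),
    )


def confusion_matrix(
    true_labels: np.ndarray, predicted_labels: np.ndarray, class_order: list[str]
) -> np.ndarray:
    """Counts with rows = true class, columns = predicted class."""
    true_labels = np.asarray(true_labels, dtype=object)
    predicted_labels = np.asarray(predicted_labels, dtype=object)
    if len(true_labels) != len(predicted_labels):
        raise ConfigError("label vectors differ in length")
    index = {c: i for i, c in enumerate(class_order)}
    M = np.zeros((len(class_order), len(class_order)), dtype=np.int64)
    for t, p in zip(true_labels, predicted_labels):
        if t not in index or p not in index:
            raise ConfigError(f"label {t!r} or {p!r} not in class order")
        M[index[t], index[p]] += 1
    return M


@dataclass
class OfflineResult:
    classifier: str
    accuracies_pct: list[float]
    confusion: np.ndarray
    class_order: list[str]
    train_time_s: float
    test_time_ms: float
    models: list[TrainedClassifier] = field(default_factory=list, repr=False)

    @property
    def mean_accuracy_pct(self) -> float:
        return float(np.mean(self.accuracies_pct))

    @property
    def sd_accuracy_pct(self) -> float:
        return float(np.std(self.accuracies_pct, ddof=1)) if len(self.accuracies_pct) > 1 else 0.0

    @property
    def per_class_accuracy_pct(self) -> pd.Series:
        row_sums = self.confusion.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            acc = np.where(row_sums > 0, np.diag(self.confusion) / row_sums * 100.0, np.nan)
        return pd.Series(acc, index=self.class_order)


def cross_validate(
    spec: ClassifierSpec,
    features: FeatureMatrix,
    reps: int = 10,
    seed: int = 0,
    fractions: tuple[float, float, float] = (0.4, 0.2, 0.4),
    stratified: bool = True,
    keep_models: bool = False,
) -> OfflineResult:
    """Repeated randomized 40/20/40 evaluation of one classifier."""
    X, y = features.X, features.labels
    class_order = features.classes
    accuracies: list[float] = []
    confusion = np.zeros((len(class_order), len(class_order)), dtype=np.int64)
    train_times: list[float] = []
    test_times_ms: list[float] = []
    models: list[TrainedClassifier] = []
    for rep in range(reps):
        split = split_data(y, fractions, seed=seed * 1000 + rep, stratified=stratified)
        try:
            model = train(
                spec,
                X[split.train_idx], y[split.train_idx],
                X[split.val_idx], y[split.val_idx],
            )
        except Exception as exc:
            raise RuntimeError(f"training failed at repetition {rep}: {exc}") from exc
        t0 = time.perf_counter()
        pred = model.predict_batch(X[split.test_idx])
        elapsed = time.perf_counter() - t0
        truth = y[split.test_idx]
        accuracies.append(float(np.mean(pred == truth) * 100.0))
        confusion += confusion_matrix(truth, pred, class_order)
        train_times.append(model.train_time_s)
        test_times_ms.append(elapsed / max(len(truth), 1) * 1000.0)
        model.test_time_ms = test_times_ms[-1]
        if keep_models:
            models.append(model)
    return OfflineResult(
        classifier=spec.name,
        accuracies_pct=accuracies,
        confusion=confusion,
        class_order=class_order,
        train_time_s=float(np.mean(train_times)),
        test_time_ms=float(np.mean(test_times_ms)),
        models=models,
    )
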