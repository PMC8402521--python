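"""Segmentation and Hudgins time-domain feature extraction.

Contractions are trimmed to their central portion (15% dropped at each end by
default, keeping the middle 70%), then cut into overlapping windows (200 ms
with 50 ms increments by default).  Each window yields, per channel, the
Hudgins set:

- MAV, mean absolute value: ``(1/N) * sum |x_k|``
- ZC, zero crossings: sign changes of the amplitude, with an optional
  amplitude dead-zone threshold; zeros inherit the previous nonzero sign
- SSC, slope sign changes: interior points where the slope changes sign,
  with an optional dead-zone on the larger adjacent step
- WL, waveform length: ``sum |x_{k+1} - x_k|``

Features are laid out channel-major: ``ch1:(MAV,ZC,SSC,WL), ch2:(...), ...``,
so four channels give the classic 16-dimensional feature vector.

Windows never straddle segment boundaries: each schedule segment is windowed
independently so every window has an unambiguous label.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view

from .session_io import REST_LABEL, ConfigError, RecordingSession

__all__ = [
    "WindowSpec",
    "FeatureMatrix",
    "FEATURE_NAMES",
    "trim_contraction",
    "window_signal",
    "mav",
    "zero_crossings",
    "slope_sign_changes",
    "waveform_length",
    "extract_features",
]

FEATURE_NAMES = ("mav", "zc", "ssc", "wl")


@dataclass(frozen=True)
class WindowSpec:
    window_ms: float = 200.0
    increment_ms: float = 50.0
    trim_fraction_each_side: float = 0.15
    zc_threshold: float = 0.0
    ssc_threshold: float = 0.0

    def __post_init__(self) -> None:
        if not 0 < self.increment_ms <= self.window_ms:
            raise ConfigError("require 0 < increment_ms <= window_ms")
        if not 0 <= self.trim_fraction_each_side < 0.5:
            raise ConfigError("require 0 <= trim_fraction_each_side < 0.5")

    def window_samples(self, fs: float) -> int:
        return int(round(self.window_ms * fs / 1000.0))

    def increment_samples(self, fs: float) -> int:
        return int(round(self.increment_ms * fs / 1000.0))


def trim_contraction(segment: np.ndarray, trim_fraction_each_side: float) -> np.ndarray:
    """Central portion of a contraction: drop ``floor(n*fraction)`` samples per side."""
    n = segment.shape[0]
    k = int(np.floor(n * trim_fraction_each_side))
    return segment[k:n - k]


def window_signal(
    signal: np.ndarray, fs: float, spec: WindowSpec
) -> tuple[np.ndarray, np.ndarray]:
    """Overlapping windows of a [n_samples, n_channels] signal.

    Window ``i`` covers samples ``[i*inc, i*inc + win)``; the returned
    timestamps are window-end times ``(i*inc + win)/fs``.  Returns
    ``(windows[n_windows, win, n_channels], end_times_s)``.
    """
    signal = np.asarray(signal, dtype=np.float64)
    if signal.ndim == 1:
        signal = signal[:, None]  # single channel
    win = spec.window_samples(fs)
    inc = spec.increment_samples(fs)
    n = signal.shape[0]
    if n < win:
        raise ConfigError(f"signal of {n} samples is shorter than one {win}-sample window")
    views = sliding_window_view(signal, win, axis=0)[::inc]  # [n_w, n_ch, win]
    windows = np.ascontiguousarray(np.swapaxes(views, 1, 2))  # [n_w, win, n_ch]
    n_windows = windows.shape[0]
    ends = (np.arange(n_windows) * inc + win) / fs
    return windows, ends


# ---------------------------------------------------------------------------
# scalar feature operators (1-D window of one channel)

def mav(x: np.ndarray) -> float:
    x = np.asarray(x, dtype=np.float64)
    if x.size == 0:
        raise ConfigError("empty window")
    return float(np.mean(np.abs(x)))


def zero_crossings(x: np.ndarray, threshold: float = 0.0) -> int:
    """Count sign changes; ``sign(0)`` inherits the previous nonzero sign.

    A change between consecutive samples counts only when the amplitude step
    ``|x_k - x_{k+1}|`` reaches ``threshold``.
    """
    x = np.asarray(x, dtype=np.float64)
    if x.size == 0:
        raise ConfigError("empty window")
    count = 0
    prev_sign = 0.0
    prev_val = x[0]
    for val in x:
        s = np.sign(val)
        if s != 0.0:
            if prev_sign != 0.0 and s != prev_sign and abs(val - prev_val) >= threshold:
                count += 1
            prev_sign = s
        prev_val = val
    return count


def slope_sign_changes(x: np.ndarray, threshold: float = 0.0) -> int:
    """Count interior points where the slope changes sign.

    Point ``k`` counts when ``(x_k - x_{k-1})*(x_k - x_{k+1}) > 0`` and the
    larger adjacent step reaches ``threshold``.
    """
    x = np.asarray(x, dtype=np.float64)
    if x.size < 3:
        raise ConfigError("SSC needs a window of at least 3 samples")
    d1 = x[1:-1] - x[:-2]
    d2 = x[1:-1] - x[2:]
    return int(np.count_nonzero((d1 * d2 > 0) & (np.maximum(np.abs(d1), np.abs(d2)) >= threshold)))


def waveform_length(x: np.ndarray) -> float:
    x = np.asarray(x, dtype=np.float64)
    if x.size < 2:
        raise ConfigError("WL needs a window of at least 2 samples")
    return float(np.sum(np.abs(np.diff(x))))


# ---------------------------------------------------------------------------
# vectorized block path (equivalent to the scalar operators; tested as such)

def _propagated_signs(x: np.ndarray) -> np.ndarray:
    """np.sign with zeros replaced by the previous nonzero sign along axis 0."""
    s = np.sign(x)
    if np.any(s == 0):
        for k in range(1, s.shape[0]):
            zero = s[k] == 0
            if np.any(zero):
                s[k] = np.where(zero, s[k - 1], s[k])
    return s


def features_block(windows: np.ndarray, spec: WindowSpec) -> np.ndarray:
    """Hudgins features for a stack of windows ``[n_w, win, n_ch]``.

    Returns ``[n_w, 4*n_ch]`` in channel-major order.
    """
    w = np.asarray(windows, dtype=np.float64)
    n_w, win, n_ch = w.shape
    mav_f = np.mean(np.abs(w), axis=1)
    wl_f = np.sum(np.abs(np.diff(w, axis=1)), axis=1)

    s = _propagated_signs(np.swapaxes(w, 0, 1))  # [win, n_w, n_ch]
    xs = np.swapaxes(w, 0, 1)
    step = np.abs(xs[1:] - xs[:-1])
    change = (s[1:] != s[:-1]) & (s[:-1] != 0) & (s[1:] != 0) & (step >= spec.zc_threshold)
    zc_f = np.count_nonzero(change, axis=0).astype(np.float64)

    d1 = xs[1:-1] - xs[:-2]
    d2 = xs[1:-1] - xs[2:]
    ssc_hit = (d1 * d2 > 0) & (np.maximum(np.abs(d1), np.abs(d2)) >= spec.ssc_threshold)
    ssc_f = np.count_nonzero(ssc_hit, axis=0).astype(np.float64)

    out = np.empty((n_w, 4 * n_ch))
    for c in range(n_ch):
        out[:, 4 * c + 0] = mav_f[:, c]
        out[:, 4 * c + 1] = zc_f[:, c]
        out[:, 4 * c + 2] = ssc_f[:, c]
        out[:, 4 * c + 3] = wl_f[:, c]
    return out


@dataclass
class FeatureMatrix:
    """Per-window feature vectors with labels and window-end timestamps."""

    X: np.ndarray  # [n_windows, 4*n_channels]
    labels: np.ndarray  # class name per window
    window_end_s: np.ndarray
    feature_order: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=np.float64)
        self.labels = np.asarray(self.labels, dtype=object)
        self.window_end_s = np.asarray(self.window_end_s, dtype=np.float64)
        if not self.feature_order:
            n_ch = self.X.shape[1] // 4
            self.feature_order = tuple(
                f"ch{c + 1}_{name}" for c in range(n_ch) for name in FEATURE_NAMES
            )
        if not np.isfinite(self.X).all():
            raise ConfigError("feature matrix contains non-finite values")

    @property
    def n_windows(self) -> int:
        return self.X.shape[0]

    @property
    def classes(self) -> list[str]:
        return sorted(set(self.labels.tolist()))

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.X, columns=list(self.feature_order))
        df.insert(0, "label", self.labels)
        df.insert(1, "window_end_s", self.window_end_s)
        return df

    def to_csv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "FeatureMatrix":
        df = pd.read_csv(path)
        return cls(
            X=df.drop(columns=["label", "window_end_s"]).to_numpy(dtype=np.float64),
            labels=df["label"].to_numpy(dtype=object),
            window_end_s=df["window_end_s"].to_numpy(dtype=np.float64),
            feature_order=tuple(c for c in df.columns if c not in ("label", "window_end_s")),
        )


def extract_features(
    session: RecordingSession,
    spec: WindowSpec = WindowSpec(),
    include_rest: bool = True,
) -> FeatureMatrix:
    """Trim, window and featurize every usable segment of a session.

    Contraction segments are trimmed by ``trim_fraction_each_side`` then
    windowed; rest segments (when ``include_rest``) are windowed untrimmed.
    Timestamps are absolute window-end times within the session.
    """
    X_parts: list[np.ndarray] = []
    labels: list[str] = []
    ends: list[np.ndarray] = []
    for seg in session.schedule:
        if seg.label == REST_LABEL and not include_rest:
            continue
        chunk = session.signal[seg.start:seg.end]
        offset = seg.start
        if seg.label != REST_LABEL:
            k = int(np.floor(chunk.shape[0] * spec.trim_fraction_each_side))
            chunk = trim_contraction(chunk, spec.trim_fraction_each_side)
            offset += k
        windows, t = window_signal(chunk, session.fs, spec)
        X_parts.append(features_block(windows, spec))
        labels.extend([seg.label] * windows.shape[0])
        ends.append(t + offset / session.fs)
    if not X_parts:
        raise ConfigError("no usable segments in schedule")
    return FeatureMatrix(
        X=np.vstack(X_parts),
        labels=np.asarray(labels, dtype=object),
        window_end_s=np.concatenate(ends),
    )
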