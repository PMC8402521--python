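"""Recording-session data model and file I/O.

A *session* is one multi-channel surface-EMG recording together with its
labelled schedule of contraction and rest segments.  The on-disk format is a
plain multichannel WAV (float32) or a headerless CSV (one column per channel)
plus a JSON sidecar (same basename, ``.json``) carrying the sampling rate, the
schedule and free-form metadata.

Sample indexing is 0-based with half-open segments ``[start, end)``; times in
seconds are ``sample / fs``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import wavfile

__all__ = [
    "DEFAULT_MOVEMENTS",
    "REST_LABEL",
    "ConfigError",
    "FormatError",
    "ProtocolConfig",
    "Segment",
    "RecordingSession",
    "build_schedule",
    "load_session",
    "save_session",
]

#: The ten hand/wrist movement classes evaluated by the benchmark.
DEFAULT_MOVEMENTS = (
    "open hand",
    "close hand",
    "flex hand",
    "extend hand",
    "pronation",
    "supination",
    "side grip",
    "fine grip",
    "agree",
    "pointer",
)

#: Label used for relaxation periods (trained as an additional class by default).
REST_LABEL = "rest"


class ConfigError(ValueError):
    """Invalid protocol or generator configuration."""


class FormatError(ValueError):
    """A session file or object violates a structural invariant."""


@dataclass(frozen=True)
class Segment:
    """One labelled, half-open ``[start, end)`` stretch of samples."""

    label: str
    start: int
    end: int

    @property
    def n_samples(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class ProtocolConfig:
    """Recording protocol: which movements, held how long, repeated how often.

    Defaults mirror the benchmark protocol: ten movements, 3 s contraction
    followed by 3 s relaxation, three repetitions each (18 s of data per
    motion), 4 bipolar channels sampled at 1000 Hz, with rest trained as an
    eleventh class.
    """

    movements: tuple[str, ...] = DEFAULT_MOVEMENTS
    contraction_s: float = 3.0
    relax_s: float = 3.0
    repetitions: int = 3
    fs: float = 1000.0
    n_channels: int = 4
    include_rest_class: bool = True

    def __post_init__(self) -> None:
        if not self.movements:
            raise ConfigError("at least one movement is required")
        if len(set(self.movements)) != len(self.movements):
            raise ConfigError("movement names must be unique")
        if REST_LABEL in self.movements:
            raise ConfigError(f"{REST_LABEL!r} is reserved for relaxation segments")
        if self.contraction_s <= 0:
            raise ConfigError("contraction_s must be positive")
        if self.relax_s < 0:
            raise ConfigError("relax_s must be non-negative")
        if self.repetitions < 1:
            raise ConfigError("repetitions must be >= 1")
        if self.fs <= 0:
            raise ConfigError("fs must be positive")
        if self.n_channels < 1:
            raise ConfigError("n_channels must be >= 1")

    @property
    def contraction_samples(self) -> int:
        return int(round(self.contraction_s * self.fs))

    @property
    def relax_samples(self) -> int:
        return int(round(self.relax_s * self.fs))

    @property
    def classes(self) -> tuple[str, ...]:
        """All trainable class labels (movements plus rest when enabled)."""
        if self.include_rest_class:
            return self.movements + (REST_LABEL,)
        return self.movements


def build_schedule(protocol: ProtocolConfig) -> list[Segment]:
    """Lay out the contraction/rest schedule for one offline recording trial.

    For each movement in the listed order: ``repetitions`` pairs of a
    contraction segment followed by a rest segment.  Total length is exactly
    ``n_movements * repetitions * (contraction_s + relax_s) * fs`` samples.
    """
    segments: list[Segment] = []
    cursor = 0
    c, r = protocol.contraction_samples, protocol.relax_samples
    for movement in protocol.movements:
        for _ in range(protocol.repetitions):
            segments.append(Segment(movement, cursor, cursor + c))
            cursor += c
            if r > 0:
                segments.append(Segment(REST_LABEL, cursor, cursor + r))
                cursor += r
    return segments


@dataclass
class RecordingSession:
    """A validated multi-channel recording with its labelled schedule."""

    signal: np.ndarray  # [n_samples, n_channels], float
    fs: float
    schedule: list[Segment]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=np.float64)
        if self.signal.ndim != 2:
            raise FormatError("signal must be a 2-D [n_samples, n_channels] array")
        self.validate()

    @property
    def n_samples(self) -> int:
        return self.signal.shape[0]

    @property
    def n_channels(self) -> int:
        return self.signal.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def validate(self) -> None:
        if self.fs <= 0:
            raise FormatError("fs must be positive")
        if not np.isfinite(self.signal).all():
            raise FormatError("signal contains non-finite samples")
        if not self.schedule:
            raise FormatError("schedule is empty")
        prev_end = 0
        for seg in self.schedule:
            if seg.start < prev_end:
                raise FormatError(f"segments overlap or are unsorted at {seg}")
            if seg.end <= seg.start:
                raise FormatError(f"empty or inverted segment {seg}")
            if seg.end > self.n_samples:
                raise FormatError(
                    f"segment {seg} ends beyond signal length {self.n_samples}"
                )
            prev_end = seg.end

    def movement_labels(self) -> list[str]:
        """Distinct non-rest labels in schedule order of first appearance."""
        seen: list[str] = []
        for seg in self.schedule:
            if seg.label != REST_LABEL and seg.label not in seen:
                seen.append(seg.label)
        return seen

    def with_signal(self, signal: np.ndarray) -> "RecordingSession":
        return replace(self, signal=signal)


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".json")


def save_session(session: RecordingSession, path: str | Path) -> None:
    """Write a session as ``.wav`` (float32) or ``.csv`` plus a JSON sidecar.

    The format is chosen from the file extension.  ``load_session`` inverts
    this: the schedule round-trips exactly, the signal to float32 precision
    for WAV and full double precision for CSV.
    """
    path = Path(path)
    session.validate()
    if path.suffix.lower() == ".wav":
        wavfile.write(path, int(round(session.fs)), session.signal.astype(np.float32))
    elif path.suffix.lower() == ".csv":
        pd.DataFrame(session.signal).to_csv(path, header=False, index=False, float_format="%.17g")
    else:
        raise FormatError(f"unsupported session format {path.suffix!r} (use .wav or .csv)")
    sidecar = {
        "fs": session.fs,
        "channels": session.n_channels,
        "schedule": [
            {"label": s.label, "start": s.start, "end": s.end} for s in session.schedule
        ],
        "metadata": session.metadata,
    }
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=1))


def load_session(path: str | Path) -> RecordingSession:
    """Read a session written by :func:`save_session` and validate it."""
    path = Path(path)
    sidecar_path = _sidecar_path(path)
    if not sidecar_path.exists():
        raise FormatError(f"missing JSON sidecar {sidecar_path}")
    sidecar = json.loads(sidecar_path.read_text())
    if path.suffix.lower() == ".wav":
        fs_file, signal = wavfile.read(path)
        signal = np.atleast_2d(np.asarray(signal, dtype=np.float64))
        if signal.shape[0] == 1:
            signal = signal.T
        if float(fs_file) != float(sidecar["fs"]):
            raise FormatError(
                f"sampling rate mismatch: WAV header {fs_file}, sidecar {sidecar['fs']}"
            )
    elif path.suffix.lower() == ".csv":
        signal = pd.read_csv(path, header=None).to_numpy(dtype=np.float64)
    else:
        raise FormatError(f"unsupported session format {path.suffix!r}")
    if signal.shape[1] != int(sidecar["channels"]):
        raise FormatError(
            f"channel-count mismatch: file has {signal.shape[1]}, "
            f"sidecar says {sidecar['channels']}"
        )
    schedule = [
        Segment(str(s["label"]), int(s["start"]), int(s["end"]))
        for s in sidecar["schedule"]
    ]
    return RecordingSession(
        signal=signal,
        fs=float(sidecar["fs"]),
        schedule=schedule,
        metadata=dict(sidecar.get("metadata", {})),
    )
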