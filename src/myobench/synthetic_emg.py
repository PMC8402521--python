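"""Synthetic surface-EMG generator.

Surface EMG during an isometric contraction is well approximated, for the
purposes of time-domain feature analysis, by amplitude-modulated band-limited
Gaussian noise: the interference pattern of many motor-unit action potential
trains is near-Gaussian, its bandwidth sits in roughly 20-500 Hz, and voluntary
effort modulates its standard deviation per muscle site.  The generator
produces exactly that structure: for sample ``t`` of a segment of movement
``m`` on channel ``c``,

    x[t, c] = e(t) * activation[m, c] * mvc_scale * g[t, c]
              + rest_noise_sd * n[t, c]
              + powerline_amp * sin(2*pi*50*t + phi_c)

where ``g`` and ``n`` are independent zero-mean unit-variance Gaussian
processes band-pass filtered to ``[band_low, band_high]`` (4th-order
Butterworth, forward-backward), ``e(t)`` is a trapezoidal envelope with
``envelope_ramp_s`` onset/offset ramps (0 during rest), and ``phi_c`` is a
per-channel phase fixed by the seed.  Channels are mutually independent; no
cross-talk mixing is applied.

Everything is deterministic given the configuration seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

import numpy as np
from scipy import signal as sps

from .session_io import (
    REST_LABEL,
    ConfigError,
    ProtocolConfig,
    RecordingSession,
    build_schedule,
)

__all__ = [
    "SyntheticConfig",
    "SignalStream",
    "default_activation",
    "generate_session",
    "generate_stream",
]

# Effective spread cap: activation rows are 0.5 +- 0.125*min(separability, _SEP_CAP)
# per coordinate, so entries stay inside [0, 1] without clipping and the mean
# pairwise row distance is exactly proportional to min(separability, _SEP_CAP).
_SEP_CAP = 4.0


def default_activation(
    n_movements: int, n_channels: int, separability: float = 1.0, seed: int = 0
) -> np.ndarray:
    """Per-movement, per-channel contraction amplitudes in [0, 1].

    Rows emulate distinct muscle-synergy patterns.  They are a deterministic
    function of ``seed``; the mean pairwise Euclidean row distance is
    monotonically non-decreasing in ``separability`` and all rows coincide at
    ``separability == 0``.
    """
    if n_movements < 1 or n_channels < 1:
        raise ConfigError("n_movements and n_channels must be >= 1")
    if separability < 0:
        raise ConfigError("separability must be >= 0")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x5E9]))
    directions = rng.uniform(-1.0, 1.0, size=(n_movements, n_channels))
    scale = 0.125 * min(float(separability), _SEP_CAP)
    return np.clip(0.5 + scale * directions, 0.0, 1.0)


@dataclass
class SyntheticConfig:
    """Generator configuration; defaults reproduce the benchmark protocol."""

    protocol: ProtocolConfig = field(default_factory=ProtocolConfig)
    activation: np.ndarray | None = None  # [n_movements, n_channels] in [0, 1]
    mvc_scale: float = 1.0
    rest_noise_sd: float = 0.02
    band_low_hz: float = 20.0
    band_high_hz: float = 500.0
    powerline_amp: float = 0.0
    envelope_ramp_s: float = 0.25
    separability: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.band_low_hz <= 0 or self.band_low_hz >= self.band_high_hz:
            raise ConfigError("require 0 < band_low_hz < band_high_hz")
        if self.band_low_hz >= self.protocol.fs / 2:
            raise ConfigError("band_low_hz must be below Nyquist")
        if self.rest_noise_sd < 0:
            raise ConfigError("rest_noise_sd must be >= 0")
        if self.activation is None:
            self.activation = default_activation(
                len(self.protocol.movements),
                self.protocol.n_channels,
                self.separability,
                self.seed,
            )
        self.activation = np.asarray(self.activation, dtype=np.float64)
        expected = (len(self.protocol.movements), self.protocol.n_channels)
        if self.activation.shape != expected:
            raise ConfigError(
                f"activation shape {self.activation.shape} != {expected}"
            )
        if self.activation.min() < 0 or self.activation.max() > 1:
            raise ConfigError("activation entries must lie in [0, 1]")


def _band_sos(config: SyntheticConfig) -> np.ndarray:
    """Butterworth design for the signal band.

    When ``band_high_hz`` reaches the Nyquist frequency (as with the default
    500 Hz at fs=1000 Hz) the band-pass degenerates to a high-pass at
    ``band_low_hz``: the sampled process carries no power above Nyquist.
    """
    fs = config.protocol.fs
    nyq = fs / 2.0
    if config.band_high_hz >= nyq:
        return sps.butter(4, config.band_low_hz, btype="highpass", fs=fs, output="sos")
    return sps.butter(
        4, [config.band_low_hz, config.band_high_hz], btype="bandpass", fs=fs, output="sos"
    )


def _bandlimited_noise(
    rng: np.random.Generator, n_samples: int, n_channels: int, sos: np.ndarray
) -> np.ndarray:
    """Zero-mean, unit-variance Gaussian noise filtered to the signal band."""
    white = rng.standard_normal((n_samples, n_channels))
    x = sps.sosfiltfilt(sos, white, axis=0)
    x -= x.mean(axis=0)
    sd = x.std(axis=0)
    sd[sd == 0] = 1.0
    return x / sd


def _trapezoid(n: int, ramp: int) -> np.ndarray:
    """Trapezoidal envelope over ``n`` samples with ``ramp``-sample edges."""
    e = np.ones(n)
    ramp = min(ramp, n // 2)
    if ramp > 0:
        edge = np.linspace(0.0, 1.0, ramp, endpoint=False)
        e[:ramp] = edge
        e[n - ramp:] = edge[::-1]
    return e


def _powerline(config: SyntheticConfig, t: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    phases = rng.uniform(0.0, 2 * np.pi, size=config.protocol.n_channels)
    return config.powerline_amp * np.sin(2 * np.pi * 50.0 * t[:, None] + phases[None, :])


def generate_session(config: SyntheticConfig) -> RecordingSession:
    """Generate one complete offline recording trial as a RecordingSession."""
    protocol = config.protocol
    schedule = build_schedule(protocol)
    n_samples = schedule[-1].end
    n_channels = protocol.n_channels
    sos = _band_sos(config)
    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), 1]))

    g = _bandlimited_noise(rng, n_samples, n_channels, sos)
    n = _bandlimited_noise(rng, n_samples, n_channels, sos)

    envelope = np.zeros(n_samples)
    gain = np.zeros((n_samples, n_channels))
    ramp = int(round(config.envelope_ramp_s * protocol.fs))
    movement_index = {m: i for i, m in enumerate(protocol.movements)}
    for seg in schedule:
        if seg.label == REST_LABEL:
            continue
        e = _trapezoid(seg.n_samples, ramp)
        envelope[seg.start:seg.end] = e
        gain[seg.start:seg.end, :] = config.activation[movement_index[seg.label]]

    x = envelope[:, None] * gain * config.mvc_scale * g + config.rest_noise_sd * n
    if config.powerline_amp > 0:
        t = np.arange(n_samples) / protocol.fs
        x = x + _powerline(config, t, rng)

    return RecordingSession(
        signal=x,
        fs=protocol.fs,
        schedule=schedule,
        metadata={
            "generator": "myobench.synthetic_emg",
            "seed": int(config.seed),
            "separability": float(config.separability),
            "mvc_scale": float(config.mvc_scale),
            "rest_noise_sd": float(config.rest_noise_sd),
        },
    )


@dataclass
class SignalStream:
    """A chunked real-time signal with ground-truth labels for audit.

    ``chunks`` yields ``(timestamp_s, array[chunk_samples, n_channels])`` with
    the timestamp at the *end* of the chunk; chunk size equals the windowing
    increment.  ``cue_time_s`` is when the movement cue is shown; the true
    contraction starts ``reaction_delay_s`` later.
    """

    fs: float
    increment_s: float
    cue_time_s: float
    movement: str
    label_changes: list[tuple[float, str]]  # (start_s, label), sorted
    _signal: np.ndarray

    @property
    def n_samples(self) -> int:
        return self._signal.shape[0]

    def label_at(self, t: float) -> str:
        label = self.label_changes[0][1]
        for start, lab in self.label_changes:
            if t >= start:
                label = lab
        return label

    def chunks(self) -> Iterator[tuple[float, np.ndarray]]:
        inc = int(round(self.increment_s * self.fs))
        n_chunks = self.n_samples // inc
        for i in range(n_chunks):
            yield ((i + 1) * inc) / self.fs, self._signal[i * inc:(i + 1) * inc]


def generate_stream(
    config: SyntheticConfig,
    movement: str,
    cue_time_s: float | None = None,
    pre_rest_s: float = 1.0,
    reaction_delay_s: float = 0.3,
    total_s: float = 12.0,
    increment_s: float = 0.05,
) -> SignalStream:
    """Simulate the real-time trial of one cued movement.

    Rest-only signal until ``cue_time_s + reaction_delay_s`` (``cue_time_s``
    defaults to ``pre_rest_s``), then a ramped, sustained contraction of the
    cued movement until ``total_s``.  The virtual subject holds the
    contraction for as long as the trial lasts.
    """
    protocol = config.protocol
    if movement not in protocol.movements:
        raise ConfigError(f"unknown movement {movement!r}")
    if cue_time_s is None:
        cue_time_s = pre_rest_s
    if total_s <= 0.2:
        raise ConfigError("total_s too short for the analysis window to fill")
    onset_s = cue_time_s + reaction_delay_s
    if onset_s >= total_s:
        raise ConfigError("contraction onset falls beyond the end of the stream")

    fs = protocol.fs
    n_samples = int(round(total_s * fs))
    n_channels = protocol.n_channels
    sos = _band_sos(config)
    rng = np.random.default_rng(
        np.random.SeedSequence([int(config.seed), 2, _stable_label_hash(movement)])
    )
    g = _bandlimited_noise(rng, n_samples, n_channels, sos)
    n = _bandlimited_noise(rng, n_samples, n_channels, sos)

    onset = int(round(onset_s * fs))
    ramp = int(round(config.envelope_ramp_s * fs))
    envelope = np.zeros(n_samples)
    hold = n_samples - onset
    envelope[onset:] = 1.0
    if ramp > 0 and hold > 0:
        k = min(ramp, hold)
        envelope[onset:onset + k] = np.linspace(0.0, 1.0, k, endpoint=False)

    row = config.activation[list(protocol.movements).index(movement)]
    x = envelope[:, None] * row[None, :] * config.mvc_scale * g + config.rest_noise_sd * n
    if config.powerline_amp > 0:
        t = np.arange(n_samples) / fs
        x = x + _powerline(config, t, rng)

    return SignalStream(
        fs=fs,
        increment_s=increment_s,
        cue_time_s=cue_time_s,
        movement=movement,
        label_changes=[(0.0, REST_LABEL), (onset_s, movement)],
        _signal=x,
    )


def _stable_label_hash(label: str) -> int:
    """Deterministic small non-negative int from a label (process-independent)."""
    h = 0
    for ch in label:
        h = (h * 31 + ord(ch)) % (2**31 - 1)
    return h
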