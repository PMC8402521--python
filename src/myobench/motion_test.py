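"""Discrete-time simulator of the real-time motion test and its metrics.

Protocol: each of the ten movements is cued three times in a seed-randomized
order.  After the cue the system has up to 10 s to accumulate 20 correct
predictions; a prediction is emitted every 50 ms from the most recent 200 ms
of signal (window-end timestamps), starting as soon as the rolling buffer
first holds a full window.  The timeout clock starts at cue onset.

Scoring per trial (``rest`` predictions never anchor a trial):

- selection time   — first non-rest prediction to first correct prediction
- completion time  — first non-rest prediction to the 20th correct prediction
- real-time accuracy — correct/total predictions between the first non-rest
  prediction and the 20th correct one (recall), as a percentage
- completed        — the 20th correct prediction arrived before timeout

Aggregation: completion rate uses all trials; accuracy, selection time and
completion time are averaged over completed trials only (incomplete trials
leave those metrics undefined).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .classifiers import TrainedClassifier
from .features import WindowSpec, features_block
from .session_io import DEFAULT_MOVEMENTS, REST_LABEL, ConfigError
from .synthetic_emg import SignalStream

__all__ = [
    "MotionTestProtocol",
    "PredictionEvent",
    "TrialRecord",
    "MotionTestResult",
    "run_motion_test",
    "score_trial",
    "aggregate",
]


@dataclass(frozen=True)
class MotionTestProtocol:
    movements: tuple[str, ...] = DEFAULT_MOVEMENTS
    repetitions_per_movement: int = 3
    timeout_s: float = 10.0
    required_correct: int = 20
    prediction_period_s: float = 0.05
    window_s: float = 0.2

    def __post_init__(self) -> None:
        if self.required_correct < 1:
            raise ConfigError("required_correct must be >= 1")
        if self.prediction_period_s > self.window_s:
            raise ConfigError("prediction period must not exceed the window length")


@dataclass(frozen=True)
class PredictionEvent:
    """One classifier output; ``time_s`` is the window-end time relative to cue onset."""

    time_s: float
    label: str


@dataclass
class TrialRecord:
    target: str
    events: list[PredictionEvent]
    completed: bool
    selection_time_s: float | None
    completion_time_s: float | None
    rt_accuracy_pct: float | None


@dataclass
class MotionTestResult:
    trials: list[TrialRecord]
    protocol: MotionTestProtocol

    @property
    def completion_rate_pct(self) -> float:
        return float(np.mean([t.completed for t in self.trials]) * 100.0)

    def overall(self) -> dict:
        return aggregate(self.trials)

    def per_movement(self) -> pd.DataFrame:
        rows = {}
        for movement in sorted({t.target for t in self.trials}):
            rows[movement] = aggregate([t for t in self.trials if t.target == movement])
        return pd.DataFrame(rows).T

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "target": [t.target for t in self.trials],
                "completed": [t.completed for t in self.trials],
                "selection_time_s": [t.selection_time_s for t in self.trials],
                "completion_time_s": [t.completion_time_s for t in self.trials],
                "rt_accuracy_pct": [t.rt_accuracy_pct for t in self.trials],
                "n_events": [len(t.events) for t in self.trials],
            }
        )


def score_trial(
    events: Sequence[PredictionEvent],
    target: str,
    required_correct: int = 20,
    timeout_s: float = 10.0,
    rest_label: str = REST_LABEL,
) -> TrialRecord:
    """Score one trial from its prediction-event timeline.

    Only events at or before the timeout count.  The anchor is the first
    non-rest prediction; a trial with no 20th correct prediction before the
    timeout is incomplete and its time/accuracy metrics stay undefined.
    """
    usable = [e for e in events if e.time_s <= timeout_s + 1e-12]
    anchor_i = next((i for i, e in enumerate(usable) if e.label != rest_label), None)
    record = TrialRecord(
        target=target,
        events=list(events),
        completed=False,
        selection_time_s=None,
        completion_time_s=None,
        rt_accuracy_pct=None,
    )
    if anchor_i is None:
        return record
    anchor_t = usable[anchor_i].time_s
    correct_times = [e.time_s for e in usable[anchor_i:] if e.label == target]
    if len(correct_times) < required_correct:
        return record
    first_correct_t = correct_times[0]
    nth_correct_t = correct_times[required_correct - 1]
    total = sum(1 for e in usable[anchor_i:] if e.time_s <= nth_correct_t + 1e-12)
    record.completed = True
    record.selection_time_s = first_correct_t - anchor_t
    record.completion_time_s = nth_correct_t - anchor_t
    record.rt_accuracy_pct = required_correct / total * 100.0
    return record


def run_motion_test(
    model: TrainedClassifier,
    stream_source: Callable[[str, int], SignalStream],
    protocol: MotionTestProtocol = MotionTestProtocol(),
    seed: int = 0,
    window_spec: WindowSpec = WindowSpec(),
) -> MotionTestResult:
    """Run the full motion test for one trained classifier.

    ``stream_source(movement, trial_seed)`` must return a
    :class:`SignalStream` for the cued movement; the simulator consumes it in
    prediction-period chunks, maintains a rolling analysis window, and emits
    one prediction per chunk once the buffer is full, stopping at the
    ``required_correct``-th correct prediction or at timeout.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x307E57]))
    trial_list = [
        m for m in protocol.movements for _ in range(protocol.repetitions_per_movement)
    ]
    order = rng.permutation(len(trial_list))
    trials: list[TrialRecord] = []
    for trial_no, j in enumerate(order):
        movement = trial_list[j]
        trial_seed = int(rng.integers(0, 2**31 - 1))
        stream = stream_source(movement, trial_seed)
        events = _consume_stream(model, stream, protocol, window_spec)
        trials.append(
            score_trial(events, movement, protocol.required_correct, protocol.timeout_s)
        )
    return MotionTestResult(trials=trials, protocol=protocol)


def _consume_stream(
    model: TrainedClassifier,
    stream: SignalStream,
    protocol: MotionTestProtocol,
    window_spec: WindowSpec,
) -> list[PredictionEvent]:
    win = int(round(protocol.window_s * stream.fs))
    buffer: list[np.ndarray] = []
    buffered = 0
    events: list[PredictionEvent] = []
    n_correct = 0
    for t_end, chunk in stream.chunks():
        buffer.append(chunk)
        buffered += chunk.shape[0]
        if buffered < win:
            continue
        window = np.concatenate(buffer, axis=0)[-win:]
        buffer = [window]
        buffered = win
        t_rel = t_end - stream.cue_time_s
        if t_rel > protocol.timeout_s + 1e-12:
            break
        x = features_block(window[None, :, :], window_spec)[0]
        label = model.predict(x)
        events.append(PredictionEvent(time_s=t_rel, label=label))
        if label == stream.movement:
            n_correct += 1
            if n_correct >= protocol.required_correct:
                break
    return events


def aggregate(trials: Sequence[TrialRecord]) -> dict:
    """Summary metrics for a set of trials.

    Completion rate covers all trials; the remaining metrics average over
    completed trials only and are ``nan`` when nothing completed.
    """
    if not trials:
        raise ConfigError("no trials to aggregate")
    completed = [t for t in trials if t.completed]
    out = {
        "n_trials": len(trials),
        "n_completed": len(completed),
        "completion_rate_pct": len(completed) / len(trials) * 100.0,
    }
    for key, attr in [
        ("rt_accuracy_pct", "rt_accuracy_pct"),
        ("selection_time_s", "selection_time_s"),
        ("completion_time_s", "completion_time_s"),
    ]:
        vals = [getattr(t, attr) for t in completed if getattr(t, attr) is not None]
        out[key] = float(np.mean(vals)) if vals else float("nan")
    return out
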