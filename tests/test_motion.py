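import numpy as np
import pytest

from myobench.classifiers import ClassifierSpec, train
from myobench.features import WindowSpec
from myobench.motion_test import (
    MotionTestProtocol,
    PredictionEvent,
    TrialRecord,
    aggregate,
    run_motion_test,
    score_trial,
)
from myobench.offline import split_data
from myobench.session_io import ConfigError, ProtocolConfig, REST_LABEL
from myobench.synthetic_emg import SyntheticConfig, generate_stream


def _events(spec):
    """events from a list of (time, label) pairs"""
    return [PredictionEvent(time_s=t, label=lab) for t, lab in spec]


class TestScoreTrial:
    def test_hand_enumerated_timeline(self):
        # rest at 0.20-0.30, one wrong at 0.35, then correct every 50 ms
        timeline = [(0.20, "rest"), (0.25, "rest"), (0.30, "rest"), (0.35, "wrong")]
        timeline += [(0.40 + 0.05 * k, "target") for k in range(20)]  # 0.40..1.35
        rec = score_trial(_events(timeline), "target", required_correct=20, timeout_s=10.0)
        assert rec.completed
        assert rec.selection_time_s == pytest.approx(0.05)
        assert rec.completion_time_s == pytest.approx(1.00)
        assert rec.rt_accuracy_pct == pytest.approx(20 / 21 * 100.0)

    def test_oracle_predictor_bound(self):
        # a perfect predictor completes at the 20th event
        timeline = [(0.2 + 0.05 * k, "target") for k in range(30)]
        rec = score_trial(_events(timeline), "target")
        assert rec.completed
        assert rec.selection_time_s == 0.0
        assert rec.completion_time_s == pytest.approx(19 * 0.05)
        assert rec.rt_accuracy_pct == pytest.approx(100.0)

    def test_first_non_rest_already_correct(self):
        timeline = [(0.2, "rest"), (0.25, "target")] + [
            (0.30 + 0.05 * k, "target") for k in range(19)
        ]
        rec = score_trial(_events(timeline), "target")
        assert rec.selection_time_s == 0.0

    def test_only_19_correct_incomplete(self):
        timeline = [(0.2 + 0.05 * k, "target") for k in range(19)]
        rec = score_trial(_events(timeline), "target")
        assert not rec.completed
        assert rec.selection_time_s is None
        assert rec.completion_time_s is None
        assert rec.rt_accuracy_pct is None

    def test_all_rest_incomplete(self):
        timeline = [(0.2 + 0.05 * k, "rest") for k in range(50)]
        rec = score_trial(_events(timeline), "target")
        assert not rec.completed

    def test_events_after_20th_correct_ignored(self):
        base = [(0.2 + 0.05 * k, "target") for k in range(20)]
        extra = base + [(1.2, "wrong"), (1.25, "wrong"), (1.3, "target")]
        r1 = score_trial(_events(base), "target")
        r2 = score_trial(_events(extra), "target")
        assert r1.completion_time_s == r2.completion_time_s
        assert r1.rt_accuracy_pct == r2.rt_accuracy_pct

    def test_timeout_cuts_late_corrects(self):
        # correct events at 9.10, 9.15, ...: the 20th lands at 10.05
        timeline = [(9.10 + 0.05 * k, "target") for k in range(25)]
        rec = score_trial(_events(timeline), "target", timeout_s=10.0)
        assert not rec.completed
        rec2 = score_trial(_events(timeline), "target", timeout_s=10.5)
        assert rec2.completed


class TestAggregate:
    def _mk(self, completed, acc=None, sel=None, comp=None, target="m"):
        return TrialRecord(target=target, events=[], completed=completed,
                           selection_time_s=sel, completion_time_s=comp,
                           rt_accuracy_pct=acc)

    def test_completion_rate_all_trials(self):
        trials = [self._mk(True, 100, 0.1, 1.0)] * 15 + [self._mk(False)] * 15
        out = aggregate(trials)
        assert out["completion_rate_pct"] == pytest.approx(50.0)

    def test_perfect_accuracy_mean(self):
        trials = [self._mk(True, 100.0, 0.0, 0.95)] * 4
        assert aggregate(trials)["rt_accuracy_pct"] == pytest.approx(100.0)

    def test_mixed_means_match_manual(self):
        trials = [
            self._mk(True, 90.0, 0.10, 1.00),
            self._mk(True, 80.0, 0.30, 2.00),
            self._mk(False),
            self._mk(True, 70.0, 0.20, 1.50),
        ]
        out = aggregate(trials)
        assert out["completion_rate_pct"] == pytest.approx(75.0)
        assert out["rt_accuracy_pct"] == pytest.approx(80.0)
        assert out["selection_time_s"] == pytest.approx(0.2)
        assert out["completion_time_s"] == pytest.approx(1.5)

    def test_zero_completed(self):
        out = aggregate([self._mk(False)] * 3)
        assert out["completion_rate_pct"] == 0.0
        assert np.isnan(out["rt_accuracy_pct"])

    def test_empty_rejected(self):
        with pytest.raises(ConfigError):
            aggregate([])


class _OracleModel:
    """Stand-in TrainedClassifier that always answers with a fixed label."""

    def __init__(self, label):
        self.label = label

    def predict(self, x):
        return self.label


@pytest.fixture(scope="module")
def small_setup():
    protocol = ProtocolConfig(movements=("open hand", "close hand", "pronation"))
    syn = SyntheticConfig(protocol=protocol, seed=13)
    mt = MotionTestProtocol(movements=protocol.movements, repetitions_per_movement=1)

    def stream_source(movement, trial_seed):
        cfg = SyntheticConfig(protocol=protocol, activation=syn.activation,
                              seed=trial_seed)
        return generate_stream(cfg, movement, total_s=11.5)

    return syn, mt, stream_source


class TestRunMotionTest:
    def test_always_rest_model_incomplete(self, small_setup):
        _, mt, stream_source = small_setup
        result = run_motion_test(_OracleModel(REST_LABEL), stream_source, mt, seed=0)
        assert result.completion_rate_pct == 0.0
        assert all(not t.completed for t in result.trials)

    def test_oracle_model_completes_fast(self, small_setup):
        syn, mt, stream_source = small_setup
        # per-movement fixed-label oracle: completes at exactly the 20th event
        for movement in mt.movements:
            result = run_motion_test(
                _OracleModel(movement),
                stream_source,
                MotionTestProtocol(movements=(movement,), repetitions_per_movement=1),
                seed=0,
            )
            trial = result.trials[0]
            assert trial.completed
            assert trial.selection_time_s == 0.0
            assert trial.completion_time_s == pytest.approx(19 * 0.05)
            assert trial.rt_accuracy_pct == pytest.approx(100.0)

    def test_deterministic_given_seed(self, small_setup, default_features):
        syn, mt, stream_source = small_setup
        split = split_data(default_features.labels, seed=0)
        model = train(ClassifierSpec(name="LDA", seed=0),
                      default_features.X[split.train_idx],
                      default_features.labels[split.train_idx])
        # movements of the default session match the small protocol subset
        r1 = run_motion_test(model, stream_source, mt, seed=42)
        r2 = run_motion_test(model, stream_source, mt, seed=42)
        for t1, t2 in zip(r1.trials, r2.trials):
            assert t1.target == t2.target
            assert t1.events == t2.events
            assert t1.completed == t2.completed

    def test_trained_model_metric_invariants(self, small_setup, default_features):
        _, mt, stream_source = small_setup
        split = split_data(default_features.labels, seed=0)
        model = train(ClassifierSpec(name="LDA", seed=0),
                      default_features.X[split.train_idx],
                      default_features.labels[split.train_idx],
                      default_features.X[split.val_idx],
                      default_features.labels[split.val_idx])
        result = run_motion_test(model, stream_source, mt, seed=7)
        for trial in result.trials:
            if trial.completed:
                assert 0.0 <= trial.selection_time_s <= trial.completion_time_s
                assert trial.completion_time_s >= (mt.required_correct - 1) * mt.prediction_period_s
                assert 0.0 < trial.rt_accuracy_pct <= 100.0


class TestStreamConsumption:
    def test_first_event_at_full_buffer(self):
        """The first prediction fires when 200 ms have accumulated."""
        protocol = ProtocolConfig(movements=("open hand",))
        cfg = SyntheticConfig(protocol=protocol, seed=1)
        stream = generate_stream(cfg, "open hand", pre_rest_s=1.0, total_s=11.5)
        mt = MotionTestProtocol(movements=("open hand",), repetitions_per_movement=1)
        from myobench.motion_test import _consume_stream

        events = _consume_stream(_OracleModel("open hand"), stream, mt, WindowSpec())
        # stream starts at t=0, cue at 1.0; first window complete at 0.2 abs
        assert events[0].time_s == pytest.approx(0.2 - 1.0)
        assert events[1].time_s - events[0].time_s == pytest.approx(0.05)
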