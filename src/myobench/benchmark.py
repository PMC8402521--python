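"""End-to-end benchmark: synthetic subjects -> offline CV -> motion test -> table.

For every synthetic subject the pipeline generates an offline recording
session, extracts Hudgins features, runs repeated 40/20/40 cross-validation
for each classifier, trains one model per classifier for the real-time stage
and runs the motion test (classifier order randomized per subject).  Per
subject/classifier metrics feed the ANOVA/Duncan summary table.

A single master seed fans out into independent per-subject, per-classifier
and per-trial sub-seeds through ``numpy.random.SeedSequence``, so any slice
of the benchmark is reproducible in isolation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .classifiers import CLASSIFIER_NAMES, ClassifierSpec, train
from .features import WindowSpec, extract_features
from .motion_test import MotionTestProtocol, run_motion_test
from .offline import cross_validate, split_data
from .session_io import ProtocolConfig
from .stats_report import METRIC_COLUMNS, SummaryTable, summary_table
from .synthetic_emg import SyntheticConfig, generate_stream

__all__ = ["RunConfig", "BenchmarkResult", "run_benchmark", "subject_seed"]

logger = logging.getLogger(__name__)


def subject_seed(master_seed: int, *tags: int) -> int:
    """Deterministic sub-seed (< 2**31) from a master seed and integer tags."""
    ss = np.random.SeedSequence([int(master_seed), *map(int, tags)])
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31 - 1))


@dataclass
class RunConfig:
    n_subjects: int = 15
    classifiers: tuple[str, ...] = CLASSIFIER_NAMES
    offline_reps: int = 10
    seed: int = 0
    protocol: ProtocolConfig = field(default_factory=ProtocolConfig)
    window_spec: WindowSpec = field(default_factory=WindowSpec)
    motion_protocol: MotionTestProtocol | None = None
    separability: float = 1.0
    rest_noise_sd: float = 0.02
    mvc_scale: float = 1.0
    powerline_amp: float = 0.0
    pre_rest_s: float = 1.0
    reaction_delay_s: float = 0.3
    outdir: Path | None = None

    def __post_init__(self) -> None:
        unknown = set(self.classifiers) - set(CLASSIFIER_NAMES)
        if unknown:
            raise ValueError(f"unknown classifiers: {sorted(unknown)}")
        if self.motion_protocol is None:
            self.motion_protocol = MotionTestProtocol(movements=self.protocol.movements)


@dataclass
class BenchmarkResult:
    per_subject: pd.DataFrame  # rows: subject x classifier x metrics
    summary: SummaryTable

    def groups_per_metric(self) -> dict[str, dict[str, np.ndarray]]:
        out: dict[str, dict[str, np.ndarray]] = {}
        for metric in METRIC_COLUMNS:
            per_clf = {}
            for clf, sub in self.per_subject.groupby("classifier"):
                vals = sub[metric].to_numpy(dtype=np.float64)
                per_clf[str(clf)] = vals
            out[metric] = per_clf
        return out


def _subject_synthetic_config(config: RunConfig, subject: int) -> SyntheticConfig:
    return SyntheticConfig(
        protocol=config.protocol,
        mvc_scale=config.mvc_scale,
        rest_noise_sd=config.rest_noise_sd,
        powerline_amp=config.powerline_amp,
        separability=config.separability,
        seed=subject_seed(config.seed, 1, subject),
    )


def run_subject(config: RunConfig, subject: int) -> list[dict]:
    """Offline CV plus motion test for all classifiers of one synthetic subject."""
    from .synthetic_emg import generate_session

    syn = _subject_synthetic_config(config, subject)
    session = generate_session(syn)
    features = extract_features(session, config.window_spec, include_rest=True)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2, subject]))
    clf_order = list(rng.permutation(list(config.classifiers)))

    rows = []
    for clf_name in clf_order:
        clf_seed = subject_seed(config.seed, 3, subject, _name_tag(clf_name))
        spec = ClassifierSpec(name=clf_name, seed=clf_seed)
        offline = cross_validate(
            spec, features, reps=config.offline_reps, seed=clf_seed
        )
        # one dedicated model for the real-time stage, trained on a fresh split
        split = split_data(features.labels, seed=clf_seed * 7 + 1)
        model = train(
            spec,
            features.X[split.train_idx], features.labels[split.train_idx],
            features.X[split.val_idx], features.labels[split.val_idx],
        )

        def stream_source(movement: str, trial_seed: int):
            cfg = SyntheticConfig(
                protocol=syn.protocol,
                activation=syn.activation,
                mvc_scale=syn.mvc_scale,
                rest_noise_sd=syn.rest_noise_sd,
                powerline_amp=syn.powerline_amp,
                separability=syn.separability,
                seed=trial_seed,
            )
            total = config.pre_rest_s + config.motion_protocol.timeout_s + 0.5
            return generate_stream(
                cfg,
                movement,
                pre_rest_s=config.pre_rest_s,
                reaction_delay_s=config.reaction_delay_s,
                total_s=total,
                increment_s=config.motion_protocol.prediction_period_s,
            )

        motion = run_motion_test(
            model,
            stream_source,
            protocol=config.motion_protocol,
            seed=clf_seed,
            window_spec=config.window_spec,
        )
        overall = motion.overall()
        rows.append(
            {
                "subject": subject,
                "classifier": clf_name,
                "offline_accuracy_pct": offline.mean_accuracy_pct,
                "offline_accuracy_sd_pct": offline.sd_accuracy_pct,
                "train_time_s": offline.train_time_s,
                "test_time_ms": offline.test_time_ms,
                "rt_accuracy_pct": overall["rt_accuracy_pct"],
                "selection_time_s": overall["selection_time_s"],
                "completion_time_s": overall["completion_time_s"],
                "completion_rate_pct": overall["completion_rate_pct"],
            }
        )
        logger.info(
            "subject %d %s: offline %.1f%%, real-time %.1f%%, completion %.1f%%",
            subject, clf_name,
            rows[-1]["offline_accuracy_pct"],
            rows[-1]["rt_accuracy_pct"],
            rows[-1]["completion_rate_pct"],
        )
    return rows


def run_benchmark(config: RunConfig) -> BenchmarkResult:
    """Run the whole benchmark and assemble the summary table."""
    rows: list[dict] = []
    for subject in range(config.n_subjects):
        try:
            rows.extend(run_subject(config, subject))
        except Exception:
            logger.exception("subject %d failed; partial results preserved", subject)
            if not rows:
                raise
    per_subject = pd.DataFrame(rows).sort_values(["classifier", "subject"]).reset_index(drop=True)
    groups = {}
    for metric in METRIC_COLUMNS:
        groups[metric] = {
            str(clf): sub[metric].to_numpy(dtype=np.float64)
            for clf, sub in per_subject.groupby("classifier")
        }
    summary = summary_table(groups)
    result = BenchmarkResult(per_subject=per_subject, summary=summary)
    if config.outdir is not None:
        outdir = Path(config.outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        per_subject.to_csv(outdir / "per_subject.csv", index=False)
        summary.to_csv(outdir / "summary.csv")
        (outdir / "summary.md").write_text(summary.to_markdown() + "\n")
    return result


def _name_tag(name: str) -> int:
    h = 0
    for ch in name:
        h = (h * 31 + ord(ch)) % (2**31 - 1)
    return h
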