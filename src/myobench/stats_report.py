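"""One-way ANOVA, Duncan's multiple range test, and the summary table.

The benchmark compares classifiers metric by metric as a completely
randomized design: one-way fixed-effects ANOVA followed by Duncan's multiple
range test at alpha = 0.05.  Duncan's critical range for a span of ``p``
ordered means is

    R_p = q(1 - (1 - alpha)^(p-1); p, df_within) * sqrt(MSE / n_h)

with ``q`` the studentized-range quantile and ``n_h`` the harmonic mean group
size (the balanced case reduces to the common group size).  Means whose
ordered span stays within the critical range share a letter; a group may
carry several letters ("ab", "abc") when overlapping runs are separately
non-significant.

A Shapiro-Wilk p-value is logged per metric as an informal normality check.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .session_io import ConfigError

__all__ = [
    "AnovaResult",
    "one_way_anova",
    "duncan_mrt",
    "SummaryTable",
    "summary_table",
    "METRIC_COLUMNS",
]

logger = logging.getLogger(__name__)

#: metric key -> (column header, higher-is-better)
METRIC_COLUMNS = {
    "offline_accuracy_pct": ("Offline Accuracy (%)", True),
    "train_time_s": ("TrTime (s)", False),
    "test_time_ms": ("TTime (ms)", False),
    "rt_accuracy_pct": ("Real-Time Accuracy (%)", True),
    "selection_time_s": ("SelTime (s)", False),
    "completion_time_s": ("CompTime (s)", False),
    "completion_rate_pct": ("CompRate (%)", True),
}


@dataclass(frozen=True)
class AnovaResult:
    F: float
    p: float
    df_between: int
    df_within: int
    mse: float


def one_way_anova(groups: dict[str, np.ndarray] | list[np.ndarray]) -> AnovaResult:
    """Standard fixed-effects one-way decomposition."""
    arrays = list(groups.values()) if isinstance(groups, dict) else list(groups)
    arrays = [np.asarray(g, dtype=np.float64) for g in arrays]
    k = len(arrays)
    if k < 2:
        raise ConfigError("ANOVA needs at least 2 groups")
    if any(len(g) < 1 for g in arrays):
        raise ConfigError("every group needs at least one observation")
    n_total = sum(len(g) for g in arrays)
    if n_total <= k:
        raise ConfigError("degenerate degrees of freedom (n_total <= k)")
    grand = np.concatenate(arrays).mean()
    ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in arrays)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in arrays)
    df_between = k - 1
    df_within = n_total - k
    ms_between = ss_between / df_between
    mse = ss_within / df_within
    F = ms_between / mse if mse > 0 else (0.0 if ms_between == 0 else np.inf)
    p = float(stats.f.sf(F, df_between, df_within)) if np.isfinite(F) else 0.0
    return AnovaResult(F=float(F), p=p, df_between=df_between, df_within=df_within, mse=float(mse))


def duncan_mrt(groups: dict[str, np.ndarray], alpha: float = 0.05) -> dict[str, str]:
    """Duncan letter assignment; groups sharing a letter do not differ at alpha.

    Means are ranked (best first); for each ordered pair the observed range is
    compared with the critical range for its span, and maximal non-significant
    runs of the ordered means each receive one letter.
    """
    names = list(groups.keys())
    arrays = {n: np.asarray(groups[n], dtype=np.float64) for n in names}
    if any(len(v) == 0 for v in arrays.values()):
        raise ConfigError("empty group")
    anova = one_way_anova(arrays)
    sizes = np.array([len(arrays[n]) for n in names], dtype=np.float64)
    n_h = len(sizes) / np.sum(1.0 / sizes)  # harmonic mean group size
    means = np.array([arrays[n].mean() for n in names])
    order = np.argsort(-means)  # descending
    sorted_means = means[order]
    k = len(names)

    se = np.sqrt(anova.mse / n_h)
    crit = np.zeros(k + 1)
    for span in range(2, k + 1):
        level = 1.0 - (1.0 - alpha) ** (span - 1)
        q = stats.studentized_range.ppf(1.0 - level, span, anova.df_within) if se > 0 else 0.0
        crit[span] = q * se

    def nonsig(i: int, j: int) -> bool:
        return (sorted_means[i] - sorted_means[j]) <= crit[j - i + 1] + 1e-12

    # maximal non-significant runs over the ordered means; a run contained in
    # an earlier one adds nothing (Duncan's protection rule makes sub-ranges
    # of a non-significant range non-significant)
    intervals: list[tuple[int, int]] = []
    last_hi = -1
    for i in range(k):
        j = i
        while j + 1 < k and nonsig(i, j + 1):
            j += 1
        if j > last_hi:
            intervals.append((i, j))
            last_hi = j
    # assign letters
    letters = [""] * k
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    for letter_i, (lo, hi) in enumerate(intervals):
        for pos in range(lo, hi + 1):
            letters[pos] += alphabet[letter_i % len(alphabet)]
    out = {}
    for pos, gi in enumerate(order):
        out[names[gi]] = letters[pos]
    return out


@dataclass
class SummaryTable:
    """Per-classifier means +- SD with Duncan letters for every metric."""

    table: pd.DataFrame       # formatted cells "mean ± sd ^letters^"
    means: pd.DataFrame
    sds: pd.DataFrame
    letters: pd.DataFrame
    best: dict[str, str]      # metric key -> classifier with the best mean

    def to_markdown(self) -> str:
        return self.table.to_markdown()

    def to_csv(self, path) -> None:
        self.table.to_csv(path)


def summary_table(
    groups_per_metric: dict[str, dict[str, np.ndarray]],
    alpha: float = 0.05,
) -> SummaryTable:
    """Build the benchmark summary from per-metric, per-classifier samples.

    ``groups_per_metric[metric][classifier]`` holds the per-subject values.
    Metrics listed in :data:`METRIC_COLUMNS` but absent from the input are
    omitted with a warning.
    """
    present = [m for m in METRIC_COLUMNS if m in groups_per_metric]
    missing = [m for m in METRIC_COLUMNS if m not in groups_per_metric]
    for m in missing:
        warnings.warn(f"metric {m!r} missing; column omitted", stacklevel=2)
    if not present:
        raise ConfigError("no known metrics supplied")
    classifiers = list(groups_per_metric[present[0]].keys())

    means = pd.DataFrame(index=classifiers, columns=present, dtype=float)
    sds = pd.DataFrame(index=classifiers, columns=present, dtype=float)
    letters = pd.DataFrame(index=classifiers, columns=present, dtype=object)
    formatted = pd.DataFrame(index=classifiers, columns=[METRIC_COLUMNS[m][0] for m in present],
                             dtype=object)
    best: dict[str, str] = {}
    for m in present:
        groups = {c: np.asarray(v, dtype=np.float64) for c, v in groups_per_metric[m].items()}
        groups = {c: v[np.isfinite(v)] for c, v in groups.items()}
        groups = {c: v for c, v in groups.items() if len(v) > 0}
        if len(groups) < 2 or any(len(v) < 2 for v in groups.values()):
            lets = {c: "" for c in groups}
        else:
            try:
                sw_p = stats.shapiro(np.concatenate(
                    [v - v.mean() for v in groups.values()]
                )).pvalue
                logger.info("metric %s: Shapiro-Wilk p=%.3g on pooled residuals", m, sw_p)
            except Exception:
                pass
            lets = duncan_mrt(groups, alpha=alpha)
        higher_better = METRIC_COLUMNS[m][1]
        for c in classifiers:
            v = groups.get(c)
            if v is None:
                means.loc[c, m] = np.nan
                sds.loc[c, m] = np.nan
                letters.loc[c, m] = ""
                formatted.loc[c, METRIC_COLUMNS[m][0]] = "—"
                continue
            mu = float(np.mean(v))
            sd = float(np.std(v, ddof=1)) if len(v) > 1 else 0.0
            means.loc[c, m] = mu
            sds.loc[c, m] = sd
            letters.loc[c, m] = lets.get(c, "")
            formatted.loc[c, METRIC_COLUMNS[m][0]] = (
                f"{mu:.3g} ^{lets.get(c, '')}^ ± {sd:.3g}"
            )
        col = means[m].dropna()
        if len(col):
            best[m] = str(col.idxmax() if higher_better else col.idxmin())
    return SummaryTable(table=formatted, means=means, sds=sds, letters=letters, best=best)
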