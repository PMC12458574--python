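"""Descriptive and classical inferential statistics.

Group comparisons are parametric (t-tests) unless the relevant summary
distribution violates normality (Shapiro-Wilk, alpha = 0.05) or, for
between-group tests, variance homogeneity (Levene); then Wilcoxon
signed-rank / rank-sum tests are used. Bonferroni correction is applied
within families: the four within-group confidence-change tests form one
family, the two between-group comparisons another. Participant-level
summaries are cleaned with the 1.5 x IQR rule before testing.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "iqr_filter",
    "feedback_change_tests",
    "within_subject_correlation",
    "rm_anova",
]


def iqr_filter(x: np.ndarray) -> np.ndarray:
    """Drop values outside [Q1 - 1.5 IQR, Q3 + 1.5 IQR]."""
    x = np.asarray(x, dtype=float)
    q1, q3 = np.percentile(x, [25, 75])
    iqr = q3 - q1
    return x[(x >= q1 - 1.5 * iqr) & (x <= q3 + 1.5 * iqr)]


def _is_normal(x: np.ndarray, alpha: float = 0.05) -> bool:
    if len(x) < 3 or np.ptp(x) == 0:
        return False
    return sps.shapiro(x).pvalue >= alpha


def _one_sample(x: np.ndarray) -> tuple[str, float, float]:
    if _is_normal(x):
        res = sps.ttest_1samp(x, 0.0)
        return "t", float(res.statistic), float(res.pvalue)
    res = sps.wilcoxon(x)
    return "wilcoxon", float(res.statistic), float(res.pvalue)


def _two_sample(a: np.ndarray, b: np.ndarray) -> tuple[str, float, float]:
    normal = _is_normal(a) and _is_normal(b)
    if normal and len(a) > 2 and len(b) > 2:
        if sps.levene(a, b).pvalue >= 0.05:
            res = sps.ttest_ind(a, b)
            return "t", float(res.statistic), float(res.pvalue)
    res = sps.ranksums(a, b)
    return "ranksum", float(res.statistic), float(res.pvalue)


def feedback_change_tests(cohort) -> pd.DataFrame:
    """Mean confidence change after correct vs incorrect trials, per group.

    The trial-level change conf_t - conf_{t-1} (within level) is averaged
    per participant separately for trials following a correct and an
    incorrect outcome. Within each group, each mean change is tested
    against zero (family of 4, Bonferroni); the groups are then compared
    per condition (family of 2, Bonferroni).
    """
    demo = cohort.demographics
    groups = list(demo["group"].unique())
    if len(groups) != 2:
        raise ValueError("feedback change tests need exactly two groups")
    for g in groups:
        if (demo["group"] == g).sum() < 3:
            raise ValueError(f"group {g!r} has fewer than 3 participants")

    df = cohort.trials.merge(demo[["participant_id", "group"]], on="participant_id")
    by = df.groupby(["participant_id", "level"], sort=False)
    df = df.assign(
        dconf=by["confidence"].diff(),
        prev_outcome=by["outcome"].shift(1),
    ).dropna(subset=["dconf", "prev_outcome"])

    summaries: dict[tuple[str, int], np.ndarray] = {}
    for (g, prev), sub in df.groupby(["group", "prev_outcome"]):
        per_part = sub.groupby("participant_id")["dconf"].mean().to_numpy()
        summaries[(g, int(prev))] = iqr_filter(per_part)

    rows = []
    within = []
    for g in groups:
        for prev, label in ((1, "post-correct"), (0, "post-incorrect")):
            x = summaries[(g, prev)]
            test, stat, p = _one_sample(x)
            within.append(
                dict(comparison=f"{g} {label} vs 0", group=g, condition=label,
                     mean_change=float(x.mean()), n=len(x), test=test,
                     statistic=stat, p=p)
            )
    m = len(within)
    for r in within:
        r["p_bonf"] = min(1.0, m * r["p"])
    rows.extend(within)

    between = []
    for prev, label in ((1, "post-correct"), (0, "post-incorrect")):
        a, b = summaries[(groups[0], prev)], summaries[(groups[1], prev)]
        test, stat, p = _two_sample(a, b)
        between.append(
            dict(comparison=f"{groups[0]} vs {groups[1]} {label}",
                 group="both", condition=label,
                 mean_change=float(a.mean() - b.mean()),
                 n=len(a) + len(b), test=test, statistic=stat, p=p)
        )
    m = len(between)
    for r in between:
        r["p_bonf"] = min(1.0, m * r["p"])
    rows.extend(between)
    return pd.DataFrame(rows)


def within_subject_correlation(
    traces: pd.DataFrame, x: str = "gc_pre", y: str = "cc_pre"
) -> tuple[float, float, pd.DataFrame]:
    """Per-participant Spearman correlation of the two certainty traces.

    Returns (mean, SD, per-participant table). Participants with a
    constant trace have no defined correlation and are excluded with a
    flag.
    """
    rows = []
    for pid, sub in traces.groupby("participant_id", sort=False):
        if len(sub) < 10:
            raise ValueError(f"participant {pid}: fewer than 10 trials")
        if sub[x].nunique() < 2 or sub[y].nunique() < 2:
            rows.append(dict(participant_id=pid, r=np.nan, constant=True))
            continue
        r = sps.spearmanr(sub[x], sub[y]).statistic
        rows.append(dict(participant_id=pid, r=float(r), constant=False))
    table = pd.DataFrame(rows)
    valid = table.loc[~table["constant"], "r"]
    return float(valid.mean()), float(valid.std(ddof=1)), table


def rm_anova(cohort, metric: str = "outcome") -> pd.DataFrame:
    """Mixed-design ANOVA: group (between) x task level (within).

    Computed on participant x level means. Raises if any participant is
    missing a level.
    """
    import pingouin as pg

    df = cohort.trials.merge(
        cohort.demographics[["participant_id", "group"]], on="participant_id"
    )
    cell = (
        df.groupby(["participant_id", "group", "level"])[metric]
        .mean()
        .reset_index()
    )
    counts = cell.groupby("participant_id")["level"].nunique()
    n_levels = cell["level"].nunique()
    if (counts != n_levels).any():
        missing = counts[counts != n_levels].index.tolist()
        raise ValueError(f"participants missing levels: {missing}")
    return pg.mixed_anova(
        data=cell, dv=metric, within="level", between="group",
        subject="participant_id",
    )
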