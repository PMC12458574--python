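"""Participant- and trial-level exclusion rules.

Participants are excluded when overall accuracy is at or below chance
(default: trial-weighted chance across levels, reflecting that chance is
1/2 at two-stimulus levels and 1/3 at three-stimulus levels) or when more
than 90% of their confidence ratings are identical. Trial-level RT
outliers are removed per participant x level on the log scale: trials
more than 3 SD from the mean log-RT, with the first trial of each block
excluded both from the threshold computation and from removal.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Tuple

import numpy as np
import pandas as pd

__all__ = ["ExclusionReport", "apply_exclusions", "rt_outlier_filter", "chance_level"]


@dataclass
class ExclusionReport:
    participants: pd.DataFrame  # per participant: accuracy, threshold, flags
    n_excluded: int
    chance_threshold: float


def chance_level(trials: pd.DataFrame, mode: str = "weighted"):
    """Chance accuracy implied by the stimulus counts in a trial log.

    ``weighted``: single threshold = trial-weighted mean of per-level
    chance (1 / number of stimuli). ``per_level``: Series of per-level
    thresholds.
    """
    stim_cols = [c for c in trials.columns if c.startswith("stim")]
    n_stim = trials[stim_cols].apply(
        lambda r: sum(1 for v in r if isinstance(v, str) and v != ""), axis=1
    )
    per_trial = 1.0 / n_stim
    if mode == "weighted":
        return float(per_trial.mean())
    if mode == "per_level":
        return per_trial.groupby(trials["level"]).mean()
    raise ValueError(f"unknown chance mode {mode!r}")


def apply_exclusions(cohort, mode: str = "weighted") -> Tuple[object, ExclusionReport]:
    """Apply participant-level exclusion rules to a cohort.

    Returns a filtered copy of the cohort and a report with per-participant
    accuracy, the chance threshold, and exclusion flags/reasons.
    """
    from ..cohort import CohortDataset

    trials = cohort.trials
    if trials.empty:
        raise ValueError("empty cohort")

    rows = []
    for pid, sub in trials.groupby("participant_id", sort=False):
        acc = float(sub["outcome"].mean())
        if mode == "per_level":
            per = chance_level(sub, "per_level")
            lvl_acc = sub.groupby("level")["outcome"].mean()
            at_chance = bool((lvl_acc <= per.reindex(lvl_acc.index)).all())
            threshold = float(per.mean())
        else:
            threshold = chance_level(sub, "weighted")
            at_chance = acc <= threshold
        conf = sub["confidence"].dropna()
        mode_frac = float(conf.value_counts().iloc[0] / len(conf)) if len(conf) else 1.0
        constant_conf = mode_frac > 0.9
        reason = []
        if at_chance:
            reason.append("chance performance")
        if constant_conf:
            reason.append("constant confidence")
        rows.append(
            dict(participant_id=pid, accuracy=acc, chance_threshold=threshold,
                 mode_confidence_fraction=mode_frac, excluded=bool(reason),
                 reason="; ".join(reason))
        )
    report_df = pd.DataFrame(rows)
    excluded = set(report_df.loc[report_df["excluded"], "participant_id"])

    keep = ~trials["participant_id"].isin(excluded)
    filtered = CohortDataset(
        trials=trials[keep].reset_index(drop=True),
        demographics=cohort.demographics[
            ~cohort.demographics["participant_id"].isin(excluded)
        ].reset_index(drop=True),
        truth=cohort.truth[
            ~cohort.truth["participant_id"].isin(excluded)
        ].reset_index(drop=True) if cohort.truth is not None else None,
        records={k: v for k, v in cohort.records.items() if k not in excluded}
        if cohort.records is not None else None,
    )
    report = ExclusionReport(
        participants=report_df,
        n_excluded=len(excluded),
        chance_threshold=float(report_df["chance_threshold"].mean()),
    )
    return filtered, report


def rt_outlier_filter(log: pd.DataFrame) -> Tuple[pd.DataFrame, float]:
    """Remove log-RT outliers (>3 SD) per participant x level.

    The first trial of each block neither enters the threshold computation
    nor is ever removed. With zero RT variance nothing is removed.
    """
    if "rt" not in log.columns:
        raise ValueError("trial log has no rt column")
    rt = log["rt"]
    if (rt.dropna() <= 0).any():
        raise ValueError("nonpositive RT encountered")

    first_of_block = log.groupby(
        ["participant_id", "level", "block"], sort=False
    )["trial"].transform("min") == log["trial"]

    log_rt = np.log(rt.astype(float))
    grp = ["participant_id", "level"]
    base = log_rt.where(~first_of_block)
    mean = base.groupby([log[c] for c in grp]).transform("mean")
    sd = base.groupby([log[c] for c in grp]).transform("std")
    with np.errstate(invalid="ignore"):
        z = (log_rt - mean) / sd
    outlier = (~first_of_block) & sd.notna() & (sd > 0) & (z.abs() > 3)
    frac = float(outlier.mean())
    return log[~outlier].reset_index(drop=True), frac
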