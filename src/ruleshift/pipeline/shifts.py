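"""Shift-aligned annotation and peri-shift averaging.

Conventions: the covert rule change takes effect on the shift trial
itself (distance 0, where feedback first contradicts the old rule);
distance 1 is the first post-shift trial. Windows are truncated at level
boundaries and never cross them.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["annotate_shift_distance", "shift_aligned_summary"]


def annotate_shift_distance(trials: pd.DataFrame) -> pd.DataFrame:
    """Add ``dist`` (trials since the most recent shift; shift trial = 0)
    and ``last_shift_type`` columns. Trials before a level's first shift
    get NaN distance."""
    out = trials.copy()
    grp = [out["participant_id"], out["level"]]
    shift_trial = out["trial"].where(out["shift"] == 1)
    last_shift = shift_trial.groupby(grp, sort=False).ffill()
    out["dist"] = out["trial"] - last_shift
    stype = out["shift_type"].where(out["shift"] == 1)
    out["last_shift_type"] = stype.groupby(grp, sort=False).ffill()
    return out


def shift_aligned_summary(
    cohort, metric: str, window: int = 5
) -> pd.DataFrame:
    """Peri-shift average of a metric per group x shift type x distance.

    Distances run from -window to +window around each shift (0 = shift
    trial). Per-participant means are computed first; the table reports
    their group mean and standard error.
    """
    trials = cohort.trials
    demo = cohort.demographics[["participant_id", "group"]]
    events = trials.loc[
        trials["shift"] == 1, ["participant_id", "level", "trial", "shift_type"]
    ].rename(columns={"trial": "shift_trial"})

    offsets = pd.DataFrame({"distance": np.arange(-window, window + 1)})
    expanded = events.merge(offsets, how="cross")
    expanded["trial"] = expanded["shift_trial"] + expanded["distance"]

    merged = expanded.merge(
        trials[["participant_id", "level", "trial", metric]],
        on=["participant_id", "level", "trial"],
        how="inner",  # out-of-level offsets simply drop out (truncation)
    )
    per_part = (
        merged.groupby(["participant_id", "shift_type", "distance"])[metric]
        .mean()
        .reset_index()
        .merge(demo, on="participant_id")
    )
    out = (
        per_part.groupby(["group", "shift_type", "distance"])[metric]
        .agg(mean="mean", se=lambda v: v.std(ddof=1) / np.sqrt(len(v)), n="count")
        .reset_index()
    )
    return out
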