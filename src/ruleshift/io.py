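"""Readers/writers for trial-log, demographics, trace and result tables.

All tables are delimited text with explicit headers; model results are
written as structured JSON alongside a run manifest recording seeds and a
config hash. Confidence is stored as integers 1-100 (the slider's
granularity).

Trial-log schema (one row per trial):

    participant_id, level, block, trial, stim0..stim{k}, rule_dim,
    rule_feature, shift, shift_type, choice, outcome, confidence, rt

``stim{i}`` columns hold the semicolon-joined feature labels of stimulus
i in dimension order; levels with fewer stimuli leave trailing stim
columns empty.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .task import Rule, StimulusDisplay, TrialRecord

__all__ = [
    "records_to_frame",
    "frame_to_records",
    "write_trials",
    "read_trials",
    "write_table",
    "read_demographics",
    "write_results",
    "config_hash",
]

_BASE_COLUMNS = [
    "participant_id", "level", "block", "trial", "rule_dim", "rule_feature",
    "shift", "shift_type", "choice", "outcome", "confidence", "rt",
]


def records_to_frame(records: Sequence[TrialRecord]) -> pd.DataFrame:
    """Flatten TrialRecords to the standard tabular schema."""
    max_stim = max(r.display.n_stimuli for r in records)
    rows = []
    for r in records:
        row = {
            "participant_id": r.participant_id,
            "level": r.level_id,
            "block": r.block,
            "trial": r.trial_index,
            "rule_dim": r.rule.dimension,
            "rule_feature": r.rule.rewarded_feature,
            "shift": int(r.is_shift_trial),
            "shift_type": r.shift_type,
            "choice": r.choice,
            "outcome": r.outcome,
            "confidence": r.confidence if r.confidence is not None else np.nan,
            "rt": r.rt if r.rt is not None else np.nan,
            "slider_start": r.slider_start if r.slider_start is not None else np.nan,
        }
        for i in range(max_stim):
            row[f"stim{i}"] = (
                ";".join(r.display.stimuli[i]) if i < r.display.n_stimuli else ""
            )
        rows.append(row)
    cols = (_BASE_COLUMNS[:4] + [f"stim{i}" for i in range(max_stim)]
            + _BASE_COLUMNS[4:] + ["slider_start"])
    return pd.DataFrame(rows)[cols]


def frame_to_records(df: pd.DataFrame) -> list[TrialRecord]:
    """Rebuild typed TrialRecords from the tabular schema."""
    stim_cols = sorted(
        (c for c in df.columns if c.startswith("stim")), key=lambda c: int(c[4:])
    )
    records = []
    for row in df.itertuples(index=False):
        stimuli = tuple(
            tuple(getattr(row, c).split(";"))
            for c in stim_cols
            if isinstance(getattr(row, c), str) and getattr(row, c) != ""
        )
        conf = getattr(row, "confidence", np.nan)
        rt = getattr(row, "rt", np.nan)
        slider = getattr(row, "slider_start", np.nan)
        records.append(
            TrialRecord(
                participant_id=str(row.participant_id),
                level_id=int(row.level),
                block=int(row.block),
                trial_index=int(row.trial),
                display=StimulusDisplay(stimuli),
                rule=Rule(str(row.rule_dim), str(row.rule_feature)),
                is_shift_trial=bool(row.shift),
                shift_type=str(row.shift_type),
                choice=int(row.choice),
                outcome=int(row.outcome),
                confidence=None if pd.isna(conf) else float(conf),
                rt=None if pd.isna(rt) else float(rt),
                slider_start=None if pd.isna(slider) else int(slider),
            )
        )
    return records


def write_trials(df: pd.DataFrame, path, sep: str = "\t") -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep=sep, index=False)


def read_trials(path, sep: str = "\t") -> pd.DataFrame:
    """Read and validate a trial-log table.

    Raises ValueError naming the missing column or the offending rows for
    range violations (confidence outside 1-100, negative RT).
    """
    df = pd.read_csv(path, sep=sep)
    stim_cols = [c for c in df.columns if c.startswith("stim")]
    df[stim_cols] = df[stim_cols].fillna("")
    required = [c for c in _BASE_COLUMNS if c not in ("confidence", "rt")] + ["stim0"]
    for col in required:
        if col not in df.columns:
            raise ValueError(f"trial log {path}: missing required column {col!r}")
    if "confidence" in df.columns:
        conf = df["confidence"].dropna()
        bad = conf[(conf < 1) | (conf > 100)]
        if len(bad):
            raise ValueError(
                f"trial log {path}: confidence outside [1, 100] at rows "
                f"{list(bad.index[:5])}"
            )
    if "rt" in df.columns:
        rt = df["rt"].dropna()
        bad = rt[rt <= 0]
        if len(bad):
            raise ValueError(
                f"trial log {path}: nonpositive rt at rows {list(bad.index[:5])}"
            )
    return df


def write_table(df: pd.DataFrame, path, sep: str = "\t") -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep=sep, index=False)


def read_demographics(path, sep: str = "\t") -> pd.DataFrame:
    df = pd.read_csv(path, sep=sep)
    for col in ("participant_id", "group", "age", "gender", "iq"):
        if col not in df.columns:
            raise ValueError(f"demographics {path}: missing required column {col!r}")
    return df


def config_hash(config) -> str:
    """Stable short hash of a config mapping (for the run manifest)."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def write_results(results, path, seed: Optional[int] = None,
                  config: Optional[dict] = None) -> dict:
    """Serialise fitted model results plus a run manifest to JSON.

    ``results`` is a sequence of objects exposing ``to_dict()`` (the
    pipeline's ModelResult). Returns the manifest entry.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    manifest = {
        "n_models": len(results),
        "seed": seed,
        "config_hash": config_hash(config) if config is not None else None,
    }
    payload = {"manifest": manifest, "models": [r.to_dict() for r in results]}
    path.write_text(json.dumps(payload, indent=2, default=_json_default))
    return manifest


def _json_default(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serialisable: {type(obj)}")
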