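"""Deterministic intra-/extra-dimensional rule-shifting task engine.

The task presents 2-3 multi-featured stimuli per trial. One (dimension,
feature) pair is the covert rule; choosing the stimulus that carries the
rewarded feature yields a coin. The rule changes without warning every
6-11 trials, either within the relevant dimension (ID shift: same
dimension, new rewarded feature) or across dimensions (ED shift). Three
levels of increasing difficulty: level 1 has 2 stimuli x 2 dimensions
(60 trials, two blocks of 30), level 2 adds a third dimension (70 trials),
level 3 adds a third stimulus (70 trials), for 200 trials in total.

Every dimension's full feature set is laid out on each trial, one feature
per stimulus, with the pairing re-randomised per trial; hence exactly one
displayed stimulus carries the rewarded feature.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Optional, Sequence

import numpy as np

__all__ = [
    "DimensionSpec",
    "LevelSpec",
    "Rule",
    "ShiftEvent",
    "ShiftSchedule",
    "StimulusDisplay",
    "TrialRecord",
    "make_default_levels",
    "sample_shift_schedule",
    "sample_trial_layout",
    "evaluate_choice",
    "run_level",
    "random_policy",
]


@dataclass(frozen=True)
class DimensionSpec:
    """A stimulus dimension (e.g. colour) and its ordered feature labels."""

    name: str
    features: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.features) < 2:
            raise ValueError(f"dimension {self.name!r} needs >=2 features")
        if len(set(self.features)) != len(self.features):
            raise ValueError(f"duplicate features in dimension {self.name!r}")


@dataclass(frozen=True)
class Rule:
    """The currently rewarded (dimension, feature) pair."""

    dimension: str
    rewarded_feature: str


@dataclass(frozen=True)
class LevelSpec:
    """Static configuration of one task level."""

    level_id: int
    n_stimuli: int
    dimensions: tuple[DimensionSpec, ...]
    n_blocks: int
    trials_per_block: int
    shift_gap_min: int = 6
    shift_gap_max: int = 11

    def __post_init__(self) -> None:
        feats = [f for d in self.dimensions for f in d.features]
        if len(set(feats)) != len(feats):
            raise ValueError("feature labels must be unique across dimensions")
        for d in self.dimensions:
            if len(d.features) != self.n_stimuli:
                raise ValueError(
                    f"dimension {d.name!r} has {len(d.features)} features; "
                    f"level {self.level_id} displays {self.n_stimuli} stimuli"
                )
        if not (1 <= self.shift_gap_min <= self.shift_gap_max):
            raise ValueError("invalid shift gap bounds")

    @property
    def n_trials(self) -> int:
        return self.n_blocks * self.trials_per_block

    @property
    def features(self) -> tuple[str, ...]:
        """All unique features across the display, in dimension order."""
        return tuple(f for d in self.dimensions for f in d.features)

    def block_of(self, trial_index: int) -> int:
        return trial_index // self.trials_per_block


@dataclass(frozen=True)
class ShiftEvent:
    """A covert rule change taking effect at ``trial_index`` (0-based)."""

    trial_index: int
    shift_type: str  # "ID" | "ED"
    old_rule: Rule
    new_rule: Rule


@dataclass(frozen=True)
class ShiftSchedule:
    """Initial rule plus the ordered covert shift events of one level."""

    initial_rule: Rule
    events: tuple[ShiftEvent, ...]

    def rule_at(self, trial_index: int) -> Rule:
        rule = self.initial_rule
        for ev in self.events:
            if ev.trial_index <= trial_index:
                rule = ev.new_rule
            else:
                break
        return rule

    def rules_by_trial(self, n_trials: int) -> list[Rule]:
        rules = []
        rule = self.initial_rule
        idx = {ev.trial_index: ev.new_rule for ev in self.events}
        for t in range(n_trials):
            rule = idx.get(t, rule)
            rules.append(rule)
        return rules


@dataclass(frozen=True)
class StimulusDisplay:
    """One trial's layout: per stimulus, the tuple of features it carries.

    Feature order within a stimulus follows the level's dimension order.
    """

    stimuli: tuple[tuple[str, ...], ...]

    @property
    def n_stimuli(self) -> int:
        return len(self.stimuli)

    def features_of(self, index: int) -> tuple[str, ...]:
        if not 0 <= index < len(self.stimuli):
            raise IndexError(f"stimulus index {index} out of range")
        return self.stimuli[index]

    @property
    def all_features(self) -> tuple[str, ...]:
        return tuple(f for s in self.stimuli for f in s)


@dataclass
class TrialRecord:
    """One behavioural trial: display, rule, choice, outcome, report."""

    participant_id: str
    level_id: int
    block: int
    trial_index: int
    display: StimulusDisplay
    rule: Rule
    is_shift_trial: bool
    shift_type: str  # "ID" | "ED" | "none"
    choice: int
    outcome: int
    confidence: Optional[float] = None
    rt: Optional[float] = None
    slider_start: Optional[int] = None  # random slider start; no behavioural role


def make_default_levels() -> list[LevelSpec]:
    """The default three-level design: 60/70/70 trials, 2/2/3 stimuli.

    Level 1: 2 dimensions x 2 features; level 2 introduces a third
    dimension (still 2 stimuli); level 3 adds a third stimulus, so every
    dimension carries 3 features.
    """
    l1 = LevelSpec(
        level_id=1,
        n_stimuli=2,
        dimensions=(
            DimensionSpec("color", ("orange", "blue")),
            DimensionSpec("shape", ("round", "star")),
        ),
        n_blocks=2,
        trials_per_block=30,
    )
    l2 = LevelSpec(
        level_id=2,
        n_stimuli=2,
        dimensions=(
            DimensionSpec("color", ("green", "purple")),
            DimensionSpec("shape", ("square", "triangle")),
            DimensionSpec("hair", ("hair", "no-hair")),
        ),
        n_blocks=2,
        trials_per_block=35,
    )
    l3 = LevelSpec(
        level_id=3,
        n_stimuli=3,
        dimensions=(
            DimensionSpec("color", ("red", "yellow", "cyan")),
            DimensionSpec("shape", ("oval", "spiky", "blob")),
            DimensionSpec("hair", ("curly", "straight", "bald")),
        ),
        n_blocks=2,
        trials_per_block=35,
    )
    return [l1, l2, l3]


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    if not isinstance(seed, (int, np.integer)):
        raise TypeError(f"seed must be an integer or Generator, got {type(seed).__name__}")
    return np.random.default_rng(seed)


def _draw_rule(level: LevelSpec, rng: np.random.Generator) -> Rule:
    dim = level.dimensions[rng.integers(len(level.dimensions))]
    feat = dim.features[rng.integers(len(dim.features))]
    return Rule(dim.name, feat)


def _draw_shifted_rule(level: LevelSpec, old: Rule, shift_type: str,
                       rng: np.random.Generator) -> Rule:
    if shift_type == "ID":
        dim = next(d for d in level.dimensions if d.name == old.dimension)
        options = [f for f in dim.features if f != old.rewarded_feature]
        return Rule(dim.name, options[rng.integers(len(options))])
    if shift_type == "ED":
        others = [d for d in level.dimensions if d.name != old.dimension]
        dim = others[rng.integers(len(others))]
        return Rule(dim.name, dim.features[rng.integers(len(dim.features))])
    raise ValueError(f"unknown shift type {shift_type!r}")


def sample_shift_schedule(level: LevelSpec, seed) -> ShiftSchedule:
    """Sample the covert rule schedule for one level.

    Inter-shift gaps are i.i.d. uniform on {gap_min..gap_max} (default
    6..11); the first shift occurs one gap after the level start, so trial
    0 is never a shift trial. Each shift is ID or ED with probability 1/2,
    constrained so every block containing at least two shifts sees both
    types. Block boundaries do not reset the gap counter.
    """
    rng = _as_rng(seed)
    initial = _draw_rule(level, rng)

    positions: list[int] = []
    t = int(rng.integers(level.shift_gap_min, level.shift_gap_max + 1))
    while t < level.n_trials:
        positions.append(t)
        t += int(rng.integers(level.shift_gap_min, level.shift_gap_max + 1))

    blocks = [level.block_of(p) for p in positions]
    for _ in range(1000):
        types = ["ID" if rng.random() < 0.5 else "ED" for _ in positions]
        ok = True
        for b in set(blocks):
            tb = [ty for ty, bb in zip(types, blocks) if bb == b]
            if len(tb) >= 2 and len(set(tb)) < 2:
                ok = False
                break
        if ok:
            break
    else:  # pragma: no cover - 1000 Bernoulli draws cannot all collide
        raise RuntimeError("could not satisfy per-block shift-type constraint")

    events = []
    rule = initial
    for pos, ty in zip(positions, types):
        new = _draw_shifted_rule(level, rule, ty, rng)
        events.append(ShiftEvent(pos, ty, rule, new))
        rule = new
    return ShiftSchedule(initial, tuple(events))


def sample_trial_layout(level: LevelSpec, seed) -> StimulusDisplay:
    """Randomise the feature-to-stimulus assignment for one trial.

    Each dimension's features are permuted over the stimuli, so every
    feature appears on exactly one stimulus and, within each dimension,
    the displayed stimuli carry pairwise distinct features.
    """
    rng = _as_rng(seed)
    cols = []
    for dim in level.dimensions:
        perm = rng.permutation(level.n_stimuli)
        cols.append([dim.features[p] for p in perm])
    stimuli = tuple(tuple(col[i] for col in cols) for i in range(level.n_stimuli))
    return StimulusDisplay(stimuli)


def evaluate_choice(display: StimulusDisplay, choice: int, rule: Rule) -> int:
    """Coin (1) iff the chosen stimulus carries the rewarded feature."""
    feats = display.features_of(choice)
    return int(rule.rewarded_feature in feats)


def random_policy(display: StimulusDisplay, history: Sequence[TrialRecord],
                  rng: np.random.Generator) -> int:
    return int(rng.integers(display.n_stimuli))


def run_level(
    level: LevelSpec,
    policy: Callable,
    seed,
    participant_id: str = "sim",
    schedule: Optional[ShiftSchedule] = None,
) -> list[TrialRecord]:
    """Run one level under a choice policy, returning one record per trial.

    ``policy(display, history, rng)`` must return a valid stimulus index;
    ``history`` is the list of completed TrialRecords of this level.
    """
    rng = _as_rng(seed)
    if schedule is None:
        schedule = sample_shift_schedule(level, rng)
    rules = schedule.rules_by_trial(level.n_trials)
    shift_at = {ev.trial_index: ev.shift_type for ev in schedule.events}

    records: list[TrialRecord] = []
    for t in range(level.n_trials):
        display = sample_trial_layout(level, rng)
        choice = int(policy(display, records, rng))
        if not 0 <= choice < display.n_stimuli:
            raise ValueError(f"policy returned invalid stimulus index {choice}")
        outcome = evaluate_choice(display, choice, rules[t])
        records.append(
            TrialRecord(
                participant_id=participant_id,
                level_id=level.level_id,
                block=level.block_of(t),
                trial_index=t,
                display=display,
                rule=rules[t],
                is_shift_trial=t in shift_at,
                shift_type=shift_at.get(t, "none"),
                choice=choice,
                outcome=outcome,
                slider_start=int(rng.integers(1, 101)),
            )
        )
    return records
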