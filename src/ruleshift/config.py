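"""Run configuration: a small YAML-round-trippable record of everything a
reproduction run needs (seeds, task geometry, group presets, model toggles)."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from .task import DimensionSpec, LevelSpec, make_default_levels

__all__ = ["RunConfig", "levels_from_config", "levels_to_config"]


@dataclass
class RunConfig:
    seed: int = 0
    n_per_group: int = 29
    delta_b: float = 12.0
    delta_w: float = 3.0
    exclusion_mode: str = "weighted"  # "weighted" | "per_level"
    model_spec: str = "joint"  # "joint" | "gc_only"
    output_dir: str = "results"
    levels: list = field(default_factory=list)  # [] -> package defaults

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        return cls(**data)

    def as_dict(self) -> dict:
        return asdict(self)


def levels_to_config(levels) -> list:
    return [
        dict(
            level_id=lv.level_id,
            n_stimuli=lv.n_stimuli,
            n_blocks=lv.n_blocks,
            trials_per_block=lv.trials_per_block,
            shift_gap_min=lv.shift_gap_min,
            shift_gap_max=lv.shift_gap_max,
            dimensions={d.name: list(d.features) for d in lv.dimensions},
        )
        for lv in levels
    ]


def levels_from_config(config: "RunConfig | list"):
    entries = config.levels if isinstance(config, RunConfig) else config
    if not entries:
        return make_default_levels()
    return [
        LevelSpec(
            level_id=e["level_id"],
            n_stimuli=e["n_stimuli"],
            dimensions=tuple(
                DimensionSpec(name, tuple(feats))
                for name, feats in e["dimensions"].items()
            ),
            n_blocks=e["n_blocks"],
            trials_per_block=e["trials_per_block"],
            shift_gap_min=e.get("shift_gap_min", 6),
            shift_gap_max=e.get("shift_gap_max", 11),
        )
        for e in entries
    ]
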