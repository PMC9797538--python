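"""Run configuration: a fully serializable description of a pipeline run.

Loaded from YAML (JSON is a subset of YAML, so plain JSON files work too).
Unknown keys are rejected so typos cannot silently change a run.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .protocol import ProtocolTimeline
from .synth import EffectProfile


@dataclass
class RunConfig:
    n_subjects: int = 172
    seed: int = 0
    effects: EffectProfile = field(default_factory=EffectProfile)
    timeline: ProtocolTimeline = field(default_factory=ProtocolTimeline.default)
    modalities: tuple[str, ...] = ("EEG", "EMG", "COP")
    lobe_map_path: str | None = None
    platform_x_cm: float = 50.0
    platform_y_cm: float = 50.0
    test_fraction: float = 0.2
    cv_folds: int = 10
    group_by_subject: bool = True
    rank_boot: int = 0
    # (merge configuration, modality set) pairs to run; defaults to the
    # standard nine-row grid over the four biosignal sets.
    grid: tuple[tuple[str, tuple[str, ...]], ...] = (
        ("binary_bl", ("EEG",)),
        ("six_phase", ("EEG",)),
        ("six_phase", ("EMG",)),
        ("five_phase", ("EMG",)),
        ("four_phase_movement", ("EMG",)),
        ("five_phase", ("COP",)),
        ("three_phase_movement", ("COP",)),
        ("five_phase", ("EMG", "COP")),
        ("three_phase_movement", ("EMG", "COP")),
    )

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["effects"] = self.effects.to_dict()
        d["timeline"] = self.timeline.to_dict()
        d["modalities"] = list(self.modalities)
        d["grid"] = [[m, list(mods)] for m, mods in self.grid]
        return d

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        raw = dict(raw)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "effects" in raw and not isinstance(raw["effects"], EffectProfile):
            raw["effects"] = EffectProfile(**raw["effects"])
        if "timeline" in raw and not isinstance(raw["timeline"], ProtocolTimeline):
            raw["timeline"] = ProtocolTimeline.from_dict(raw["timeline"])
        if "modalities" in raw:
            raw["modalities"] = tuple(raw["modalities"])
        if "grid" in raw:
            raw["grid"] = tuple((m, tuple(mods)) for m, mods in raw["grid"])
        return cls(**raw)

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))
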