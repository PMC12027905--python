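"""YAML configuration holding every tunable of the pipeline.

The defaults equal the study values (500 Hz, 11.36 deg/s, windows 11/100/
500/1000 samples, 20 deg/s saccade threshold, q = 0.05).  Unknown keys are
rejected so typos fail loudly, and a config round-trips losslessly through
its YAML file.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .session import StimulusSpec
from .synth import SimulationParams

__all__ = ["SessionConfig"]


def _to_plain(obj):
    if isinstance(obj, tuple):
        return [_to_plain(x) for x in obj]
    if isinstance(obj, dict):
        return {k: _to_plain(v) for k, v in obj.items()}
    return obj


def _retuple(cls, data: dict) -> dict:
    """YAML has no tuples; restore them from the dataclass field types."""
    out = dict(data)
    for f in dataclasses.fields(cls):
        if f.name in out and isinstance(out[f.name], list):
            out[f.name] = tuple(out[f.name])
    return out


@dataclass
class SessionConfig:
    """Bundle of all module tunables plus the simulation seed."""

    stimulus: StimulusSpec = field(default_factory=StimulusSpec)
    simulation: SimulationParams = field(default_factory=SimulationParams)
    # preprocessing
    sentinel_high: float = 100_000.0
    position_ma_window: int = 11
    pupil_smooth_window: int = 100
    # OKN pipeline
    saccade_threshold: float = 20.0
    spv_smooth_window: int = 1000
    # latency
    accel_smooth_window: int = 500
    search_halfwidth: float = 1.5
    # statistics
    q: float = 0.05
    paired: bool = True
    # session
    seed: int = 0

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return _to_plain(d)

    @classmethod
    def from_dict(cls, data: dict) -> "SessionConfig":
        data = dict(data)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "stimulus" in data:
            sub = _retuple(StimulusSpec, data["stimulus"])
            extra = set(sub) - {f.name for f in dataclasses.fields(StimulusSpec)}
            if extra:
                raise ValueError(f"unknown stimulus keys: {sorted(extra)}")
            data["stimulus"] = StimulusSpec(**sub)
        if "simulation" in data:
            sub = _retuple(SimulationParams, data["simulation"])
            extra = set(sub) - {f.name for f in dataclasses.fields(SimulationParams)}
            if extra:
                raise ValueError(f"unknown simulation keys: {sorted(extra)}")
            data["simulation"] = SimulationParams(**sub)
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SessionConfig":
        data = yaml.safe_load(Path(path).read_text())
        if not isinstance(data, dict):
            raise ValueError(f"config file {path} does not hold a mapping")
        return cls.from_dict(data)
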