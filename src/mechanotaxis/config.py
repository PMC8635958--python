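"""Run configuration: defaults profile, overrides, YAML/JSON round trip.

Parameter values that the underlying study leaves open (rates, force
magnitudes, the strain band, time steps) ship as a calibrated ``defaults``
profile; every field can be overridden per run.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import yaml

from .mechanics import MechanicsParams
from .mechanosensing import MechanoParams
from .signaling import SignalingParams

__all__ = ["MeshConfig", "ScheduleConfig", "SimConfig", "apply_overrides"]


@dataclass
class MeshConfig:
    diameter: float = 10.0     # μm
    n_membrane: int = 45
    n_interior: int = 421


@dataclass
class ScheduleConfig:
    t_end: float = 900.0           # s
    stimulus_onset: float | None = None   # s; None = no stimulus
    gradient_percent: float = 2.0
    gradient_angle_deg: float = 90.0      # relative to polarity at onset
    concentration_at_cell: float = 1.0    # source normalization at placement
    record_every: float = 25.0            # scalar/trajectory cadence, s
    kymo_every: float = 5.0               # kymograph cadence, s
    snapshot_every: float = 30.0          # shape snapshot cadence, s

    def __post_init__(self) -> None:
        if self.t_end <= 0:
            raise ValueError("t_end must be positive")


@dataclass
class SimConfig:
    mesh: MeshConfig = field(default_factory=MeshConfig)
    mechanics: MechanicsParams = field(default_factory=MechanicsParams)
    signaling: SignalingParams = field(default_factory=SignalingParams)
    mechano: MechanoParams = field(default_factory=MechanoParams)
    schedule: ScheduleConfig = field(default_factory=ScheduleConfig)
    master_seed: int = 0

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        return cls(
            mesh=MeshConfig(**d.get("mesh", {})),
            mechanics=MechanicsParams(**d.get("mechanics", {})),
            signaling=SignalingParams(**d.get("signaling", {})),
            mechano=MechanoParams(**d.get("mechano", {})),
            schedule=ScheduleConfig(**d.get("schedule", {})),
            master_seed=int(d.get("master_seed", 0)),
        )

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "SimConfig":
        return cls.from_dict(yaml.safe_load(text))

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), sort_keys=True)

    def copy(self) -> "SimConfig":
        return SimConfig.from_dict(self.to_dict())


def apply_overrides(config: SimConfig, overrides: dict | None) -> SimConfig:
    """Return a copy of ``config`` with dotted-path overrides applied,
    e.g. {"mechano.filgap_total": 0.0, "signaling.n_pi3k_total": 240}."""
    cfg = config.copy()
    for path, value in (overrides or {}).items():
        obj = cfg
        *head, leaf = path.split(".")
        for part in head:
            obj = getattr(obj, part)
        if not hasattr(obj, leaf):
            raise AttributeError(f"unknown config field {path!r}")
        setattr(obj, leaf, value)
    # re-run validation
    return SimConfig.from_dict(cfg.to_dict())
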