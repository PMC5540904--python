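"""Structured run configuration: every tunable in one serializable record.

A run is reproducible from its :class:`RunConfig` alone; the CLI logs the
fully-resolved config (all defaults filled in) before executing, and embeds
the master seed and tool version in every output file.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields

import yaml

from .cx_model import ArchConfig, DynamicsConfig
from .motor_readout import DEFAULT_THETA_ACT


@dataclass
class RunConfig:
    arena_kind: str = "open"
    condition: str = "combined"
    # neural constants
    tau_g: float = 0.1
    dt: float = 0.01
    decision_interval: float = 0.1
    trial_duration: float = 30.0
    integrator: str = "exponential"
    theta_act: float = DEFAULT_THETA_ACT
    lateral_inhibition: float = -0.3
    eb_lal_gating: float = -0.2
    lal_eb_feedback: float = 0.2
    hemisphere_shared: bool = True
    # search settings
    n_samples: int = 10_000
    master_seed: int = 1
    batch_size: int = 4096
    # manipulation settings
    manipulation_value: float = 0.0
    manipulation_scope: str = "all"
    manipulation_layer: "int | None" = None
    # intentional condition
    intentional_budget: float = 60.0

    def dynamics(self) -> DynamicsConfig:
        return DynamicsConfig(
            tau_g=self.tau_g,
            dt=self.dt,
            decision_interval=self.decision_interval,
            trial_duration=self.trial_duration,
            integrator=self.integrator,
        )

    def arch(self) -> ArchConfig:
        return ArchConfig(
            lateral_inhibition=self.lateral_inhibition,
            eb_lal_gating=self.eb_lal_gating,
            lal_eb_feedback=self.lal_eb_feedback,
            hemisphere_shared=self.hemisphere_shared,
        )

    def to_dict(self) -> dict:
        return asdict(self)

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=True)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    @classmethod
    def from_yaml(cls, text: str) -> "RunConfig":
        data = yaml.safe_load(text) or {}
        if not isinstance(data, dict):
            raise ValueError("config file must contain a mapping")
        return cls.from_dict(data)


def load_config(path) -> RunConfig:
    with open(path) as fh:
        return RunConfig.from_yaml(fh.read())


def save_config(cfg: RunConfig, path) -> None:
    with open(path, "w") as fh:
        fh.write(cfg.to_yaml())
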