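"""Run configuration: tolerances, optimizer settings, report rounding.

A :class:`RunConfig` collects every knob the CLI and the report writers use.
It round-trips losslessly through YAML so a run can be reproduced from its
config file alone.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .basis_calibration import OptimizerConfig
from .core import EnergyPair
from .errors import ConfigurationError

__all__ = ["RunConfig"]


@dataclass(frozen=True)
class RunConfig:
    energy_pair: EnergyPair = field(default_factory=EnergyPair)
    fraction_sum_tol: float = 1e-6
    histology_sum_tol: float = 5e-3
    condition_ceiling: float = 1e8
    optimizer: OptimizerConfig = field(default_factory=OptimizerConfig)
    fraction_decimals: int = 3
    concentration_decimals: int = 3

    def __post_init__(self) -> None:
        for name in ("fraction_sum_tol", "histology_sum_tol", "condition_ceiling"):
            if not getattr(self, name) > 0:
                raise ConfigurationError(f"{name} must be > 0")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        data = dict(data)
        if "energy_pair" in data and isinstance(data["energy_pair"], dict):
            data["energy_pair"] = EnergyPair(**data["energy_pair"])
        if "optimizer" in data and isinstance(data["optimizer"], dict):
            opt = dict(data["optimizer"])
            for key in ("c_bounds", "f4_bounds"):
                if key in opt and opt[key] is not None:
                    opt[key] = tuple(opt[key])
            data["optimizer"] = OptimizerConfig(**opt)
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        return cls.from_dict(data or {})
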