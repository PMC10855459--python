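"""YAML run configuration.

A run is fully reproducible from config + seed: the master seed is the
single source of randomness, and per-component streams (box builder,
velocity initialisation, thermostat) are derived from it by fixed
offsets, so each component is independently reproducible.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

__all__ = ["RunConfig", "ConfigError", "component_seed", "SEED_OFFSETS"]

#: fixed offsets carving independent streams out of one master seed
SEED_OFFSETS = {"builder": 0, "velocities": 1, "thermostat": 2, "fixture": 3}


class ConfigError(ValueError):
    pass


def component_seed(master_seed: int, component: str) -> int:
    if component not in SEED_OFFSETS:
        raise ConfigError(f"unknown seed component {component!r}")
    return (int(master_seed) * 8 + SEED_OFFSETS[component]) % (2**31 - 1)


_VALID_SECTIONS = {"system", "model", "integrator", "region", "alchemy",
                   "outputs", "seed"}
_VALID_ENSEMBLES = {"nve", "nvt"}


@dataclass
class RunConfig:
    system: dict = field(default_factory=dict)
    model: dict = field(default_factory=lambda: {"builtin": "water"})
    integrator: dict = field(default_factory=dict)
    region: dict = field(default_factory=dict)
    alchemy: dict = field(default_factory=dict)
    outputs: dict = field(default_factory=dict)
    seed: int = 0

    def validate(self) -> "RunConfig":
        if not ({"builder", "file"} & set(self.system)):
            raise ConfigError("system section needs 'builder' or 'file'")
        if not ({"builtin", "path"} & set(self.model)):
            raise ConfigError("model section needs 'builtin' or 'path'")
        ens = self.integrator.get("ensemble", "nve")
        if ens not in _VALID_ENSEMBLES:
            raise ConfigError(f"unknown ensemble {ens!r}")
        if self.integrator.get("dt", 2e-4) <= 0:
            raise ConfigError("dt must be positive")
        lam = self.model.get("lambda", 1.0)
        if not 0.0 <= lam <= 1.0:
            raise ConfigError("model lambda must lie in [0, 1]")
        return self

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        unknown = set(data) - _VALID_SECTIONS
        if unknown:
            raise ConfigError(f"unknown config sections: {sorted(unknown)}")
        return cls(**data).validate()

    @classmethod
    def load(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        if not isinstance(data, dict):
            raise ConfigError("config file must hold a mapping")
        return cls.from_dict(data)

    def save(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))
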