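"""Serializable experiment configuration for reproducible runs."""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

__all__ = ["ExperimentConfig"]

_KNOWN_PROTOCOLS = ("variance-epochs", "angle-epochs", "angle-recovery",
                    "gamma-sweep",
                    "anisotropy-sweep", "ablation-grid", "biochem", "ceiling")


@dataclass(frozen=True)
class ExperimentConfig:
    """A fully serializable description of one experiment run.

    ``options`` are the keyword arguments of the protocol (grids, durations,
    circuit parameters); seeds are explicit and never wall-clock derived.
    Round-trips losslessly through YAML; the canonical-JSON hash identifies
    the configuration in run manifests.
    """

    protocol: str
    seed: int
    options: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.protocol not in _KNOWN_PROTOCOLS:
            raise ValueError(
                f"unknown protocol {self.protocol!r}; expected one of "
                f"{_KNOWN_PROTOCOLS}")
        if not isinstance(self.seed, int):
            raise ValueError("seed must be an integer")
        bad = [k for k in self.options if not isinstance(k, str)]
        if bad:
            raise ValueError(f"option keys must be strings, got {bad}")

    def to_dict(self) -> dict:
        return {"protocol": self.protocol, "seed": self.seed,
                "options": dict(self.options)}

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        unknown = set(d) - {"protocol", "seed", "options"}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        missing = {"protocol", "seed"} - set(d)
        if missing:
            raise ValueError(f"config missing keys: {sorted(missing)}")
        return cls(protocol=d["protocol"], seed=int(d["seed"]),
                   options=dict(d.get("options", {})))

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))
        return path

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ExperimentConfig":
        data = yaml.safe_load(Path(path).read_text())
        if not isinstance(data, dict):
            raise ValueError("config file must hold a mapping")
        return cls.from_dict(data)

    @property
    def sha256(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True,
                          separators=(",", ":")).encode()
        return hashlib.sha256(blob).hexdigest()
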