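"""Run configuration: every random procedure reads its seed from here.

A :class:`RunConfig` round-trips losslessly through YAML and fully
determines a simulate→fit run: experiment, observer model and parameters,
repeats, bootstrap size, seed and the normalization geometry.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .observer import ObserverParams

__all__ = ["RunConfig"]

_OBSERVER_KINDS = ("bayesian", "image_only", "veridical")


@dataclass
class RunConfig:
    experiment: int = 1
    observer_kind: str = "bayesian"
    observer: ObserverParams = field(default_factory=ObserverParams)
    #: decision noise (mm/s) for the oracle observers
    decision_noise: float = 1.0
    repeats: int = 10
    conditions: tuple = ("H-/B-", "H+/B-", "H-/B+", "H+/B+")
    bootstrap_b: int = 1000
    seed: int = 0
    pairing: str = "monotone"
    normalization_diameter_mm: float = 35.0
    normalization_distance_mm: float = 449.0

    def __post_init__(self) -> None:
        if self.experiment not in (1, 2):
            raise ValueError("experiment must be 1 or 2")
        if self.observer_kind not in _OBSERVER_KINDS:
            raise ValueError(f"observer_kind must be one of {_OBSERVER_KINDS}")
        if self.repeats < 1:
            raise ValueError("repeats must be >= 1")
        if isinstance(self.observer, dict):
            self.observer = ObserverParams(**self.observer)
        self.conditions = tuple(self.conditions)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["conditions"] = list(self.conditions)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        return cls(**d)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))
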