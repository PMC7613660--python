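"""Pipeline configuration with protocol defaults.

The defaults reproduce the canonical retrieval protocol: a 1000-sample LHS
training database augmented with 12 bare and 27 senescent records, active
learning from 10 initial samples for up to 1000 iterations, and 10 spectral
bands throughout.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

__all__ = ["TrainingConfig", "ALConfig", "GPRConfig", "MappingConfig",
           "PipelineConfig"]


@dataclass
class TrainingConfig:
    n: int = 1000
    seed: int = 0
    backend: str = "surrogate"
    n_bare: int = 12
    n_senescent: int = 27
    ranges: dict | None = None


@dataclass
class ALConfig:
    n_init: int = 10
    max_iter: int = 1000
    hyp_refresh: int = 10


@dataclass
class GPRConfig:
    n_restarts: int = 5
    ard: bool = False
    max_opt_iter: int = 100


@dataclass
class MappingConfig:
    clip_negative: bool = True
    nodata: float = -9999.0


@dataclass
class PipelineConfig:
    training: TrainingConfig = field(default_factory=TrainingConfig)
    al: ALConfig = field(default_factory=ALConfig)
    gpr: GPRConfig = field(default_factory=GPRConfig)
    mapping: MappingConfig = field(default_factory=MappingConfig)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        return cls(
            training=TrainingConfig(**d.get("training", {})),
            al=ALConfig(**d.get("al", {})),
            gpr=GPRConfig(**d.get("gpr", {})),
            mapping=MappingConfig(**d.get("mapping", {})),
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict()))
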