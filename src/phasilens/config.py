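"""Pipeline configuration: one YAML key-value file drives every stage.

Defaults match the printed tool parameters where available (adapter,
min_len 18, mincov 15, foldsize 340, one mapping mismatch, 21-nt
period); everything else is a declared package default.
"""

from __future__ import annotations

import dataclasses
import hashlib
from dataclasses import dataclass, field
from typing import List, Tuple

import yaml

from .errors import ConfigError
from .preprocess import DEFAULT_ADAPTER


@dataclass
class PipelineConfig:
    # preprocess
    adapter: str = DEFAULT_ADAPTER
    min_len: int = 18
    # mirna annotation
    mincov: int = 15
    foldsize: int = 340
    max_mismatch: int = 1
    # slicing / phasing
    period: int = 21
    penalty_max: float = 7.0
    category_max: int = 4
    score_min: float = 4.0
    window_cycles: int = 10
    # generator
    seed: int = 42
    depth: int = 400
    noise_fraction: float = 0.15
    p_mono_U: float = 0.93
    n_cycles: int = 8
    intron_lengths: List[int] = field(default_factory=lambda: [1113, 1340])
    rnaseq_depth: int = 300

    def validate(self) -> None:
        if self.min_len < 1:
            raise ConfigError("min_len must be >= 1")
        if self.mincov < 1:
            raise ConfigError("mincov must be >= 1")
        if self.max_mismatch not in (0, 1):
            raise ConfigError("max_mismatch must be 0 or 1")
        if self.period < 18:
            raise ConfigError("period must be >= 18")
        if not (0.0 <= self.p_mono_U <= 1.0):
            raise ConfigError("p_mono_U must be in [0, 1]")
        if self.depth <= 0 or self.rnaseq_depth <= 0:
            raise ConfigError("depths must be > 0")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**data)
        cfg.validate()
        return cfg

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        try:
            with open(path) as fh:
                data = yaml.safe_load(fh) or {}
        except yaml.YAMLError as exc:
            raise ConfigError(f"cannot parse config {path}: {exc}") from exc
        if not isinstance(data, dict):
            raise ConfigError(f"config {path} is not a key-value mapping")
        return cls.from_dict(data)

    def param_hash(self) -> str:
        payload = yaml.safe_dump(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha1(payload).hexdigest()[:12]
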