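"""Pipeline configuration: YAML-backed, strictly validated dataclasses."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .model import DEFAULT_C_GRID, DEFAULT_K_GRID
from .preprocess import PreprocessConfig


@dataclass
class SimulateConfig:
    n_subjects: int = 70
    responder_fraction: float = 37 / 70
    n_channels: int = 19
    duration_s: float = 60.0
    fs: float = 500.0
    responder_coupling: float = 0.5
    nonresponder_coupling: float = 0.4
    band_name: str = "high_beta"
    phase_lag: float = 0.5
    mixing_coefficient: float = 0.0
    noise_sd: float = 1.0
    n_validation: int = 0  # extra subjects held out as an external cohort


@dataclass
class ConnectivityConfig:
    trim_fraction: float = 0.10
    hilbert_mode: str = "epoch"  # or "whole"


@dataclass
class StatsConfig:
    alpha: float = 0.05
    sync_test: str = "mann_whitney"  # or "t_test"


@dataclass
class ModelConfig:
    selector: str = "f_score"  # or "rfe"
    outer_k: int = 10
    inner_k: int = 5
    c_grid: list = field(default_factory=lambda: list(DEFAULT_C_GRID))
    k_grid: list = field(default_factory=lambda: list(DEFAULT_K_GRID))
    min_select_fraction: float = 0.5


@dataclass
class PipelineConfig:
    seed: int = 0
    simulate: SimulateConfig = field(default_factory=SimulateConfig)
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    connectivity: ConnectivityConfig = field(default_factory=ConnectivityConfig)
    stats: StatsConfig = field(default_factory=StatsConfig)
    model: ModelConfig = field(default_factory=ModelConfig)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()).hexdigest()[:12]

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        sections = {
            "simulate": SimulateConfig, "preprocess": PreprocessConfig,
            "connectivity": ConnectivityConfig, "stats": StatsConfig,
            "model": ModelConfig,
        }
        kwargs: dict = {}
        for key, val in d.items():
            if key == "seed":
                kwargs["seed"] = int(val)
            elif key in sections:
                klass = sections[key]
                allowed = {f.name for f in dataclasses.fields(klass)}
                unknown = set(val) - allowed
                if unknown:
                    raise ValueError(f"unknown keys in section {key!r}: {sorted(unknown)}")
                kwargs[key] = klass(**val)
            else:
                raise ValueError(f"unknown config key {key!r}")
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})
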