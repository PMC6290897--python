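"""Run configuration for the pipeline CLI.

A YAML file with one block per stage; unknown keys are rejected with the full
field path so typos fail before any stage runs. A single global seed
deterministically derives per-stage sub-seeds (stage-name hashing), so stages
can be re-run independently yet reproducibly.
"""
from __future__ import annotations

import dataclasses
import zlib
from pathlib import Path
from typing import Any

import yaml

from .synthetic import SyntheticConfig


class RunConfigError(ValueError):
    pass


@dataclasses.dataclass
class CitrusParams:
    min_cluster_frac: float = 0.05
    n_folds: int = 10
    fdr_target: float = 0.01
    n_perm: int = 200
    max_pooled_events: int = 15_000


@dataclasses.dataclass
class BetaPermParams:
    n_perm: int = 100


@dataclasses.dataclass
class PLSParams:
    a_grid: tuple[int, ...] = (1, 2, 3, 4, 5)
    n_perm: int = 100
    rotation_criterion: str = "class_separation"
    n_folds: int = 3


@dataclasses.dataclass
class RunConfig:
    out_dir: str = "irsigflow_out"
    seed: int = 0
    log_level: str = "INFO"
    gate_quantile: float = 0.995
    cofactor: float = 150.0
    downsample_n: int = 10_000
    citrus: CitrusParams = dataclasses.field(default_factory=CitrusParams)
    betaperm: BetaPermParams = dataclasses.field(default_factory=BetaPermParams)
    pls: PLSParams = dataclasses.field(default_factory=PLSParams)
    synthetic: SyntheticConfig = dataclasses.field(default_factory=SyntheticConfig)

    def validate(self) -> None:
        if not 0.0 < self.gate_quantile < 1.0:
            raise RunConfigError("gate_quantile must lie in (0, 1)")
        if not self.cofactor > 0:
            raise RunConfigError("cofactor must be > 0")
        if self.downsample_n < 0:
            raise RunConfigError("downsample_n must be >= 0")
        if not 0.0 < self.citrus.min_cluster_frac <= 1.0:
            raise RunConfigError("citrus.min_cluster_frac must lie in (0, 1]")
        if self.betaperm.n_perm < 20:
            raise RunConfigError("betaperm.n_perm must be >= 20")
        if self.pls.n_perm < 20:
            raise RunConfigError("pls.n_perm must be >= 20")
        if not self.pls.a_grid:
            raise RunConfigError("pls.a_grid must be non-empty")
        self.synthetic.validate()

    def stage_seed(self, stage: str) -> int:
        """Deterministic per-stage sub-seed derived from the global seed."""
        return (zlib.crc32(stage.encode()) ^ (self.seed & 0x7FFFFFFF)) & 0x7FFFFFFF

    def config_hash(self) -> str:
        return f"{zlib.crc32(repr(self).encode()):08x}"


def _build(cls, data: dict[str, Any], path: str):
    fields = {f.name: f for f in dataclasses.fields(cls)}
    unknown = set(data) - set(fields)
    if unknown:
        raise RunConfigError(f"unknown config keys at {path}: {sorted(unknown)}")
    kwargs = {}
    for name, value in data.items():
        default = (fields[name].default_factory()
                   if fields[name].default_factory is not dataclasses.MISSING else None)
        if dataclasses.is_dataclass(default):
            if not isinstance(value, dict):
                raise RunConfigError(f"{path}.{name} must be a mapping")
            kwargs[name] = _build(type(default), value, f"{path}.{name}")
        else:
            if isinstance(default, tuple) and isinstance(value, list):
                value = tuple(value)
            kwargs[name] = value
    return cls(**kwargs)


def load_config(path: str | Path | None) -> RunConfig:
    """Load a RunConfig from YAML; missing file fields keep their defaults."""
    if path is None:
        cfg = RunConfig()
    else:
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise RunConfigError("config file must be a mapping")
        cfg = _build(RunConfig, data, "config")
    cfg.validate()
    return cfg
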