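"""Pipeline configuration.

A single :class:`PipelineConfig` dataclass collects every tunable of the
workflow (resampling interval, Savitzky-Golay window, selector settings,
index families, split ratio, model grids, master seed).  Configs load from
YAML whose keys mirror the dataclass fields, and hash stably so run
manifests can state exactly which configuration produced an artifact.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

__all__ = [
    "CARSConfig", "SFLAConfig", "RFECVConfig", "SVMConfig", "CNNConfig",
    "PipelineConfig", "ConfigError", "config_hash",
]


class ConfigError(ValueError):
    """A configuration value violates its constraint."""


@dataclass
class CARSConfig:
    n_mc_runs: int = 50
    calib_fraction: float = 0.8
    folds: int = 5
    max_components: int = 10


@dataclass
class SFLAConfig:
    n_frogs: int = 50
    n_memeplexes: int = 5
    frog_cardinality: int = 15
    local_steps: int = 5
    global_iters: int = 20
    folds: int = 5
    max_components: int = 10


@dataclass
class RFECVConfig:
    folds: int = 5
    step: int = 1
    min_bands: int = 2
    max_components: int = 10


@dataclass
class SVMConfig:
    # log2 grids; epsilon is expressed as a fraction of sd(y)
    log2_C: tuple = tuple(range(-1, 10))
    log2_gamma: tuple = tuple(range(-7, 4))
    epsilon_frac: tuple = (0.01, 0.1, 0.5)
    folds: int = 5


@dataclass
class CNNConfig:
    conv_filters: tuple = (16, 32)
    kernel_size: int = 3
    dense_units: int = 32
    learning_rate: float = 1e-3
    batch_size: int = 16
    max_epochs: int = 500
    patience: int = 50
    val_fraction: float = 0.2


@dataclass
class PipelineConfig:
    """All pipeline tunables; defaults reproduce the standard workflow."""

    resample_interval_nm: float = 2.5
    resample_start_nm: float = 325.0
    resample_stop_nm: float = 1075.0
    sg_window: int = 11
    sg_polyorder: int = 3
    cars: CARSConfig = field(default_factory=CARSConfig)
    sfla: SFLAConfig = field(default_factory=SFLAConfig)
    rfecv: RFECVConfig = field(default_factory=RFECVConfig)
    index_families: tuple = ("ARI", "CI", "DVI", "NARI")
    top_k: int = 10
    split_ratio: float = 0.7
    n_strata: int = 5
    svm: SVMConfig = field(default_factory=SVMConfig)
    cnn: CNNConfig = field(default_factory=CNNConfig)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.resample_interval_nm <= 0:
            raise ConfigError("resample_interval_nm must be > 0")
        if self.sg_window % 2 == 0 or self.sg_window <= self.sg_polyorder:
            raise ConfigError(
                "sg_window must be odd and greater than sg_polyorder"
            )
        if not 0.0 < self.split_ratio < 1.0:
            raise ConfigError("split_ratio must lie strictly in (0, 1)")
        if self.top_k < 1:
            raise ConfigError("top_k must be >= 1")

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        kwargs = dict(d)
        for name, sub in (("cars", CARSConfig), ("sfla", SFLAConfig),
                          ("rfecv", RFECVConfig), ("svm", SVMConfig),
                          ("cnn", CNNConfig)):
            if name in kwargs and isinstance(kwargs[name], dict):
                kwargs[name] = sub(**kwargs[name])
        for name in ("index_families",):
            if name in kwargs and isinstance(kwargs[name], list):
                kwargs[name] = tuple(kwargs[name])
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(Path(path)) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def config_hash(cfg: PipelineConfig) -> str:
    """Stable short hash of a config, logged with every stage."""
    blob = json.dumps(cfg.to_dict(), sort_keys=True, default=list)
    return hashlib.sha256(blob.encode()).hexdigest()[:12]
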