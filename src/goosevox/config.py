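"""Flat run configuration with YAML round-trip and strict key checking."""

from __future__ import annotations

from dataclasses import asdict, dataclass, fields
from pathlib import Path

import yaml

from .classifier import TrainConfig
from .errors import ConfigError
from .gfcc import FeatureConfig


@dataclass
class RunConfig:
    """Every tunable of the pipeline in one flat, file-backed record."""

    # feature extraction
    scale_family: str = "greenwood"
    f_min: float = 500.0
    f_max: float = 6000.0
    k: float = 0.88
    n_filters: int = 20
    n_coeffs: int = 21
    shape: str = "hamming"
    frame_len: int = 2048
    hop: int = 1024
    # selection + training
    d_target: int = 6
    grid_min: int = -10
    grid_max: int = 10
    folds: int = 5
    subsample_max: int = 600
    # evaluation
    protocol: str = "A"  # "A" (day split) or "B" (mixed k-fold)
    kfold_k: int = 5
    # generation
    snr_db: float = 10.0
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(data, dict):
            raise ConfigError(f"config file {path} must hold a key-value mapping")
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    def feature_config(self) -> FeatureConfig:
        return FeatureConfig(
            scale_family=self.scale_family, f_min=self.f_min, f_max=self.f_max,
            k=self.k, n_filters=self.n_filters, n_coeffs=self.n_coeffs,
            shape=self.shape, frame_len=self.frame_len, hop=self.hop,
        )

    def train_config(self) -> TrainConfig:
        from .gfcc import FEATURE_COLUMNS

        return TrainConfig(
            d_target=self.d_target, folds=self.folds, grid_min=self.grid_min,
            grid_max=self.grid_max, seed=self.seed,
            subsample_max=self.subsample_max,
            feature_columns=tuple(FEATURE_COLUMNS[: self.n_coeffs]),
        )
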