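"""Pipeline configuration: a single YAML file with validated defaults.

Method parameter defaults mirror the reported optima for full-resolution
462-band cubes (PCA 150 components; Folded PCA 310 components with a 151x3
fold; WaLuMI 40 bands); desk-scale synthetic runs override them.  Every
random operation takes an explicit seed from the config.
"""

from __future__ import annotations

import os
from dataclasses import asdict, dataclass, field

import yaml

__all__ = ["PipelineConfig", "ConfigError", "load_config", "save_config"]


class ConfigError(ValueError):
    """Configuration file fails schema validation."""


@dataclass
class PipelineConfig:
    # paths
    cubes_dir: str = "data/cubes"
    masks_dir: str = "data/masks"
    output_dir: str = "out"
    # split
    train_fraction: float = 0.6
    split_seed: int = 0
    # optional ROI crop: [row0, col0, height, width]
    roi: list | None = None
    # dimensionality reduction
    method: str = "pca"
    k: int = 150
    fold_height: int = 151
    fold_width: int | None = 3
    mi_bins: int = 64
    # SVM
    svm_C: float = 1.0
    svm_class_weight: str | None = "balanced"
    svm_tol: float = 1e-4
    svm_seed: int = 0
    # sweep
    sweep_ks: list | None = None
    # morphology
    morph_preset: str | None = None
    # synthetic generation
    synthetic: dict = field(default_factory=dict)

    def validate(self) -> "PipelineConfig":
        if self.method not in ("pca", "fpca", "walumi"):
            raise ConfigError(f"method must be pca/fpca/walumi, got {self.method!r}")
        if not 0 < self.train_fraction < 1:
            raise ConfigError("train_fraction must be in (0, 1)")
        if self.k < 1:
            raise ConfigError("k must be >= 1")
        if self.fold_height < 1 or (self.fold_width is not None and self.fold_width < 1):
            raise ConfigError("fold dimensions must be >= 1")
        if self.mi_bins < 2:
            raise ConfigError("mi_bins must be >= 2")
        if self.svm_C <= 0:
            raise ConfigError("svm_C must be positive")
        if self.svm_class_weight not in (None, "balanced"):
            raise ConfigError("svm_class_weight must be null or 'balanced'")
        if self.roi is not None:
            if len(self.roi) != 4 or any(int(v) != v for v in self.roi):
                raise ConfigError("roi must be [row0, col0, height, width]")
        if self.sweep_ks is not None:
            if not self.sweep_ks or any(int(k) < 1 for k in self.sweep_ks):
                raise ConfigError("sweep_ks must be a non-empty list of positive ints")
        if self.morph_preset is not None and self.morph_preset not in ("pca", "fpca", "walumi"):
            raise ConfigError(f"unknown morph_preset {self.morph_preset!r}")
        return self

    def svm_params(self) -> dict:
        return {
            "C": self.svm_C,
            "class_weight": self.svm_class_weight,
            "tol": self.svm_tol,
            "seed": self.svm_seed,
        }


def load_config(path: str | os.PathLike) -> PipelineConfig:
    """Load and validate a YAML config; unknown keys are a schema error."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigError("config must be a mapping")
    known = set(PipelineConfig.__dataclass_fields__)
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    return PipelineConfig(**raw).validate()


def save_config(config: PipelineConfig, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(asdict(config), fh, sort_keys=False)
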