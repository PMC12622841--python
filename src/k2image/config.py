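"""YAML run configuration binding the modules into reproducible runs.

A :class:`RunConfig` fully determines a run: trajectory, dataset sizes and
seeds, training hyperparameters, gridding and CS settings, output directory.
Every stochastic component carries an explicit seed, and a fully resolved
copy of the configuration is written into the output directory so a run is
reproducible from its artifacts alone.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import yaml

from .cs import CSConfig
from .nufft import GriddingConfig
from .trajectories import TrajectorySpec
from .training import TrainConfig

__all__ = ["DatasetConfig", "RunConfig"]


@dataclass
class DatasetConfig:
    """Sizes, seed, and noise settings of the synthetic dataset."""

    n_train: int = 256
    n_val: int = 64
    n_test: int = 32
    seed: int = 0
    noise_psnr_db: Optional[float] = 50.0  # None -> no noise condition

    def __post_init__(self) -> None:
        for name in ("n_train", "n_val", "n_test"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")


@dataclass
class RunConfig:
    name: str = "run"
    trajectory: TrajectorySpec = field(
        default_factory=lambda: TrajectorySpec(w_img=64, n_samples=128,
                                               n_spokes=25))
    dataset: DatasetConfig = field(default_factory=DatasetConfig)
    train: TrainConfig = field(default_factory=TrainConfig)
    gridding: Optional[GriddingConfig] = None  # None -> derived from w_img
    cs: CSConfig = field(default_factory=CSConfig)
    output_dir: str = "k2image_out"

    # -- serialization -----------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if d.get("train", {}).get("mult_noise_range") is not None:
            d["train"]["mult_noise_range"] = list(self.train.mult_noise_range)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "trajectory" in d and isinstance(d["trajectory"], dict):
            d["trajectory"] = TrajectorySpec(**d["trajectory"])
        if "dataset" in d and isinstance(d["dataset"], dict):
            d["dataset"] = DatasetConfig(**d["dataset"])
        if "train" in d and isinstance(d["train"], dict):
            t = dict(d["train"])
            if "mult_noise_range" in t and t["mult_noise_range"] is not None:
                t["mult_noise_range"] = tuple(t["mult_noise_range"])
            d["train"] = TrainConfig(**t)
        if d.get("gridding") is not None and isinstance(d["gridding"], dict):
            d["gridding"] = GriddingConfig(**d["gridding"])
        if "cs" in d and isinstance(d["cs"], dict):
            d["cs"] = CSConfig(**d["cs"])
        unknown = set(d) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as f:
            return cls.from_dict(yaml.safe_load(f) or {})

    def to_yaml(self, path) -> None:
        with open(path, "w") as f:
            yaml.safe_dump(self.to_dict(), f, sort_keys=False)

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()).hexdigest()[:16]

    def resolve_output_dir(self) -> Path:
        """Create the output directory and drop a resolved config snapshot."""
        out = Path(self.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.to_yaml(out / "config.resolved.yaml")
        return out

    def gridding_config(self) -> GriddingConfig:
        return self.gridding or GriddingConfig.for_image(self.trajectory.w_img)
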