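"""Run configuration: defaults, YAML files, and command-line overrides.

One nested mapping with ``model`` / ``train`` / ``scoring`` / ``phantom``
sections whose defaults are the pipeline's reference values (patch 15,
stride 4, latent 100, percentile 50, threshold 3, loss weights 70/10/1,
batch 64, learning rate 0.001, patience 10). Precedence is CLI override >
config file > default; unknown keys are rejected.
"""

from __future__ import annotations

import copy
import hashlib
import json
from pathlib import Path

import yaml

from .model import ModelConfig
from .phantom import LesionSpec, PhantomConfig
from .scoring import ScoringConfig
from .training import LossWeights, TrainConfig

__all__ = ["RunConfig", "DEFAULTS"]

DEFAULTS: dict = {
    "model": {
        "latent_dim": 100,
        "channel_widths": [32, 64],
        "leaky_slope": 0.2,
        "input_channels": 2,
        "patch_size": 15,
    },
    "train": {
        "batch_size": 64,
        "learning_rate": 1e-3,
        "betas": [0.5, 0.999],
        "patience_epochs": 10,
        "max_epochs": 500,
        "soft_label_fake_range": [0.0, 0.2],
        "soft_label_real_range": [0.8, 1.0],
        "label_swap": False,
        "n_train_patches": 1_000_000,
        "n_trainval_patches": 100_000,
        "loss_weights": [70.0, 10.0, 1.0],
    },
    "scoring": {
        "percentile": 50.0,
        "threshold": 3.0,
        "stride": 4,
        "min_component_patches": 2,
        "use_consistency_constant": False,
        "cross_slice_adjacency": True,
        "mad_epsilon": 1e-6,
        "min_overlap_voxels": 1,
    },
    "phantom": {
        "shape": [18, 80, 80],
        "spacing": [4.0, 0.9, 0.9],
        "noise_sd": 5.0,
        "field_amplitude": 8.0,
        "lesion_count_range": [2, 4],
        "lesion_radius_range_mm": [3.0, 6.0],
    },
    "seed": 0,
}


def _merge(base: dict, override: dict, path: str = "") -> dict:
    out = copy.deepcopy(base)
    for k, v in override.items():
        where = f"{path}.{k}" if path else k
        if k not in out:
            raise KeyError(f"unknown config key: {where}")
        if isinstance(out[k], dict):
            if not isinstance(v, dict):
                raise TypeError(f"config section {where} must be a mapping")
            out[k] = _merge(out[k], v, where)
        else:
            out[k] = v
    return out


class RunConfig:
    """Merged, validated run configuration."""

    def __init__(self, data: dict | None = None) -> None:
        self.data = _merge(DEFAULTS, data or {})

    @classmethod
    def from_file(cls, path, overrides: dict | None = None) -> "RunConfig":
        with open(path) as fh:
            file_data = yaml.safe_load(fh) or {}
        cfg = _merge(DEFAULTS, file_data)
        if overrides:
            cfg = _merge(cfg, overrides)
        out = cls.__new__(cls)
        out.data = cfg
        return out

    # -- typed views -----------------------------------------------------
    @property
    def seed(self) -> int:
        return int(self.data["seed"])

    def model_config(self, latent_dim: int | None = None) -> ModelConfig:
        m = self.data["model"]
        return ModelConfig(
            latent_dim=int(latent_dim or m["latent_dim"]),
            channel_widths=tuple(m["channel_widths"]),
            leaky_slope=m["leaky_slope"],
            input_channels=m["input_channels"],
            patch_size=m["patch_size"],
        )

    def train_config(self, seed: int | None = None) -> TrainConfig:
        t = self.data["train"]
        return TrainConfig(
            batch_size=t["batch_size"],
            learning_rate=t["learning_rate"],
            betas=tuple(t["betas"]),
            patience_epochs=t["patience_epochs"],
            max_epochs=t["max_epochs"],
            soft_label_fake_range=tuple(t["soft_label_fake_range"]),
            soft_label_real_range=tuple(t["soft_label_real_range"]),
            label_swap=t["label_swap"],
            rng_seed=self.seed if seed is None else seed,
        )

    def loss_weights(self) -> LossWeights:
        return LossWeights(*self.data["train"]["loss_weights"])

    def scoring_config(self) -> ScoringConfig:
        s = self.data["scoring"]
        return ScoringConfig(
            percentile=s["percentile"],
            threshold=s["threshold"],
            stride=s["stride"],
            patch_size=self.data["model"]["patch_size"],
            min_component_patches=s["min_component_patches"],
            use_consistency_constant=s["use_consistency_constant"],
            cross_slice_adjacency=s["cross_slice_adjacency"],
        )

    def phantom_config(self, rng_seed: int = 0) -> PhantomConfig:
        p = self.data["phantom"]
        return PhantomConfig(
            shape=tuple(p["shape"]),
            spacing=tuple(p["spacing"]),
            noise_sd=p["noise_sd"],
            field_amplitude=p["field_amplitude"],
            rng_seed=rng_seed,
        )

    def lesion_spec(self) -> LesionSpec:
        p = self.data["phantom"]
        return LesionSpec(
            count_range=tuple(p["lesion_count_range"]),
            radius_range_mm=tuple(p["lesion_radius_range_mm"]),
        )

    # -- provenance ------------------------------------------------------
    def manifest(self, inputs: list | None = None) -> dict:
        from . import __version__

        entry = {"config": self.data, "version": __version__, "inputs": []}
        for p in inputs or []:
            p = Path(p)
            digest = hashlib.sha256(p.read_bytes()).hexdigest()[:16] if p.is_file() else None
            entry["inputs"].append({"path": str(p), "sha256_16": digest})
        return entry

    def dump(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.data, fh, sort_keys=False)

    def to_json(self) -> str:
        return json.dumps(self.data, indent=2)
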