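"""Self-describing checkpoint archives: parameters + model config +
latent calibration (+ training record) in one ``.npz`` file."""

from __future__ import annotations

import json

import numpy as np

from .model import Discriminator, Generator, ModelConfig
from .scoring import LatentCalibration
from .training import TrainRecord

__all__ = ["save_checkpoint", "load_checkpoint"]


def save_checkpoint(
    path,
    generator: Generator,
    discriminator: Discriminator | None = None,
    calibration: LatentCalibration | None = None,
    train_record: TrainRecord | None = None,
) -> None:
    arrays = {f"gen/{k}": v for k, v in generator.state_arrays().items()}
    if discriminator is not None:
        arrays.update(
            {f"disc/{k}": v for k, v in discriminator.state_arrays().items()}
        )
    meta = {"config": generator.config.to_json(), "has_disc": discriminator is not None}
    if calibration is not None:
        arrays["cal/median"] = calibration.median
        arrays["cal/mad"] = calibration.mad
        meta["cal"] = {
            "n_patches_used": calibration.n_patches_used,
            "epsilon": calibration.epsilon,
        }
    if train_record is not None:
        meta["record"] = {
            "train_loss": train_record.train_loss,
            "trainval_loss": train_record.trainval_loss,
            "best_epoch": train_record.best_epoch,
            "best_trainval_loss": train_record.best_trainval_loss,
            "stopped_epoch": train_record.stopped_epoch,
        }
    arrays["meta"] = np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)
    np.savez_compressed(str(path), **arrays)


def load_checkpoint(path):
    """Returns (generator, discriminator | None, calibration | None, record | None)."""
    with np.load(str(path)) as data:
        arrays = {k: data[k] for k in data.files}
    meta = json.loads(bytes(arrays.pop("meta")).decode())
    config = ModelConfig.from_json(meta["config"])
    rng = np.random.default_rng(0)
    gen = Generator(config, rng)
    gen.load_state_arrays(
        {k[4:]: v for k, v in arrays.items() if k.startswith("gen/")}
    )
    disc = None
    if meta.get("has_disc"):
        disc = Discriminator(config, rng)
        disc.load_state_arrays(
            {k[5:]: v for k, v in arrays.items() if k.startswith("disc/")}
        )
    cal = None
    if "cal/median" in arrays:
        cal = LatentCalibration(
            median=arrays["cal/median"],
            mad=arrays["cal/mad"],
            n_patches_used=meta["cal"]["n_patches_used"],
            epsilon=meta["cal"]["epsilon"],
        )
    record = None
    if "record" in meta:
        r = meta["record"]
        record = TrainRecord(
            train_loss=r["train_loss"],
            trainval_loss=r["trainval_loss"],
            best_epoch=r["best_epoch"],
            best_trainval_loss=r["best_trainval_loss"],
            stopped_epoch=r["stopped_epoch"],
        )
    return gen, disc, cal, record
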