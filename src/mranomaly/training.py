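"""Adversarial training: three-term generator loss, soft-label
discriminator loss, early stopping on a held-out training-validation set,
and best-epoch weight selection.

Generator loss (minimized):

    L = w_con * L_con + w_enc * L_enc + w_adv * L_adv
    L_con = mean |x - x̂|            (reconstruction, L1)
    L_enc = mean (z - ẑ)^2          (latent consistency)
    L_adv = mean (f(x) - f(x̂))^2   (discriminator feature matching)

with default weights (70, 10, 1). The discriminator minimizes binary
cross-entropy against *soft* labels: real targets drawn uniformly from
[0.8, 1], fake targets from [0, 0.2], which damps vanishing gradients.
Training stops once the training-validation generator loss has not set a
new minimum for ``patience_epochs`` consecutive epochs; the returned
weights are those of the best epoch.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np

from .model import (
    Discriminator,
    Generator,
    GeneratorOutput,
    ModelConfig,
)
from .nn import Adam
from .patches import PatchSet, augment_flips

__all__ = [
    "LossWeights",
    "TrainConfig",
    "TrainRecord",
    "EarlyStopper",
    "generator_loss",
    "discriminator_loss",
    "bce",
    "train",
]


@dataclass
class LossWeights:
    w_con: float = 70.0
    w_enc: float = 10.0
    w_adv: float = 1.0

    def __post_init__(self) -> None:
        if min(self.w_con, self.w_enc, self.w_adv) < 0:
            raise ValueError("loss weights must be nonnegative")


@dataclass
class TrainConfig:
    batch_size: int = 64
    learning_rate: float = 1e-3
    betas: tuple[float, float] = (0.5, 0.999)
    patience_epochs: int = 10
    max_epochs: int = 500
    soft_label_fake_range: tuple[float, float] = (0.0, 0.2)
    soft_label_real_range: tuple[float, float] = (0.8, 1.0)
    label_swap: bool = False
    rng_seed: int = 0

    def __post_init__(self) -> None:
        fr, rr = self.soft_label_fake_range, self.soft_label_real_range
        for lo, hi in (fr, rr):
            if not (0.0 <= lo <= hi <= 1.0):
                raise ValueError("soft label ranges must lie within [0, 1]")
        if fr[1] > rr[0]:
            raise ValueError("fake and real soft-label ranges must be disjoint")
        if self.patience_epochs < 1:
            raise ValueError("patience must be >= 1")


@dataclass
class TrainRecord:
    train_loss: list = field(default_factory=list)
    trainval_loss: list = field(default_factory=list)
    components: list = field(default_factory=list)  # per-epoch trainval terms
    best_epoch: int = -1
    best_trainval_loss: float = float("inf")
    stopped_epoch: int = -1

    @property
    def n_epochs(self) -> int:
        return len(self.trainval_loss)


class EarlyStopper:
    """Stop after ``patience`` consecutive epochs without a new minimum."""

    def __init__(self, patience: int) -> None:
        self.patience = patience
        self.best = float("inf")
        self.best_epoch = -1
        self._epoch = -1

    def update(self, loss: float) -> bool:
        """Record one epoch's loss; return True when training should stop."""
        self._epoch += 1
        if loss < self.best:
            self.best = loss
            self.best_epoch = self._epoch
        return self._epoch - self.best_epoch >= self.patience


def generator_loss(
    x: np.ndarray,
    output: GeneratorOutput,
    f_x: np.ndarray,
    f_xhat: np.ndarray,
    weights: LossWeights,
) -> tuple[float, dict]:
    """Weighted three-term generator loss and its unweighted components."""
    l_con = float(np.mean(np.abs(x - output.reconstruction)))
    l_enc = float(np.mean((output.z - output.z_hat) ** 2))
    l_adv = float(np.mean((f_x - f_xhat) ** 2))
    total = weights.w_con * l_con + weights.w_enc * l_enc + weights.w_adv * l_adv
    return total, {"con": l_con, "enc": l_enc, "adv": l_adv}


def _generator_loss_grads(
    x: np.ndarray,
    output: GeneratorOutput,
    f_x: np.ndarray,
    f_xhat: np.ndarray,
    weights: LossWeights,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Gradients of the weighted loss at x̂ (direct), z, ẑ, and f(x̂)."""
    xhat = output.reconstruction
    d_xhat = weights.w_con * np.sign(xhat - x) / x.size
    dz_core = 2.0 * (output.z - output.z_hat) / output.z.size
    d_z = weights.w_enc * dz_core
    d_zhat = -weights.w_enc * dz_core
    d_fxhat = -weights.w_adv * 2.0 * (f_x - f_xhat) / f_x.size
    return (
        d_xhat.astype(np.float32),
        d_z.astype(np.float32),
        d_zhat.astype(np.float32),
        d_fxhat.astype(np.float32),
    )


def bce(p: np.ndarray, label: np.ndarray, eps: float = 1e-7) -> np.ndarray:
    """Elementwise binary cross-entropy with (possibly soft) targets."""
    p = np.clip(p, eps, 1.0 - eps)
    return -(label * np.log(p) + (1.0 - label) * np.log(1.0 - p))


def draw_soft_labels(
    n: int, rng: np.random.Generator, config: TrainConfig
) -> tuple[np.ndarray, np.ndarray]:
    rlo, rhi = config.soft_label_real_range
    flo, fhi = config.soft_label_fake_range
    l_real = rng.uniform(rlo, rhi, size=n)
    l_fake = rng.uniform(flo, fhi, size=n)
    if config.label_swap:
        l_real, l_fake = l_fake, l_real
    return l_real, l_fake


def discriminator_loss(
    p_real: np.ndarray,
    p_fake: np.ndarray,
    rng: np.random.Generator,
    config: TrainConfig | None = None,
) -> tuple[float, np.ndarray, np.ndarray]:
    """Soft-label BCE loss; returns (loss, real labels, fake labels)."""
    config = config or TrainConfig()
    p_real = np.atleast_1d(p_real)
    p_fake = np.atleast_1d(p_fake)
    l_real, l_fake = draw_soft_labels(len(p_real), rng, config)
    loss = float(np.mean(bce(p_real, l_real)) + np.mean(bce(p_fake, l_fake)))
    return loss, l_real, l_fake


def evaluate_generator_loss(
    generator: Generator,
    discriminator: Discriminator,
    patches: np.ndarray,
    weights: LossWeights,
    batch_size: int = 256,
) -> tuple[float, dict]:
    """Deterministic (evaluation-mode, unaugmented) weighted generator loss."""
    totals = np.zeros(3)
    n = len(patches)
    for i in range(0, n, batch_size):
        xb = patches[i : i + batch_size]
        out = generator.forward(xb, train=False)
        f_x = discriminator.forward(xb, train=False).features
        f_xhat = discriminator.forward(out.reconstruction, train=False).features
        _, comps = generator_loss(xb, out, f_x, f_xhat, weights)
        w = len(xb) / n
        totals += w * np.array([comps["con"], comps["enc"], comps["adv"]])
    comps = {"con": totals[0], "enc": totals[1], "adv": totals[2]}
    total = (
        weights.w_con * comps["con"]
        + weights.w_enc * comps["enc"]
        + weights.w_adv * comps["adv"]
    )
    return float(total), comps


def train(
    train_patches: PatchSet,
    trainval_patches: PatchSet,
    model_config: ModelConfig,
    train_config: TrainConfig,
    weights: LossWeights | None = None,
    callback=None,
) -> tuple[Generator, Discriminator, TrainRecord]:
    """Run the adversarial loop; return best-epoch generator/discriminator.

    Per minibatch the discriminator takes one update step first, then the
    generator. Flip augmentation is redrawn every epoch from a seed
    derived from the base seed plus the epoch index; the early-stopping
    loss is evaluated without augmentation in evaluation mode.
    """
    if len(train_patches) == 0 or len(trainval_patches) == 0:
        raise ValueError("training and training-validation patch sets must be nonempty")
    weights = weights or LossWeights()
    cfg = train_config
    master = np.random.default_rng(cfg.rng_seed)
    gen = Generator(model_config, np.random.default_rng(master.integers(2**31)))
    disc = Discriminator(model_config, np.random.default_rng(master.integers(2**31)))
    shuffle_rng = np.random.default_rng(master.integers(2**31))
    label_rng = np.random.default_rng(master.integers(2**31))
    flip_base = int(master.integers(2**31))

    opt_g = Adam(gen.parameters(), lr=cfg.learning_rate, betas=cfg.betas)
    opt_d = Adam(disc.parameters(), lr=cfg.learning_rate, betas=cfg.betas)

    record = TrainRecord()
    stopper = EarlyStopper(cfg.patience_epochs)
    best_state = None
    trainval = trainval_patches.patches

    for epoch in range(cfg.max_epochs):
        aug = augment_flips(train_patches, rng_seed=flip_base + epoch).patches
        order = shuffle_rng.permutation(len(aug))
        epoch_losses = []
        for start in range(0, len(order), cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            if len(idx) < 2:
                continue  # batch norm needs more than one sample
            x = aug[idx]

            out = gen.forward(x, train=True)
            xhat = out.reconstruction

            # --- discriminator step (x̂ treated as constant) ---
            opt_d.zero_grad()
            d_real = disc.forward(x, train=True)
            l_real, l_fake = draw_soft_labels(len(x), label_rng, cfg)
            disc.backward_from_logit((d_real.probability - l_real) / len(x))
            d_fake = disc.forward(xhat, train=True)
            disc.backward_from_logit((d_fake.probability - l_fake) / len(x))
            opt_d.step()

            # --- generator step ---
            opt_g.zero_grad()
            f_x = disc.forward(x, train=True).features
            d_out_fake = disc.forward(xhat, train=True)
            f_xhat = d_out_fake.features
            total, comps = generator_loss(x, out, f_x, f_xhat, weights)
            if not np.isfinite(total):
                raise FloatingPointError(
                    f"non-finite generator loss at epoch {epoch}"
                )
            d_xhat, d_z, d_zhat, d_fxhat = _generator_loss_grads(
                x, out, f_x, f_xhat, weights
            )
            # route the adversarial gradient through the discriminator to x̂,
            # discarding the discriminator's own parameter gradients
            d_xhat_adv = disc.backward_from_features(d_fxhat)
            for p in disc.parameters():
                p.zero_grad()
            gen.backward(d_xhat + d_xhat_adv, d_z, d_zhat)
            opt_g.step()
            epoch_losses.append(total)

        val_total, val_comps = evaluate_generator_loss(gen, disc, trainval, weights)
        record.train_loss.append(float(np.mean(epoch_losses)))
        record.trainval_loss.append(val_total)
        record.components.append(val_comps)
        improved = val_total < stopper.best
        should_stop = stopper.update(val_total)
        if improved:
            best_state = (
                copy.deepcopy(gen.state_arrays()),
                copy.deepcopy(disc.state_arrays()),
            )
        if callback is not None:
            callback(epoch, record)
        if should_stop:
            break

    record.best_epoch = stopper.best_epoch
    record.best_trainval_loss = stopper.best
    record.stopped_epoch = record.n_epochs - 1
    if best_state is not None:
        gen.load_state_arrays(best_state[0])
        disc.load_state_arrays(best_state[1])
    return gen, disc, record
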