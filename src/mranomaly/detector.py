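"""Scikit-learn style front end to the whole patch pipeline.

:class:`GanomalyPatchDetector` is an unsupervised outlier estimator over
two-channel image patches: ``fit`` trains the adversarial
encoder–decoder–encoder on normal-tissue patches and calibrates the
latent median/MAD statistics; ``anomaly_scores`` returns the modified
Z-score percentile per patch, and the sklearn outlier conventions
(``score_samples``, ``decision_function``, ``predict``) are mapped onto
it so the estimator composes with pipelines and model selection.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, OutlierMixin
from sklearn.utils.validation import check_is_fitted

from .model import ModelConfig
from .patches import PatchSet
from .scoring import (
    ScoringConfig,
    aggregate_scores,
    calibrate,
    latent_differences,
    modified_z,
    score_volume,
)
from .training import LossWeights, TrainConfig, train
from .volumes import MultiChannelVolume

__all__ = ["GanomalyPatchDetector"]


class GanomalyPatchDetector(OutlierMixin, BaseEstimator):
    """Adversarial autoencoder anomaly detector for two-channel patches.

    Parameters mirror the pipeline defaults: 15x15 patches, latent size
    100, generator loss weights (70, 10, 1), Adam at learning rate 1e-3
    with minibatches of 64, early stopping after 10 non-improving epochs
    on a training-validation split, anomaly score = 50th percentile of
    the elementwise modified Z-scores of z - ẑ, flagged above 3.

    Attributes (after ``fit``)
    --------------------------
    generator_, discriminator_ : trained networks (best epoch)
    calibration_ : per-element latent median/MAD
    train_record_ : per-epoch losses, best epoch
    """

    def __init__(
        self,
        latent_dim: int = 100,
        channel_widths: tuple[int, ...] = (32, 64),
        leaky_slope: float = 0.2,
        patch_size: int = 15,
        input_channels: int = 2,
        w_con: float = 70.0,
        w_enc: float = 10.0,
        w_adv: float = 1.0,
        batch_size: int = 64,
        learning_rate: float = 1e-3,
        betas: tuple[float, float] = (0.5, 0.999),
        patience_epochs: int = 10,
        max_epochs: int = 500,
        label_swap: bool = False,
        percentile: float = 50.0,
        threshold: float = 3.0,
        mad_epsilon: float = 1e-6,
        use_consistency_constant: bool = False,
        validation_fraction: float = 0.1,
        random_state: int | None = None,
    ) -> None:
        self.latent_dim = latent_dim
        self.channel_widths = channel_widths
        self.leaky_slope = leaky_slope
        self.patch_size = patch_size
        self.input_channels = input_channels
        self.w_con = w_con
        self.w_enc = w_enc
        self.w_adv = w_adv
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.betas = betas
        self.patience_epochs = patience_epochs
        self.max_epochs = max_epochs
        self.label_swap = label_swap
        self.percentile = percentile
        self.threshold = threshold
        self.mad_epsilon = mad_epsilon
        self.use_consistency_constant = use_consistency_constant
        self.validation_fraction = validation_fraction
        self.random_state = random_state

    # ------------------------------------------------------------------
    def _model_config(self) -> ModelConfig:
        return ModelConfig(
            latent_dim=self.latent_dim,
            channel_widths=tuple(self.channel_widths),
            leaky_slope=self.leaky_slope,
            input_channels=self.input_channels,
            patch_size=self.patch_size,
        )

    def _scoring_config(self, percentile: float | None = None) -> ScoringConfig:
        return ScoringConfig(
            percentile=self.percentile if percentile is None else percentile,
            threshold=self.threshold,
            patch_size=self.patch_size,
            use_consistency_constant=self.use_consistency_constant,
        )

    def _validate_patches(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=np.float32)
        if X.ndim != 4 or X.shape[1:] != (
            self.input_channels,
            self.patch_size,
            self.patch_size,
        ):
            raise ValueError(
                f"expected patches of shape (n, {self.input_channels}, "
                f"{self.patch_size}, {self.patch_size}), got {X.shape}"
            )
        if not np.all(np.isfinite(X)):
            raise ValueError("patches must be finite")
        return X

    # ------------------------------------------------------------------
    def fit(self, X, y=None, X_val=None):
        """Train on normal-tissue patches and calibrate latent statistics.

        ``X_val`` is the training-validation patch set driving early
        stopping; when omitted, ``validation_fraction`` of ``X`` is held
        out (prefer patches from held-out subjects when available).
        """
        X = self._validate_patches(X)
        seed = 0 if self.random_state is None else int(self.random_state)
        if X_val is None:
            rng = np.random.default_rng(seed)
            order = rng.permutation(len(X))
            n_val = max(1, int(round(self.validation_fraction * len(X))))
            if n_val >= len(X):
                raise ValueError("not enough patches to split a validation set")
            X_val, X = X[order[:n_val]], X[order[n_val:]]
        else:
            X_val = self._validate_patches(X_val)
        gen, disc, record = train(
            PatchSet(X),
            PatchSet(X_val),
            self._model_config(),
            TrainConfig(
                batch_size=self.batch_size,
                learning_rate=self.learning_rate,
                betas=tuple(self.betas),
                patience_epochs=self.patience_epochs,
                max_epochs=self.max_epochs,
                label_swap=self.label_swap,
                rng_seed=seed,
            ),
            LossWeights(self.w_con, self.w_enc, self.w_adv),
        )
        self.generator_ = gen
        self.discriminator_ = disc
        self.train_record_ = record
        self.calibration_ = calibrate(gen, PatchSet(X), epsilon=self.mad_epsilon)
        self.n_features_in_ = int(np.prod(X.shape[1:]))
        return self

    # ------------------------------------------------------------------
    def transform(self, X) -> np.ndarray:
        """Elementwise modified Z-scores, one row per patch."""
        check_is_fitted(self, "calibration_")
        X = self._validate_patches(X)
        d = latent_differences(self.generator_, X)
        return modified_z(d, self.calibration_, self.use_consistency_constant)

    def anomaly_scores(self, X) -> np.ndarray:
        """Per-patch anomaly score: Nth percentile of the elementwise
        modified Z-scores (higher = more anomalous)."""
        return aggregate_scores(self.transform(X), self.percentile)

    def score_samples(self, X) -> np.ndarray:
        """Sklearn convention: higher = more normal."""
        return -self.anomaly_scores(X)

    def decision_function(self, X) -> np.ndarray:
        """Positive for patches below the flagging threshold (inliers)."""
        return self.threshold - self.anomaly_scores(X)

    def predict(self, X) -> np.ndarray:
        """+1 for normal patches, -1 for flagged (score > threshold)."""
        return np.where(self.decision_function(X) >= 0, 1, -1)

    # ------------------------------------------------------------------
    def score_volume(self, volume: MultiChannelVolume, percentile=None, stride=4):
        """Dense-grid anomaly map of one normalized volume."""
        check_is_fitted(self, "calibration_")
        cfg = self._scoring_config(percentile)
        cfg.stride = stride
        return score_volume(self.generator_, self.calibration_, volume, cfg)
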