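"""Encoder–decoder–encoder generator and discriminator for 15x15 patches.

The generator maps a two-channel patch x to a latent vector z (encoder),
reconstructs x̂ from z (decoder), and re-encodes x̂ to ẑ with a second,
independently parameterized copy of the encoder. The discriminator shares
the encoder topology up to a feature block, whose flattened activations
f(·) feed the adversarial feature-matching loss, followed by a single
convolution to a scalar real/fake logit.

Spatial trace with the default 15x15 patch: two 5x5 stride-2 pad-1
convolutions (15 → 7 → 3) then a 3x3 stride-1 pad-0 convolution to a
latent_dim x 1 x 1 bottleneck; the decoder mirrors it exactly with
transposed convolutions (1 → 3 → 7 → 15).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .nn import BatchNorm2d, Conv2d, ConvTranspose2d, LeakyReLU, Sequential

__all__ = [
    "ModelConfig",
    "GeneratorOutput",
    "DiscriminatorOutput",
    "Generator",
    "Discriminator",
    "build_generator",
    "build_discriminator",
    "SWEEP_LATENT_SIZES",
]

# latent sizes examined in the latent-size sweep
SWEEP_LATENT_SIZES = (50, 75, 100, 150, 200, 300, 400)


@dataclass
class ModelConfig:
    latent_dim: int = 100
    channel_widths: tuple[int, ...] = (32, 64)
    leaky_slope: float = 0.2
    input_channels: int = 2
    patch_size: int = 15

    def __post_init__(self) -> None:
        if self.latent_dim < 1:
            raise ValueError("latent_dim must be positive")
        if self.leaky_slope <= 0:
            raise ValueError("leaky_slope must be positive")
        if not self.channel_widths:
            raise ValueError("need at least one channel width")

    def encoder_trace(self) -> list[int]:
        """Spatial sizes after each encoder convolution, input first.

        Raises if any strided convolution is not exactly invertible by its
        transposed counterpart (the decoder could not mirror it).
        """
        trace = [self.patch_size]
        h = self.patch_size
        for _ in self.channel_widths:
            h2 = (h + 2 * 1 - 5) // 2 + 1
            if h2 < 1 or (h2 - 1) * 2 - 2 * 1 + 5 != h:
                raise ValueError(
                    f"patch size {self.patch_size} incompatible with 5x5/s2/p1 "
                    f"encoder blocks (stuck at spatial size {h})"
                )
            trace.append(h2)
            h = h2
        hf = h - 3 + 1
        if hf < 1 or (hf - 1) + 3 != h:
            raise ValueError(f"3x3 latent convolution does not fit spatial size {h}")
        trace.append(hf)
        return trace

    def to_json(self) -> str:
        return json.dumps(
            {
                "latent_dim": self.latent_dim,
                "channel_widths": list(self.channel_widths),
                "leaky_slope": self.leaky_slope,
                "input_channels": self.input_channels,
                "patch_size": self.patch_size,
            }
        )

    @classmethod
    def from_json(cls, s: str) -> "ModelConfig":
        d = json.loads(s)
        d["channel_widths"] = tuple(d["channel_widths"])
        return cls(**d)


@dataclass
class GeneratorOutput:
    reconstruction: np.ndarray  # (n, channels, patch, patch)
    z: np.ndarray  # (n, latent_dim)
    z_hat: np.ndarray  # (n, latent_dim)


@dataclass
class DiscriminatorOutput:
    features: np.ndarray  # (n, feature_len)
    probability: np.ndarray  # (n,)
    logit: np.ndarray = field(default=None)


def _encoder_stack(cfg: ModelConfig, rng: np.random.Generator, tag: str) -> Sequential:
    layers = []
    c_in = cfg.input_channels
    for i, w in enumerate(cfg.channel_widths):
        layers += [
            Conv2d(c_in, w, 5, 2, 1, rng=rng, name=f"{tag}.conv{i}"),
            BatchNorm2d(w, rng=rng, name=f"{tag}.bn{i}"),
            LeakyReLU(cfg.leaky_slope),
        ]
        c_in = w
    # latent-producing convolution: linear, no batch norm
    layers.append(Conv2d(c_in, cfg.latent_dim, 3, 1, 0, rng=rng, name=f"{tag}.convz"))
    return Sequential(*layers)


def _decoder_stack(cfg: ModelConfig, rng: np.random.Generator, tag: str) -> Sequential:
    widths = list(cfg.channel_widths)
    layers = [
        ConvTranspose2d(cfg.latent_dim, widths[-1], 3, 1, 0, rng=rng, name=f"{tag}.tconvz"),
        BatchNorm2d(widths[-1], rng=rng, name=f"{tag}.bnz"),
        LeakyReLU(cfg.leaky_slope),
    ]
    for i in range(len(widths) - 1, 0, -1):
        layers += [
            ConvTranspose2d(widths[i], widths[i - 1], 5, 2, 1, rng=rng, name=f"{tag}.tconv{i}"),
            BatchNorm2d(widths[i - 1], rng=rng, name=f"{tag}.bn{i}"),
            LeakyReLU(cfg.leaky_slope),
        ]
    # linear output layer: no batch norm, no squashing (intensities are unclipped)
    layers.append(ConvTranspose2d(widths[0], cfg.input_channels, 5, 2, 1, rng=rng, name=f"{tag}.tconv0"))
    return Sequential(*layers)


class Generator:
    """G_E → G_D → G_E2; the second encoder never shares weights with the first."""

    def __init__(self, config: ModelConfig, rng: np.random.Generator) -> None:
        config.encoder_trace()  # validates the spatial arithmetic
        self.config = config
        self.encoder = _encoder_stack(config, rng, "enc")
        self.decoder = _decoder_stack(config, rng, "dec")
        self.encoder2 = _encoder_stack(config, rng, "enc2")

    # -- forward ---------------------------------------------------------
    def encode(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        z = self.encoder.forward(x, train=train)
        return z.reshape(z.shape[0], -1)

    def forward(self, x: np.ndarray, train: bool = True) -> GeneratorOutput:
        x = np.asarray(x)
        if not np.issubdtype(x.dtype, np.floating):
            x = x.astype(np.float32)
        if x.ndim == 3:
            x = x[None]
        if not np.all(np.isfinite(x)):
            raise ValueError("non-finite generator input")
        z4 = self.encoder.forward(x, train=train)
        xhat = self.decoder.forward(z4, train=train)
        zhat4 = self.encoder2.forward(xhat, train=train)
        n = x.shape[0]
        return GeneratorOutput(
            reconstruction=xhat, z=z4.reshape(n, -1), z_hat=zhat4.reshape(n, -1)
        )

    # -- backward --------------------------------------------------------
    def backward(
        self, d_xhat: np.ndarray, d_z: np.ndarray, d_zhat: np.ndarray
    ) -> None:
        """Accumulate parameter gradients from loss gradients at the outputs.

        ``d_xhat`` is the *direct* gradient at the reconstruction (from the
        reconstruction and adversarial terms); the path through the second
        encoder is added here.
        """
        n = d_z.shape[0]
        dz4 = d_z.reshape(n, self.config.latent_dim, 1, 1)
        dzhat4 = d_zhat.reshape(n, self.config.latent_dim, 1, 1)
        d_xhat_total = d_xhat + self.encoder2.backward(dzhat4)
        dz_total = dz4 + self.decoder.backward(d_xhat_total)
        self.encoder.backward(dz_total)

    def parameters(self):
        return (
            self.encoder.parameters()
            + self.decoder.parameters()
            + self.encoder2.parameters()
        )

    def state_arrays(self) -> dict[str, np.ndarray]:
        out = {}
        for tag, net in (("E", self.encoder), ("D", self.decoder), ("E2", self.encoder2)):
            for k, v in net.state_arrays().items():
                out[f"{tag}.{k}"] = v
        return out

    def load_state_arrays(self, state: dict[str, np.ndarray]) -> None:
        for tag, net in (("E", self.encoder), ("D", self.decoder), ("E2", self.encoder2)):
            net.load_state_arrays(
                {k[len(tag) + 1 :]: v for k, v in state.items() if k.startswith(f"{tag}.")}
            )


class Discriminator:
    """Encoder-topology feature extractor + 3x3 convolution to one logit."""

    def __init__(self, config: ModelConfig, rng: np.random.Generator) -> None:
        config.encoder_trace()
        self.config = config
        layers = []
        c_in = config.input_channels
        for i, w in enumerate(config.channel_widths):
            layers += [
                Conv2d(c_in, w, 5, 2, 1, rng=rng, name=f"disc.conv{i}"),
                BatchNorm2d(w, rng=rng, name=f"disc.bn{i}"),
                LeakyReLU(config.leaky_slope),
            ]
            c_in = w
        self.features_net = Sequential(*layers)
        self.classifier = Conv2d(c_in, 1, 3, 1, 0, rng=rng, name="disc.clf")
        feat_spatial = config.encoder_trace()[-2]
        self.feature_len = c_in * feat_spatial * feat_spatial

    def forward(self, x: np.ndarray, train: bool = True) -> DiscriminatorOutput:
        x = np.asarray(x)
        if not np.issubdtype(x.dtype, np.floating):
            x = x.astype(np.float32)
        if x.ndim == 3:
            x = x[None]
        feat = self.features_net.forward(x, train=train)
        logit = self.classifier.forward(feat, train=train).reshape(x.shape[0])
        prob = 1.0 / (1.0 + np.exp(-logit))
        return DiscriminatorOutput(
            features=feat.reshape(x.shape[0], -1), probability=prob, logit=logit
        )

    def backward_from_logit(self, d_logit: np.ndarray) -> np.ndarray:
        d4 = d_logit.reshape(-1, 1, 1, 1).astype(np.float32)
        dfeat = self.classifier.backward(d4)
        return self.features_net.backward(dfeat)

    def backward_from_features(self, d_feat: np.ndarray) -> np.ndarray:
        n = d_feat.shape[0]
        spatial = self.config.encoder_trace()[-2]
        d4 = d_feat.reshape(n, -1, spatial, spatial).astype(np.float32)
        return self.features_net.backward(d4)

    def parameters(self):
        return self.features_net.parameters() + self.classifier.parameters()

    def state_arrays(self) -> dict[str, np.ndarray]:
        out = {f"F.{k}": v for k, v in self.features_net.state_arrays().items()}
        out.update({f"C.{k}": v for k, v in self.classifier.state_arrays().items()})
        return out

    def load_state_arrays(self, state: dict[str, np.ndarray]) -> None:
        self.features_net.load_state_arrays(
            {k[2:]: v for k, v in state.items() if k.startswith("F.")}
        )
        self.classifier.load_state_arrays(
            {k[2:]: v for k, v in state.items() if k.startswith("C.")}
        )


def build_generator(config: ModelConfig, rng_seed: int | None = None) -> Generator:
    return Generator(config, np.random.default_rng(rng_seed))


def build_discriminator(config: ModelConfig, rng_seed: int | None = None) -> Discriminator:
    return Discriminator(config, np.random.default_rng(rng_seed))
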