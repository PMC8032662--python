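"""Minimal NumPy neural-network layers with explicit backpropagation.

Only what the two-channel 15x15-patch generator/discriminator pair needs:
strided 2D convolution, transposed convolution, batch normalization,
leaky rectified-linear activation, and a container. Layers cache their
forward inputs and expose ``backward(dy)`` returning the input gradient
while accumulating parameter gradients. All arithmetic is float64-safe
but runs in float32 by default for speed.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Parameter",
    "Layer",
    "Conv2d",
    "ConvTranspose2d",
    "BatchNorm2d",
    "LeakyReLU",
    "Sequential",
]


class Parameter:
    """A trainable array with its accumulated gradient."""

    __slots__ = ("value", "grad", "name")

    def __init__(self, value: np.ndarray, name: str = "") -> None:
        self.value = np.ascontiguousarray(value)
        self.grad = np.zeros_like(self.value)
        self.name = name

    def zero_grad(self) -> None:
        self.grad[...] = 0.0


class Layer:
    """Base layer: ``forward`` caches, ``backward`` consumes the cache."""

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def parameters(self) -> list[Parameter]:
        return []

    def state_arrays(self) -> dict[str, np.ndarray]:
        """Trainable and persistent arrays, for checkpointing."""
        return {p.name or f"p{i}": p.value for i, p in enumerate(self.parameters())}

    def load_state_arrays(self, state: dict[str, np.ndarray]) -> None:
        for i, p in enumerate(self.parameters()):
            key = p.name or f"p{i}"
            p.value[...] = state[key]


def _pad2d(x: np.ndarray, p: int) -> np.ndarray:
    if p == 0:
        return x
    return np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))


def _im2col(xp: np.ndarray, k: int, s: int) -> np.ndarray:
    """View of a padded (N,C,H,W) array as (N, Ho, Wo, C, k, k) windows."""
    n, c, h, w = xp.shape
    ho = (h - k) // s + 1
    wo = (w - k) // s + 1
    sn, sc, sh, sw = xp.strides
    return np.lib.stride_tricks.as_strided(
        xp, (n, ho, wo, c, k, k), (sn, sh * s, sw * s, sc, sh, sw)
    )


def _col2im(dcols: np.ndarray, xp_shape: tuple, k: int, s: int) -> np.ndarray:
    """Scatter-add (N, Ho, Wo, C, k, k) window gradients back to (N,C,H,W)."""
    dxp = np.zeros(xp_shape, dtype=dcols.dtype)
    ho, wo = dcols.shape[1], dcols.shape[2]
    t = np.ascontiguousarray(dcols.transpose(4, 5, 0, 3, 1, 2))
    for u in range(k):
        for v in range(k):
            dxp[:, :, u : u + ho * s : s, v : v + wo * s : s] += t[u, v]
    return dxp


class Conv2d(Layer):
    """2D cross-correlation, weight shape (out_ch, in_ch, k, k)."""

    def __init__(
        self,
        in_ch: int,
        out_ch: int,
        kernel: int,
        stride: int = 1,
        padding: int = 0,
        rng: np.random.Generator | None = None,
        init_std: float = 0.02,
        name: str = "conv",
    ) -> None:
        rng = rng if rng is not None else np.random.default_rng()
        self.in_ch, self.out_ch = in_ch, out_ch
        self.k, self.s, self.p = kernel, stride, padding
        w = rng.normal(0.0, init_std, (out_ch, in_ch, kernel, kernel))
        self.weight = Parameter(w.astype(np.float32), f"{name}.weight")
        self.bias = Parameter(np.zeros(out_ch, dtype=np.float32), f"{name}.bias")
        self._cache = None

    def out_size(self, h: int) -> int:
        return (h + 2 * self.p - self.k) // self.s + 1

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        n, c, h, w = x.shape
        ho, wo = self.out_size(h), self.out_size(w)
        if ho < 1 or wo < 1:
            raise ValueError(
                f"conv kernel {self.k} stride {self.s} pad {self.p} does not fit "
                f"input of spatial size {h}x{w}"
            )
        xp = _pad2d(x, self.p)
        cols = np.ascontiguousarray(_im2col(xp, self.k, self.s)).reshape(
            n * ho * wo, c * self.k * self.k
        )
        wmat = self.weight.value.reshape(self.out_ch, -1)
        y = cols @ wmat.T + self.bias.value
        self._cache = (cols, xp.shape, (n, ho, wo))
        return y.reshape(n, ho, wo, self.out_ch).transpose(0, 3, 1, 2)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        cols, xp_shape, (n, ho, wo) = self._cache
        dym = dy.transpose(0, 2, 3, 1).reshape(n * ho * wo, self.out_ch)
        self.weight.grad += (dym.T @ cols).reshape(self.weight.value.shape)
        self.bias.grad += dym.sum(axis=0)
        wmat = self.weight.value.reshape(self.out_ch, -1)
        dcols = (dym @ wmat).reshape(n, ho, wo, self.in_ch, self.k, self.k)
        dxp = _col2im(dcols, xp_shape, self.k, self.s)
        if self.p:
            return dxp[:, :, self.p : -self.p, self.p : -self.p]
        return dxp

    def parameters(self) -> list[Parameter]:
        return [self.weight, self.bias]


class ConvTranspose2d(Layer):
    """Transposed 2D convolution, weight shape (in_ch, out_ch, k, k).

    Output spatial size is ``(h - 1) * stride - 2 * padding + kernel``,
    the adjoint of :class:`Conv2d` with the same hyperparameters.
    """

    def __init__(
        self,
        in_ch: int,
        out_ch: int,
        kernel: int,
        stride: int = 1,
        padding: int = 0,
        rng: np.random.Generator | None = None,
        init_std: float = 0.02,
        name: str = "tconv",
    ) -> None:
        rng = rng if rng is not None else np.random.default_rng()
        self.in_ch, self.out_ch = in_ch, out_ch
        self.k, self.s, self.p = kernel, stride, padding
        w = rng.normal(0.0, init_std, (in_ch, out_ch, kernel, kernel))
        self.weight = Parameter(w.astype(np.float32), f"{name}.weight")
        self.bias = Parameter(np.zeros(out_ch, dtype=np.float32), f"{name}.bias")
        self._cache = None

    def out_size(self, h: int) -> int:
        return (h - 1) * self.s - 2 * self.p + self.k

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        n, c, h, w = x.shape
        ho, wo = self.out_size(h), self.out_size(w)
        if ho < 1 or wo < 1:
            raise ValueError("transposed conv output collapsed to zero size")
        xf = x.transpose(0, 2, 3, 1).reshape(n * h * w, c)
        t = (xf @ self.weight.value.reshape(c, -1)).reshape(
            n, h, w, self.out_ch, self.k, self.k
        )
        yp_shape = (n, self.out_ch, ho + 2 * self.p, wo + 2 * self.p)
        yp = _col2im(t, yp_shape, self.k, self.s)
        y = yp[:, :, self.p : yp_shape[2] - self.p, self.p : yp_shape[3] - self.p]
        y = y + self.bias.value[None, :, None, None]
        self._cache = (x, (n, h, w))
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        x, (n, h, w) = self._cache
        dyp = _pad2d(dy, self.p)
        cols = np.ascontiguousarray(_im2col(dyp, self.k, self.s)).reshape(
            n * h * w, self.out_ch * self.k * self.k
        )
        xf = x.transpose(0, 2, 3, 1).reshape(n * h * w, self.in_ch)
        self.weight.grad += (xf.T @ cols).reshape(self.weight.value.shape)
        self.bias.grad += dy.sum(axis=(0, 2, 3))
        wmat = self.weight.value.reshape(self.in_ch, -1)
        dx = (cols @ wmat.T).reshape(n, h, w, self.in_ch).transpose(0, 3, 1, 2)
        return dx

    def parameters(self) -> list[Parameter]:
        return [self.weight, self.bias]


class BatchNorm2d(Layer):
    """Per-channel batch normalization with running statistics."""

    def __init__(
        self,
        ch: int,
        eps: float = 1e-5,
        momentum: float = 0.1,
        rng: np.random.Generator | None = None,
        name: str = "bn",
    ) -> None:
        rng = rng if rng is not None else np.random.default_rng()
        self.eps = eps
        self.momentum = momentum
        gamma = rng.normal(1.0, 0.02, ch).astype(np.float32)
        self.gamma = Parameter(gamma, f"{name}.gamma")
        self.beta = Parameter(np.zeros(ch, dtype=np.float32), f"{name}.beta")
        self.running_mean = np.zeros(ch, dtype=np.float32)
        self.running_var = np.ones(ch, dtype=np.float32)
        self._name = name
        self._cache = None

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        if train:
            mu = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean += self.momentum * (mu - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
        else:
            mu, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu[None, :, None, None]) * inv[None, :, None, None]
        self._cache = (xhat, inv, train, x.shape)
        return self.gamma.value[None, :, None, None] * xhat + self.beta.value[
            None, :, None, None
        ]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xhat, inv, train, shape = self._cache
        dgamma = (dy * xhat).sum(axis=(0, 2, 3))
        dbeta = dy.sum(axis=(0, 2, 3))
        self.gamma.grad += dgamma
        self.beta.grad += dbeta
        g_inv = (self.gamma.value * inv)[None, :, None, None]
        if not train:
            return dy * g_inv
        m = shape[0] * shape[2] * shape[3]
        return g_inv * (
            dy
            - dbeta[None, :, None, None] / m
            - xhat * dgamma[None, :, None, None] / m
        )

    def parameters(self) -> list[Parameter]:
        return [self.gamma, self.beta]

    def state_arrays(self) -> dict[str, np.ndarray]:
        d = super().state_arrays()
        d[f"{self._name}.running_mean"] = self.running_mean
        d[f"{self._name}.running_var"] = self.running_var
        return d

    def load_state_arrays(self, state: dict[str, np.ndarray]) -> None:
        super().load_state_arrays(state)
        self.running_mean[...] = state[f"{self._name}.running_mean"]
        self.running_var[...] = state[f"{self._name}.running_var"]


class LeakyReLU(Layer):
    def __init__(self, slope: float = 0.2) -> None:
        if slope <= 0:
            raise ValueError("leaky slope must be positive")
        self.slope = slope
        self._mask = None

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        self._mask = x >= 0
        return np.where(self._mask, x, self.slope * x)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return np.where(self._mask, dy, self.slope * dy)


class Sequential(Layer):
    def __init__(self, *layers: Layer) -> None:
        self.layers = list(layers)

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def backward(self, dy: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy

    def parameters(self) -> list[Parameter]:
        out: list[Parameter] = []
        for layer in self.layers:
            out.extend(layer.parameters())
        return out

    def state_arrays(self) -> dict[str, np.ndarray]:
        out: dict[str, np.ndarray] = {}
        for i, layer in enumerate(self.layers):
            for k, v in layer.state_arrays().items():
                out[f"{i}.{k}"] = v
        return out

    def load_state_arrays(self, state: dict[str, np.ndarray]) -> None:
        for i, layer in enumerate(self.layers):
            sub = {
                k.split(".", 1)[1]: v
                for k, v in state.items()
                if k.startswith(f"{i}.")
            }
            layer.load_state_arrays(sub)
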