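"""Minimal 3D convolutional neural-network stack in numpy.

Layers follow the explicit forward/backward-cache pattern: each module
implements ``forward(x, train)`` and ``backward(dy)``, accumulating
parameter gradients in place.  Volumes are channels-last ``(N, D, H, W, C)``
float32 throughout, which lets every convolution reduce to batched matrix
products over the channel axis.

Only what the perfusion-deficit model needs is implemented: 3x3x3 stride-1
convolution, 2x2x2 stride-2 down- and up-sampling convolutions, batch
normalisation, GELU, and fully connected layers, plus Adam with L2 weight
decay.
"""

from __future__ import annotations

import numpy as np
from scipy.special import erf

from . import _kernels as _k

__all__ = [
    "Param",
    "Conv3x3",
    "ConvDown2",
    "ConvUp2",
    "BatchNorm",
    "GELU",
    "Linear",
    "Sequential",
    "Adam",
]

_DTYPE = np.float32


class Param:
    """A learnable tensor with its accumulated gradient."""

    __slots__ = ("value", "grad", "name")

    def __init__(self, value: np.ndarray, name: str = "") -> None:
        self.value = np.ascontiguousarray(value, dtype=_DTYPE)
        self.grad = np.zeros_like(self.value)
        self.name = name

    def zero_grad(self) -> None:
        self.grad[...] = 0.0


class Module:
    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


_OFFSETS3 = [(i, j, k) for i in range(3) for j in range(3) for k in range(3)]


class Conv3x3(Module):
    """3x3x3 convolution, stride 1, zero padding 1 (shape preserving).

    im2col formulation: the 27 shifted neighbourhoods are gathered into one
    contiguous (voxels, 27*cin) matrix so the whole convolution is a single
    BLAS matmul; the input gradient scatters back with 27 slice-adds.
    """

    def __init__(self, cin: int, cout: int, rng: np.random.Generator) -> None:
        scale = np.sqrt(2.0 / (cin * 27))
        self.weight = Param(rng.normal(0.0, scale, (27 * cin, cout)), "conv3.w")
        self.bias = Param(np.zeros(cout), "conv3.b")
        self.cin = cin
        self._cols: np.ndarray | None = None
        self._ws: dict = {}

    def params(self) -> list[Param]:
        return [self.weight, self.bias]

    def _im2col(self, x: np.ndarray) -> np.ndarray:
        n, d, h, w, c = x.shape
        xp = np.pad(x, ((0, 0), (1, 1), (1, 1), (1, 1), (0, 0)))
        return _k.im2col3(np.ascontiguousarray(xp), d, h, w, store=self._ws)

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        n, d, h, w, c = x.shape
        cols = self._im2col(x)
        y = cols @ self.weight.value + self.bias.value
        self._cols = cols if train else None
        self._shape = (n, d, h, w, c)
        return y.reshape(n, d, h, w, -1)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, d, h, w, c = self._shape
        dy2 = dy.reshape(-1, dy.shape[-1])
        self.bias.grad += dy2.sum(axis=0)
        self.weight.grad += self._cols.T @ dy2
        self._cols = None
        dcols = _k._buffer(self._ws, "dcols", (dy2.shape[0], 27 * c), _DTYPE)
        np.matmul(dy2, self.weight.value.T, out=dcols)
        dxp = _k.col2im3(dcols, n, d, h, w, c, store=self._ws)
        return dxp[:, 1:-1, 1:-1, 1:-1, :]


_to_blocks = _k.to_blocks
_from_blocks = _k.from_blocks


class ConvDown2(Module):
    """2x2x2 convolution with stride 2: halves every spatial dimension."""

    def __init__(self, cin: int, cout: int, rng: np.random.Generator) -> None:
        scale = np.sqrt(2.0 / (cin * 8))
        self.weight = Param(rng.normal(0.0, scale, (8 * cin, cout)), "down2.w")
        self.bias = Param(np.zeros(cout), "down2.b")
        self._blocks: np.ndarray | None = None
        self._ws: dict = {}

    def params(self) -> list[Param]:
        return [self.weight, self.bias]

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        if any(s % 2 for s in x.shape[1:4]):
            raise ValueError(f"spatial shape {x.shape[1:4]} not divisible by 2")
        blocks = _to_blocks(x, store=self._ws)
        self._blocks = blocks if train else None
        shape = blocks.shape[:4]
        y = blocks.reshape(-1, blocks.shape[-1]) @ self.weight.value + self.bias.value
        return y.reshape(shape + (-1,))

    def backward(self, dy: np.ndarray) -> np.ndarray:
        blocks = self._blocks
        dy2 = dy.reshape(-1, dy.shape[-1])
        self.bias.grad += dy2.sum(axis=0)
        self.weight.grad += blocks.reshape(-1, blocks.shape[-1]).T @ dy2
        dblocks = (dy2 @ self.weight.value.T).reshape(
            dy.shape[:4] + (self.weight.value.shape[0],)
        )
        self._blocks = None
        cin = self.weight.value.shape[0] // 8
        return _from_blocks(dblocks, cin, store=self._ws)


class ConvUp2(Module):
    """Transposed 2x2x2 stride-2 convolution: doubles every spatial dimension."""

    def __init__(self, cin: int, cout: int, rng: np.random.Generator) -> None:
        scale = np.sqrt(2.0 / cin)
        self.weight = Param(rng.normal(0.0, scale, (cin, 8 * cout)), "up2.w")
        self.bias = Param(np.zeros(8 * cout), "up2.b")
        self._x: np.ndarray | None = None
        self._cout = cout
        self._ws: dict = {}

    def params(self) -> list[Param]:
        return [self.weight, self.bias]

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        self._x = x if train else None
        y = x.reshape(-1, x.shape[-1]) @ self.weight.value + self.bias.value
        return _from_blocks(y.reshape(x.shape[:4] + (-1,)), self._cout, store=self._ws)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dyb = _to_blocks(dy, store=self._ws)
        dyb2 = dyb.reshape(-1, dyb.shape[-1])
        self.bias.grad += dyb2.sum(axis=0)
        x = self._x
        self.weight.grad += x.reshape(-1, x.shape[-1]).T @ dyb2
        self._x = None
        dx = dyb2 @ self.weight.value.T
        return dx.reshape(dyb.shape[:4] + (-1,))


class BatchNorm(Module):
    """Batch normalisation over batch + spatial axes, per channel."""

    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5) -> None:
        self.gamma = Param(np.ones(channels), "bn.gamma")
        self.beta = Param(np.zeros(channels), "bn.beta")
        self.running_mean = np.zeros(channels, dtype=_DTYPE)
        self.running_var = np.ones(channels, dtype=_DTYPE)
        self.momentum = momentum
        self.eps = eps
        self._cache = None

    def params(self) -> list[Param]:
        return [self.gamma, self.beta]

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        axes = tuple(range(x.ndim - 1))
        if train:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean += self.momentum * (mean - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
        else:
            mean, var = self.running_mean, self.running_var
        inv_sd = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean) * inv_sd
        if train:
            self._cache = (xhat, inv_sd.astype(_DTYPE), axes)
        return (self.gamma.value * xhat + self.beta.value).astype(_DTYPE)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xhat, inv_sd, axes = self._cache
        m = np.prod([dy.shape[a] for a in axes])
        self.beta.grad += dy.sum(axis=axes)
        self.gamma.grad += (dy * xhat).sum(axis=axes)
        dxhat = dy * self.gamma.value
        dx = (
            dxhat
            - dxhat.mean(axis=axes)
            - xhat * (dxhat * xhat).sum(axis=axes) / m
        ) * inv_sd
        self._cache = None
        return dx.astype(_DTYPE)


class GELU(Module):
    """Exact Gaussian error linear unit: x * Phi(x)."""

    def __init__(self) -> None:
        self._x: np.ndarray | None = None

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        self._x = x if train else None
        return (x * 0.5 * (1.0 + erf(x / np.sqrt(2.0)))).astype(_DTYPE)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        x = self._x
        phi = np.exp(-0.5 * x * x) / np.sqrt(2.0 * np.pi)
        cdf = 0.5 * (1.0 + erf(x / np.sqrt(2.0)))
        self._x = None
        return (dy * (cdf + x * phi)).astype(_DTYPE)


class Linear(Module):
    def __init__(self, nin: int, nout: int, rng: np.random.Generator) -> None:
        scale = np.sqrt(2.0 / nin)
        self.weight = Param(rng.normal(0.0, scale, (nin, nout)), "fc.w")
        self.bias = Param(np.zeros(nout), "fc.b")
        self._x: np.ndarray | None = None

    def params(self) -> list[Param]:
        return [self.weight, self.bias]

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        self._x = x if train else None
        return x @ self.weight.value + self.bias.value

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.weight.grad += self._x.T @ dy
        self.bias.grad += dy.sum(axis=0)
        x = self._x
        self._x = None
        return dy @ self.weight.value.T


class Sequential(Module):
    def __init__(self, *layers: Module) -> None:
        self.layers = list(layers)

    def params(self) -> list[Param]:
        return [p for layer in self.layers for p in layer.params()]

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def backward(self, dy: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy


class Adam:
    """Adam with L2 weight decay added to the gradient."""

    def __init__(
        self,
        params: list[Param],
        lr: float = 1e-4,
        weight_decay: float = 1e-5,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
    ) -> None:
        self.params = params
        self.lr = lr
        self.wd = weight_decay
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            g = p.grad + self.wd * p.value
            m += (1.0 - self.b1) * (g - m)
            v += (1.0 - self.b2) * (g * g - v)
            p.value -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()
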