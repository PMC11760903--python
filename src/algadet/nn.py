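"""Small learnable-layer toolkit built on :mod:`algadet.autodiff`.

Layers operate on channel-major maps ``[C, L]`` (a feature map with its
spatial axes flattened, or the merged pooled axis used by coordinate
attention).  Parameters are seeded at construction, so two modules built
with the same seed are bit-identical.
"""

from __future__ import annotations

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor

__all__ = ["Module", "PointwiseConv", "DepthwiseConv1d", "ChannelNorm", "SGD", "Adam", "ACTIVATIONS"]

ACTIVATIONS = {
    "silu": ad.silu,
    "sigmoid": ad.sigmoid,
    "relu": lambda x: ad.maximum(x, 0.0),
    "identity": lambda x: x,
}


class Module:
    """Base class: recursive parameter collection and gradient reset."""

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        for v in vars(self).values():
            if isinstance(v, Tensor) and v.requires_grad:
                params.append(v)
            elif isinstance(v, Module):
                params.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
        return params

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def n_parameters(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))

    def state_arrays(self) -> list[np.ndarray]:
        return [p.data for p in self.parameters()]

    def load_state_arrays(self, arrays) -> None:
        own = self.parameters()
        if len(arrays) != len(own):
            raise ValueError("state array count mismatch")
        for p, a in zip(own, arrays):
            if p.data.shape != a.shape:
                raise ValueError("state array shape mismatch")
            p.data = np.asarray(a, dtype=np.float64).copy()

    def __call__(self, x):
        return self.forward(x)


def _init(rng: np.random.Generator, shape, fan_in: int) -> Tensor:
    scale = np.sqrt(2.0 / max(fan_in, 1))
    return Tensor(rng.normal(0.0, scale, size=shape), requires_grad=True)


class PointwiseConv(Module):
    """1x1 convolution over the channel axis: ``y = W x + b`` on [C, L] maps."""

    def __init__(self, in_channels: int, out_channels: int, rng: np.random.Generator):
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.weight = _init(rng, (out_channels, in_channels), in_channels)
        self.bias = Tensor(np.zeros((out_channels, 1)), requires_grad=True)

    def forward(self, x):
        return ad.matmul(self.weight, x) + self.bias


class DepthwiseConv1d(Module):
    """Per-channel k-tap convolution along the spatial axis, same padding.

    Each channel is filtered independently with its own kernel, the
    depth-wise layout that keeps the parameter count at ``C * k`` instead
    of a dense layer's ``C^2 * k``.
    """

    def __init__(self, channels: int, kernel_size: int, rng: np.random.Generator):
        if kernel_size < 1 or kernel_size % 2 == 0:
            raise ValueError("kernel_size must be odd and positive")
        self.channels = channels
        self.kernel_size = kernel_size
        self.weight = _init(rng, (channels, kernel_size), kernel_size)
        self.bias = Tensor(np.zeros((channels, 1)), requires_grad=True)

    def forward(self, x):
        c, length = ad.asdata(x).shape
        if c != self.channels:
            raise ValueError(f"expected {self.channels} channels, got {c}")
        pad = self.kernel_size // 2
        zeros = np.zeros((c, pad))
        xp = ad.concatenate([zeros, x, zeros], axis=1)
        out = None
        for t in range(self.kernel_size):
            term = self.weight[:, t : t + 1] * xp[:, t : t + length]
            out = term if out is None else out + term
        return out + self.bias


class ChannelNorm(Module):
    """Per-channel standardization over the spatial axis with learnable affine."""

    def __init__(self, channels: int, eps: float = 1e-5):
        self.channels = channels
        self.eps = eps
        self.gamma = Tensor(np.ones((channels, 1)), requires_grad=True)
        self.beta = Tensor(np.zeros((channels, 1)), requires_grad=True)

    def forward(self, x):
        mu = ad.tmean(x, axis=1, keepdims=True)
        centered = x - mu
        var = ad.tmean(centered * centered, axis=1, keepdims=True)
        return centered / ad.sqrt(var + self.eps) * self.gamma + self.beta


class SGD:
    """Stochastic gradient descent with momentum and decoupled weight decay."""

    def __init__(self, params, lr: float, momentum: float = 0.0, weight_decay: float = 0.0):
        self.params = list(params)
        self.lr = lr
        self.momentum = momentum
        self.weight_decay = weight_decay
        self._velocity = [np.zeros_like(p.data) for p in self.params]

    def step(self) -> None:
        for p, v in zip(self.params, self._velocity):
            if p.grad is None:
                continue
            g = p.grad + self.weight_decay * p.data
            v *= self.momentum
            v += g
            p.data -= self.lr * v

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None


class Adam:
    """Adam optimizer with decoupled weight decay.

    Converges in far fewer steps than SGD on the small, badly-scaled
    problems of desk-scale training; the default betas are the standard
    (0.9, 0.999).
    """

    def __init__(self, params, lr: float, betas: tuple[float, float] = (0.9, 0.999),
                 eps: float = 1e-8, weight_decay: float = 0.0):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self._m = [np.zeros_like(p.data) for p in self.params]
        self._v = [np.zeros_like(p.data) for p in self.params]
        self._t = 0

    def step(self) -> None:
        self._t += 1
        for p, m, v in zip(self.params, self._m, self._v):
            if p.grad is None:
                continue
            g = p.grad
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            mhat = m / (1 - self.b1**self._t)
            vhat = v / (1 - self.b2**self._t)
            p.data -= self.lr * (mhat / (np.sqrt(vhat) + self.eps) + self.weight_decay * p.data)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None
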