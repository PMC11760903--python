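"""CAGS: coordinate attention with a group-shuffle-convolution transform.

Coordinate attention pools a feature map ``[C, H, W]`` along each spatial
direction separately, producing a height descriptor ``[C, H, 1]`` and a
width descriptor ``[C, 1, W]``, merges them into ``[C, H+W, 1]``, and learns
per-direction attention weights from the merged descriptor.  CAGS replaces
the shared transform of plain coordinate attention with a GSConv: half the
intermediate channels come from a dense 1x1 convolution, the other half
from a depth-wise convolution stacked on top of it, followed by
concatenation and a channel shuffle that mixes the two branches.  The
descriptor is then normalized, passed through a nonlinearity, split back
into its height and width parts, projected to ``C`` channels per branch and
squashed with a sigmoid; the input map is gated multiplicatively by both
attention vectors.

The block preserves the input shape and, with sigmoid gates in (0, 1),
never amplifies a feature: ``|out| <= |in|`` element-wise (unless the
additive-residual variant is enabled).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import autodiff as ad
from .nn import ACTIVATIONS, ChannelNorm, DepthwiseConv1d, Module, PointwiseConv

__all__ = ["CagsConfig", "CAGS", "GSConv", "coordinate_pool", "channel_shuffle", "cags_forward", "gsconv"]


def _asmap(x):
    data = ad.asdata(x)
    if data.ndim != 3:
        raise ValueError(f"expected a [C, H, W] feature map, got shape {data.shape}")
    if not np.all(np.isfinite(data)):
        raise ValueError("feature map contains non-finite entries")
    return data.shape


def coordinate_pool(x):
    """Directional global average pooling, merged to shape [C, H+W, 1].

    The first H rows hold per-row means (pooled over width); the remaining
    W rows hold per-column means (pooled over height).
    """
    c, h, w = _asmap(x)
    h_branch = ad.tmean(x, axis=2)  # [C, H]
    w_branch = ad.tmean(x, axis=1)  # [C, W]
    merged = ad.concatenate([h_branch, w_branch], axis=1)
    if ad.is_tensor(merged):
        return merged.reshape(c, h + w, 1)
    return merged.reshape(c, h + w, 1)


def shuffle_permutation(channels: int, groups: int) -> np.ndarray:
    """Index permutation of the reshape-transpose channel shuffle.

    Channel ``g * (C/groups) + i`` moves to position ``i * groups + g``.
    """
    if channels % groups != 0:
        raise ValueError(f"groups ({groups}) must divide the channel count ({channels})")
    return np.arange(channels).reshape(groups, channels // groups).T.reshape(-1)


def channel_shuffle(x, groups: int):
    """Apply the reshape-transpose channel permutation along axis 0."""
    c = ad.asdata(x).shape[0]
    perm = shuffle_permutation(c, groups)
    return x[perm]


class GSConv(Module):
    """Group-shuffle convolution on [C, L] maps.

    Branch 1 is a dense 1x1 convolution to ``out_channels/2``; branch 2 is a
    depth-wise convolution applied to branch 1's output, contributing the
    other ``out_channels/2``.  The concatenated result is channel-shuffled
    so the two branches interleave.
    """

    def __init__(self, in_channels: int, out_channels: int, rng: np.random.Generator,
                 dw_kernel_size: int = 5, shuffle_groups: int = 2):
        if out_channels % 2 != 0:
            raise ValueError(f"out_channels must be even, got {out_channels}")
        half = out_channels // 2
        if out_channels % shuffle_groups != 0:
            raise ValueError("shuffle_groups must divide out_channels")
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.shuffle_groups = shuffle_groups
        self.dense = PointwiseConv(in_channels, half, rng)
        self.depthwise = DepthwiseConv1d(half, dw_kernel_size, rng)

    def forward(self, x):
        dense_half = self.dense(x)
        dw_half = self.depthwise(dense_half)
        both = ad.concatenate([dense_half, dw_half], axis=0)
        return channel_shuffle(both, self.shuffle_groups)


def gsconv(x, out_channels: int, seed: int = 0, dw_kernel_size: int = 5,
           shuffle_groups: int = 2):
    """One-shot GSConv on a [C, H, W] feature map with seeded parameters.

    Spatial dimensions are preserved (stride 1, same padding); the kernels
    act along the flattened spatial axis, the layout in which the block is
    used on the merged pooled descriptor.
    """
    c, h, w = _asmap(x)
    rng = np.random.default_rng(seed)
    layer = GSConv(c, out_channels, rng, dw_kernel_size=dw_kernel_size,
                   shuffle_groups=shuffle_groups)
    flat = x.reshape(c, h * w)
    out = layer(flat)
    return out.reshape(out_channels, h, w)


@dataclass
class CagsConfig:
    """Configuration of a CAGS block.

    ``mid_channels = max(min_mid_channels, channels // reduction)``, rounded
    up to an even number so GSConv can split it into two branches.
    """

    channels: int
    reduction: int = 32
    min_mid_channels: int = 8
    groups: int = 2
    dw_kernel_size: int = 5
    activation: str = "silu"
    residual: bool = False
    #: zero-init the gate projections so both attention gates start at the
    #: neutral value 0.5 everywhere (a position-independent scale that leaves
    #: the feature geometry untouched until the gates are learned)
    neutral_gate_init: bool = True

    def __post_init__(self):
        if self.channels < 1:
            raise ValueError("channels must be >= 1")
        if self.reduction < 1 or self.min_mid_channels < 1:
            raise ValueError("reduction and min_mid_channels must be >= 1")
        if self.activation not in ACTIVATIONS:
            raise ValueError(f"unknown activation {self.activation!r}")

    @property
    def mid_channels(self) -> int:
        mid = max(self.min_mid_channels, self.channels // self.reduction)
        return mid + (mid % 2)


class CAGS(Module):
    """Drop-in coordinate-attention block with a GSConv transform."""

    def __init__(self, config: CagsConfig, seed: int = 0):
        self.config = config
        rng = np.random.default_rng(seed)
        mid = config.mid_channels
        self.gs = GSConv(config.channels, mid, rng,
                         dw_kernel_size=config.dw_kernel_size,
                         shuffle_groups=config.groups)
        self.norm = ChannelNorm(mid)
        self.act = ACTIVATIONS[config.activation]
        self.height_proj = PointwiseConv(mid, config.channels, rng)
        self.width_proj = PointwiseConv(mid, config.channels, rng)
        if config.neutral_gate_init:
            for proj in (self.height_proj, self.width_proj):
                proj.weight.data[:] = 0.0
                proj.bias.data[:] = 0.0

    def attention_weights(self, x):
        """Height and width gates, shapes [C, H] and [C, W], each in (0, 1)."""
        c, h, w = _asmap(x)
        if c != self.config.channels:
            raise ValueError(f"configured for {self.config.channels} channels, got {c}")
        pooled = coordinate_pool(x).reshape(c, h + w)
        y = self.act(self.norm(self.gs(pooled)))
        gate_h = ad.sigmoid(self.height_proj(y[:, :h]))
        gate_w = ad.sigmoid(self.width_proj(y[:, h:]))
        return gate_h, gate_w

    def forward(self, x):
        """Gate `x` by its directional attention weights; shape preserved.

        Accepts [C, H, W] or a batched [N, C, H, W] (independent per-sample
        application with shared parameters).
        """
        if ad.asdata(x).ndim == 4:
            n = ad.asdata(x).shape[0]
            return ad.stack([self.forward(x[i]) for i in range(n)], axis=0)
        c, h, w = _asmap(x)
        gate_h, gate_w = self.attention_weights(x)
        out = x * gate_h.reshape(c, h, 1) * gate_w.reshape(c, 1, w)
        if self.config.residual:
            out = out + x
        return out


def cags_forward(x, config: CagsConfig | None = None, seed: int = 0, **kwargs):
    """Functional CAGS application with parameters drawn from `seed`.

    `config` defaults to ``CagsConfig(channels=C)`` with any overrides
    passed as keyword arguments.
    """
    shape = ad.asdata(x).shape
    c = shape[1] if len(shape) == 4 else shape[0]
    if config is None:
        config = CagsConfig(channels=c, **kwargs)
    block = CAGS(config, seed=seed)
    return block(x)
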