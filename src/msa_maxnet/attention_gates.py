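"""Channel/spatial attention gating: CBAM and its multi-scale variant MCBAM.

CBAM refines a feature map in two sequential steps. Channel attention
pools the map globally by both average and max, pushes the two
descriptors through one shared bottleneck MLP and sigmoids their sum into
a per-channel gate. Spatial attention then pools the channel axis by
average and max, concatenates the two maps and convolves them (7x7) into
a single-channel gate. Each gate multiplies the features it was computed
from.

MCBAM extends this to three encoder scales meeting at a skip connection:
the *channel* gate for the current stage's features F0 (C0 x H0 x W0) is
derived from the deeper stage's features F2 (2*C0 channels, half
resolution), whose richer semantics better rank channels; the *spatial*
gate is derived from the shallower stage's features F1 (double
resolution), which retain fine localization, via a stride-2 convolution
to a single channel at the current resolution:

    F0'' = Ms(F1) * (Mc(F2) * F0)

All feature maps are channels-last; gates broadcast over the axes they
do not index.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn import BatchNorm2d, Conv2d, Linear, Module, Tensor, concat

__all__ = [
    "CBAMConfig", "ChannelAttention", "SpatialAttention", "CBAM",
    "MCBAMChannelGate", "MCBAMSpatialGate", "MCBAM",
]


@dataclass(frozen=True)
class CBAMConfig:
    channels: int
    reduction: int = 16
    spatial_kernel: int = 7

    def __post_init__(self):
        if self.channels % self.reduction:
            raise ValueError("channels must divide by the MLP reduction")
        if self.spatial_kernel % 2 == 0:
            raise ValueError("spatial kernel must be odd")


class ChannelAttention(Module):
    """Per-channel sigmoid gate from shared-MLP(avg-pool) + shared-MLP(max-pool)."""

    def __init__(self, cfg: CBAMConfig, rng: np.random.Generator | None = None):
        super().__init__()
        hidden = cfg.channels // cfg.reduction
        self.fc1 = Linear(cfg.channels, hidden, bias=False, rng=rng)
        self.fc2 = Linear(hidden, cfg.channels, bias=False, rng=rng)

    def _mlp(self, d):
        return self.fc2(self.fc1(d).relu())

    def forward(self, f) -> Tensor:
        avg = f.mean(axis=(-3, -2), keepdims=True)
        mx = f.max(axis=(-3, -2), keepdims=True)
        return (self._mlp(avg) + self._mlp(mx)).sigmoid()  # (...,1,1,C)


class SpatialAttention(Module):
    """Single-channel sigmoid gate from a conv over [channel-avg; channel-max]."""

    def __init__(self, cfg: CBAMConfig, rng: np.random.Generator | None = None):
        super().__init__()
        k = cfg.spatial_kernel
        self.conv = Conv2d(2, 1, k, padding=k // 2, rng=rng)

    def forward(self, f) -> Tensor:
        if f.ndim == 3:
            f = f.reshape(1, *f.shape)
        avg = f.mean(axis=-1, keepdims=True)
        mx = f.max(axis=-1, keepdims=True)
        return self.conv(concat([avg, mx], axis=-1)).sigmoid()  # (N,H,W,1)


class CBAM(Module):
    """Sequential channel-then-spatial gating; shape preserving."""

    def __init__(self, cfg: CBAMConfig, rng: np.random.Generator | None = None):
        super().__init__()
        self.cfg = cfg
        self.channel = ChannelAttention(cfg, rng=rng)
        self.spatial = SpatialAttention(cfg, rng=rng)

    def forward(self, f):
        squeeze = f.ndim == 3
        if squeeze:
            f = f.reshape(1, *f.shape)
        f = f * self.channel(f)
        f = f * self.spatial(f)
        return f.reshape(*f.shape[1:]) if squeeze else f


class MCBAMChannelGate(Module):
    """Channel gate for C0 channels computed from the deeper features F2.

    Avg- and max-pooled C2-dim descriptors of F2 pass through a (shared by
    default) 1x1 convolution to C0 channels; their sum is sigmoided.
    Requires C2 == 2*C0, the relation between adjacent encoder stages.
    """

    def __init__(self, c0: int, shared: bool = True,
                 rng: np.random.Generator | None = None):
        super().__init__()
        self.c0, self.c2 = c0, 2 * c0
        self.conv_avg = Linear(self.c2, c0, rng=rng)
        self.conv_max = None if shared else Linear(self.c2, c0, rng=rng)

    def forward(self, f2) -> Tensor:
        if f2.shape[-1] != self.c2:
            raise ValueError(
                f"deep features must have {self.c2} (= 2*C0) channels, got {f2.shape[-1]}")
        conv_max = self.conv_avg if self.conv_max is None else self.conv_max
        avg = f2.mean(axis=(-3, -2), keepdims=True)
        mx = f2.max(axis=(-3, -2), keepdims=True)
        return (self.conv_avg(avg) + conv_max(mx)).sigmoid()  # (...,1,1,C0)


class MCBAMSpatialGate(Module):
    """Spatial gate at (H0, W0) re-extracted from the shallower features F1.

    A stride-2 convolution (kernel matching CBAM's spatial operator)
    collapses F1 (C1, 2H0, 2W0) to one channel at the current resolution,
    then BatchNorm and sigmoid.
    """

    def __init__(self, c1: int, kernel: int = 7,
                 rng: np.random.Generator | None = None):
        super().__init__()
        self.c1 = c1
        self.conv = Conv2d(c1, 1, kernel, stride=2, padding=kernel // 2, rng=rng)
        self.bn = BatchNorm2d(1)

    def forward(self, f1, h0: int, w0: int) -> Tensor:
        if f1.ndim == 3:
            f1 = f1.reshape(1, *f1.shape)
        n, h1, w1, c = f1.shape
        if c != self.c1:
            raise ValueError(f"shallow features must have {self.c1} channels, got {c}")
        if (h1, w1) != (2 * h0, 2 * w0):
            raise ValueError(
                f"shallow extent {(h1, w1)} must be twice the target {(h0, w0)}")
        return self.bn(self.conv(f1)).sigmoid()  # (N,H0,W0,1)


class MCBAM(Module):
    """Multi-scale gating of the current stage's features before skip fusion."""

    def __init__(self, c0: int, c1: int, kernel: int = 7, shared: bool = True,
                 rng: np.random.Generator | None = None):
        super().__init__()
        self.c0 = c0
        self.channel_gate = MCBAMChannelGate(c0, shared=shared, rng=rng)
        self.spatial_gate = MCBAMSpatialGate(c1, kernel=kernel, rng=rng)

    def forward(self, f0, f1, f2):
        squeeze = f0.ndim == 3
        if squeeze:
            f0 = f0.reshape(1, *f0.shape)
        n, h0, w0, c = f0.shape
        if c != self.c0:
            raise ValueError(f"current features must have {self.c0} channels, got {c}")
        if f2.shape[-3:-1] != (h0 // 2, w0 // 2):
            raise ValueError("deep features must be at half the current resolution")
        refined = f0 * self.channel_gate(f2)
        refined = refined * self.spatial_gate(f1, h0, w0)
        return refined.reshape(h0, w0, c) if squeeze else refined
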