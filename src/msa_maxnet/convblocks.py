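"""Inverted-bottleneck convolution blocks (MBConv) and the stem.

An MBConv block expands channels with a 1x1 convolution, mixes spatially
with a 3x3 depthwise convolution, recalibrates channels with a
squeeze-excitation gate and projects back down with a second 1x1
convolution, all behind a residual connection:

    x <- x + Proj(SE(DWConv(Conv(Norm(x)))))

The stride-2 variant used at stage boundaries downsamples in the
depthwise convolution and replaces the identity shortcut with average
pooling plus a channel projection:

    x <- Proj(Pool(x)) + Proj(SE(DWConv_s2(Conv(Norm(x)))))

The expansion width is ``expansion * out_dim`` and the SE bottleneck is
``se_ratio`` of the expanded width, following the MaxViT lineage of this
block. BatchNorm precedes the block and follows both the expansion and
depthwise convolutions (each with GELU); the final projection carries
neither norm nor activation. Pointwise (1x1) convolutions are realized
as per-pixel linear maps, which are the same operation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn import (
    BatchNorm2d, DepthwiseConv2d, Linear, Module, Tensor,
)
from .nn.functional import avg_pool2d

__all__ = ["MBConvConfig", "SqueezeExcite", "MBConv", "Stem"]


@dataclass(frozen=True)
class MBConvConfig:
    in_dim: int
    out_dim: int
    expansion: int = 4
    se_ratio: float = 0.25
    downsample: bool = False

    def __post_init__(self):
        if self.expansion < 1:
            raise ValueError("expansion must be >= 1")
        if not (0 < self.se_ratio <= 1):
            raise ValueError("se_ratio must lie in (0, 1]")
        if not self.downsample and self.in_dim != self.out_dim:
            raise ValueError("non-downsampling MBConv requires in_dim == out_dim")

    @property
    def mid_dim(self) -> int:
        return self.expansion * self.out_dim

    @property
    def se_hidden(self) -> int:
        return max(1, int(self.mid_dim * self.se_ratio))


class SqueezeExcite(Module):
    """Channel gate from a globally average-pooled descriptor.

    gate = sigmoid(W2 relu(W1 mean_hw(x))); output is x * gate, so the
    spatial shape is unchanged and every gate lies strictly in (0, 1).
    """

    def __init__(self, channels: int, hidden: int,
                 rng: np.random.Generator | None = None):
        super().__init__()
        self.fc1 = Linear(channels, hidden, rng=rng)
        self.fc2 = Linear(hidden, channels, rng=rng)

    def gates(self, x) -> Tensor:
        pooled = x.mean(axis=(-3, -2), keepdims=True)  # (N,1,1,C)
        return self.fc2(self.fc1(pooled).relu()).sigmoid()

    def forward(self, x):
        return x * self.gates(x)


class MBConv(Module):
    def __init__(self, cfg: MBConvConfig, rng: np.random.Generator | None = None):
        super().__init__()
        self.cfg = cfg
        mid = cfg.mid_dim
        self.pre_norm = BatchNorm2d(cfg.in_dim)
        self.expand = Linear(cfg.in_dim, mid, rng=rng)
        self.bn1 = BatchNorm2d(mid)
        self.dw = DepthwiseConv2d(mid, 3, stride=2 if cfg.downsample else 1,
                                  padding=1, rng=rng)
        self.bn2 = BatchNorm2d(mid)
        self.se = SqueezeExcite(mid, cfg.se_hidden, rng=rng)
        self.proj = Linear(mid, cfg.out_dim, rng=rng)
        if cfg.downsample:
            self.shortcut_proj = Linear(cfg.in_dim, cfg.out_dim, rng=rng)

    def forward(self, x):
        n, h, w, c = (x.shape if x.ndim == 4 else (1,) + tuple(x.shape))
        if c != self.cfg.in_dim:
            raise ValueError(f"MBConv expects {self.cfg.in_dim} channels, got {c}")
        if self.cfg.downsample and (h % 2 or w % 2):
            raise ValueError(f"downsampling MBConv requires even extent, got ({h},{w})")
        y = self.pre_norm(x)
        y = self.bn1(self.expand(y)).gelu()
        y = self.bn2(self.dw(y)).gelu()
        y = self.se(y)
        y = self.proj(y)
        if self.cfg.downsample:
            return self.shortcut_proj(avg_pool2d(x, 2)) + y
        return x + y


class Stem(Module):
    """Patchify the input image to (H/2, W/2, stem_dim).

    A 3x3 stride-2 convolution (BatchNorm + GELU) followed by a 3x3
    stride-1 convolution — the convolutional equivalent of splitting the
    image into patches at this granularity.
    """

    def __init__(self, in_channels: int = 3, stem_dim: int = 64,
                 rng: np.random.Generator | None = None):
        super().__init__()
        from .nn import Conv2d  # local import keeps the module surface tidy
        self.conv1 = Conv2d(in_channels, stem_dim, 3, stride=2, padding=1, rng=rng)
        self.bn = BatchNorm2d(stem_dim)
        self.conv2 = Conv2d(stem_dim, stem_dim, 3, stride=1, padding=1, rng=rng)

    def forward(self, image):
        h, w = image.shape[-3], image.shape[-2]
        if h % 2 or w % 2:
            raise ValueError(f"stem requires even image extent, got ({h},{w})")
        return self.conv2(self.bn(self.conv1(image)).gelu())
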