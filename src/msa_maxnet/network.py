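"""MSA-MaxNet: multi-axis attention encoder-decoder for 2D segmentation.

Topology
--------
A stem patchifies the input to (H/2, W/2, stem_dim). Four encoder stages
each run ``depth`` units of (MBConv -> MaxViT block); the first MBConv of
a stage downsamples by 2 (doubling channels from stage 2 on), giving
feature maps at H/4..H/32 with widths C..8C. The deepest features pass
through a CBAM bottleneck. Three decoder stages mirror the encoder:
patch-expanding (2x up, half channels), fusion with the MCBAM-refined
skip features, then MaxViT blocks. A final 4x patch expansion and a 1x1
classification head produce per-pixel logits at the input resolution.

Ablation axes (config only, no code edits): ``skip_mode`` in
{mcbam, cbam, none} selects how skip features are refined, and
``downsample_mode`` in {mbconv, plain_conv} swaps every MBConv for a
single 3x3 convolution.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, replace

import numpy as np
import yaml

from .attention_gates import CBAM, CBAMConfig, MCBAM
from .convblocks import MBConv, MBConvConfig, Stem
from .maxsa import AttentionConfig, MaxViTBlock
from .nn import (
    BatchNorm2d, Conv2d, Linear, Module, ModuleList, Sequential, Tensor, no_grad,
)

__all__ = ["ModelConfig", "EncoderFeatures", "Encoder", "Decoder",
           "PatchExpand", "FinalPatchExpand", "SkipFuse", "MSAMaxNet",
           "count_parameters", "base_config", "reduced_config"]

SKIP_MODES = ("mcbam", "cbam", "none")
DOWNSAMPLE_MODES = ("mbconv", "plain_conv")


@dataclass(frozen=True)
class ModelConfig:
    """Fully determines the network (and therefore its parameter count)."""

    img_size: int = 224
    in_channels: int = 3
    num_classes: int = 9
    stem_dim: int = 64
    stage_dims: tuple[int, ...] = (64, 128, 256, 512)
    encoder_depths: tuple[int, ...] = (2, 2, 5, 2)
    decoder_depths: tuple[int, ...] = (2, 2, 2)
    window_p: int = 7
    grid_g: int = 7
    head_dim: int = 32
    mlp_ratio: float = 4.0
    expansion: int = 4
    se_ratio: float = 0.25
    cbam_reduction: int = 16
    spatial_kernel: int = 7
    skip_mode: str = "mcbam"
    downsample_mode: str = "mbconv"
    skip_fusion: str = "concat"  # or "add"

    def __post_init__(self):
        if self.skip_mode not in SKIP_MODES:
            raise ValueError(f"skip_mode must be one of {SKIP_MODES}")
        if self.downsample_mode not in DOWNSAMPLE_MODES:
            raise ValueError(f"downsample_mode must be one of {DOWNSAMPLE_MODES}")
        if len(self.stage_dims) != 4 or len(self.encoder_depths) != 4:
            raise ValueError("expected four encoder stages")
        if len(self.decoder_depths) != 3:
            raise ValueError("expected three decoder stages")
        for a, b in zip(self.stage_dims[:-1], self.stage_dims[1:]):
            if b != 2 * a:
                raise ValueError("stage widths must double stage to stage")
        if self.img_size % 32:
            raise ValueError("img_size must divide by 32")
        for s in range(4):
            extent = self.img_size // (4 * 2 ** s)
            if extent % self.window_p or extent % self.grid_g:
                raise ValueError(
                    f"stage extent {extent} not divisible by window {self.window_p} "
                    f"/ grid {self.grid_g}")

    def attention(self, dim: int) -> AttentionConfig:
        return AttentionConfig(dim=dim, head_dim=min(self.head_dim, dim),
                               window_p=self.window_p, grid_g=self.grid_g,
                               mlp_ratio=self.mlp_ratio)

    # -- serialization --------------------------------------------------------

    def to_dict(self) -> dict:
        d = asdict(self)
        for key in ("stage_dims", "encoder_depths", "decoder_depths"):
            d[key] = list(d[key])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        d = dict(d)
        for key in ("stage_dims", "encoder_depths", "decoder_depths"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "ModelConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()).hexdigest()[:16]


def base_config(**overrides) -> ModelConfig:
    """The full-size configuration (about 40 M trainable parameters)."""
    return replace(ModelConfig(), **overrides) if overrides else ModelConfig()


def reduced_config(**overrides) -> ModelConfig:
    """A desk-scale configuration: 64 px inputs, widths 16..128, P=G=2."""
    cfg = ModelConfig(img_size=64, num_classes=4, stem_dim=16,
                      stage_dims=(16, 32, 64, 128), encoder_depths=(1, 1, 1, 1),
                      decoder_depths=(1, 1, 1), window_p=2, grid_g=2,
                      head_dim=8, cbam_reduction=4)
    return replace(cfg, **overrides) if overrides else cfg


@dataclass
class EncoderFeatures:
    """Stem output (H/2) plus the four stage outputs (H/4 .. H/32)."""

    stem_out: Tensor
    stage_outs: list


class _PlainConvDown(Module):
    """Ablation replacement for MBConv: one 3x3 conv (+BN, GELU)."""

    def __init__(self, in_dim: int, out_dim: int, downsample: bool,
                 rng: np.random.Generator | None = None):
        super().__init__()
        self.conv = Conv2d(in_dim, out_dim, 3, stride=2 if downsample else 1,
                           padding=1, rng=rng)
        self.bn = BatchNorm2d(out_dim)

    def forward(self, x):
        return self.bn(self.conv(x)).gelu()


def _conv_unit(cfg: ModelConfig, in_dim: int, out_dim: int, downsample: bool,
               rng) -> Module:
    if cfg.downsample_mode == "plain_conv":
        return _PlainConvDown(in_dim, out_dim, downsample, rng=rng)
    return MBConv(MBConvConfig(in_dim, out_dim, cfg.expansion, cfg.se_ratio,
                               downsample), rng=rng)


class Encoder(Module):
    def __init__(self, cfg: ModelConfig, rng: np.random.Generator | None = None):
        super().__init__()
        self.cfg = cfg
        self.stem = Stem(cfg.in_channels, cfg.stem_dim, rng=rng)
        stages = []
        in_dim = cfg.stem_dim
        for dim, depth in zip(cfg.stage_dims, cfg.encoder_depths):
            units = []
            for k in range(depth):
                units.append(_conv_unit(cfg, in_dim if k == 0 else dim, dim,
                                        downsample=(k == 0), rng=rng))
                units.append(MaxViTBlock(cfg.attention(dim), rng=rng))
                in_dim = dim
            stages.append(Sequential(units))
        self.stages = ModuleList(stages)

    def forward(self, image) -> EncoderFeatures:
        if image.shape[-3] != self.cfg.img_size or image.shape[-2] != self.cfg.img_size:
            raise ValueError(
                f"expected {self.cfg.img_size}px input, got {image.shape[-3:-1]}")
        stem_out = self.stem(image)
        outs = []
        x = stem_out
        for stage in self.stages:
            x = stage(x)
            outs.append(x)
        return EncoderFeatures(stem_out=stem_out, stage_outs=outs)


class PatchExpand(Module):
    """2x spatial upsampling with channel halving.

    A linear expansion to 2C followed by depth-to-space: each pixel's 2C
    channels become a 2x2 patch of C/2 channels.
    """

    def __init__(self, dim: int, rng: np.random.Generator | None = None):
        super().__init__()
        if dim % 2:
            raise ValueError("patch expansion needs an even channel count")
        self.dim = dim
        self.expand = Linear(dim, 2 * dim, bias=False, rng=rng)

    def forward(self, x):
        n, h, w, c = x.shape
        if c != self.dim:
            raise ValueError(f"expected {self.dim} channels, got {c}")
        y = self.expand(x)  # (N,H,W,2C)
        y = y.reshape(n, h, w, 2, 2, c // 2)
        y = y.transpose((0, 1, 3, 2, 4, 5))
        return y.reshape(n, 2 * h, 2 * w, c // 2)


class FinalPatchExpand(Module):
    """4x spatial upsampling keeping the embedding width."""

    def __init__(self, dim: int, rng: np.random.Generator | None = None):
        super().__init__()
        self.dim = dim
        self.expand = Linear(dim, 16 * dim, bias=False, rng=rng)

    def forward(self, x):
        n, h, w, c = x.shape
        if c != self.dim:
            raise ValueError(f"expected {self.dim} channels, got {c}")
        y = self.expand(x)
        y = y.reshape(n, h, w, 4, 4, c)
        y = y.transpose((0, 1, 3, 2, 4, 5))
        return y.reshape(n, 4 * h, 4 * w, c)


class SkipFuse(Module):
    """Fuse upsampled decoder features with (refined) encoder features.

    ``concat``: channel concatenation followed by a linear projection back
    to the decoder width; ``add``: plain elementwise sum.
    """

    def __init__(self, dim: int, mode: str = "concat",
                 rng: np.random.Generator | None = None):
        super().__init__()
        if mode not in ("concat", "add"):
            raise ValueError("skip fusion mode must be 'concat' or 'add'")
        self.mode = mode
        self.dim = dim
        if mode == "concat":
            self.proj = Linear(2 * dim, dim, rng=rng)

    def forward(self, up, skip):
        if up.shape[-3:-1] != skip.shape[-3:-1]:
            raise ValueError(f"extent mismatch: {up.shape[-3:-1]} vs {skip.shape[-3:-1]}")
        if up.shape[-1] != self.dim or skip.shape[-1] != self.dim:
            raise ValueError("skip fusion requires matching channel widths")
        if self.mode == "add":
            return up + skip
        from .nn import concat as cat
        return self.proj(cat([up, skip], axis=-1))


class Decoder(Module):
    def __init__(self, cfg: ModelConfig, rng: np.random.Generator | None = None):
        super().__init__()
        self.cfg = cfg
        dims = cfg.stage_dims
        self.bottleneck = CBAM(CBAMConfig(dims[3], cfg.cbam_reduction,
                                          cfg.spatial_kernel), rng=rng)
        expands, fuses, gates, blocks = [], [], [], []
        for i, s in enumerate((2, 1, 0)):  # decoder stages at H/16, H/8, H/4
            expands.append(PatchExpand(dims[s + 1], rng=rng))
            fuses.append(SkipFuse(dims[s], cfg.skip_fusion, rng=rng))
            if cfg.skip_mode == "mcbam":
                c1 = dims[s - 1] if s > 0 else cfg.stem_dim
                gates.append(MCBAM(dims[s], c1, kernel=cfg.spatial_kernel, rng=rng))
            elif cfg.skip_mode == "cbam":
                gates.append(CBAM(CBAMConfig(dims[s], cfg.cbam_reduction,
                                             cfg.spatial_kernel), rng=rng))
            else:
                gates.append(None)
            blocks.append(Sequential([MaxViTBlock(cfg.attention(dims[s]), rng=rng)
                                      for _ in range(cfg.decoder_depths[i])]))
        self.expands = ModuleList(expands)
        self.fuses = ModuleList(fuses)
        self.gates = ModuleList([g for g in gates if g is not None])
        self._gate_for_stage = {s: g for s, g in zip((2, 1, 0), gates) if g is not None}
        self.blocks = ModuleList(blocks)
        self.final_expand = FinalPatchExpand(dims[0], rng=rng)
        self.head = Linear(dims[0], cfg.num_classes, rng=rng)

    def _refined_skip(self, feats: EncoderFeatures, s: int):
        f0 = feats.stage_outs[s]
        gate = self._gate_for_stage.get(s)
        if gate is None:
            return f0
        if isinstance(gate, MCBAM):
            f1 = feats.stage_outs[s - 1] if s > 0 else feats.stem_out
            f2 = feats.stage_outs[s + 1]
            return gate(f0, f1, f2)
        return gate(f0)

    def forward(self, feats: EncoderFeatures):
        x = self.bottleneck(feats.stage_outs[3])
        for i, s in enumerate((2, 1, 0)):
            x = self.expands[i](x)
            x = self.fuses[i](x, self._refined_skip(feats, s))
            x = self.blocks[i](x)
        x = self.final_expand(x)
        return self.head(x)


class MSAMaxNet(Module):
    """The full segmentation network; forward maps images to pixel logits."""

    def __init__(self, cfg: ModelConfig, seed: int | None = 0):
        super().__init__()
        rng = np.random.default_rng(seed)
        self.cfg = cfg
        self.encoder = Encoder(cfg, rng=rng)
        self.decoder = Decoder(cfg, rng=rng)

    def forward(self, image):
        squeeze = image.ndim == 3
        if not isinstance(image, Tensor):
            image = Tensor(np.asarray(image, dtype=np.float32))
        if squeeze:
            image = image.reshape(1, *image.shape)
        logits = self.decoder(self.encoder(image))
        return logits.reshape(*logits.shape[1:]) if squeeze else logits

    def predict(self, image) -> np.ndarray:
        """Argmax class map for one image or a batch (inference mode)."""
        was_training = self.training
        self.eval()
        try:
            with no_grad():
                logits = self.forward(image)
        finally:
            self.train(was_training)
        return np.argmax(logits.data, axis=-1).astype(np.int64)


def count_parameters(model_or_cfg) -> float:
    """Total trainable scalars in millions, rounded to two decimals."""
    model = (model_or_cfg if isinstance(model_or_cfg, Module)
             else MSAMaxNet(model_or_cfg))
    return round(model.num_parameters() / 1e6, 2)
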