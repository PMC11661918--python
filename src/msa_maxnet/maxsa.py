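"""Multi-axis self-attention (Max-SA) primitives.

The multi-axis scheme decomposes full self-attention into two sparse
forms. *Block attention* partitions the feature map into non-overlapping
P x P tiles and attends within each tile (local interactions). *Grid
attention* splits each spatial axis into G strided cosets, so tokens that
share the same intra-cell offset attend to one another across the whole
map (dilated, global interactions). Both use softmax attention with a
learned relative positional bias, and each attention stage is followed by
a position-wise MLP, with pre-layer-norm and residual connections
throughout. Because attention is always confined to groups of P*P (or
G*G) tokens, cost grows linearly with image area.

Feature maps are channels-last: (H, W, C) or batched (N, H, W, C).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .nn import (
    GELU, LayerNorm, Linear, Module, Parameter, Sequential, Tensor,
    index_select_last,
)
from .nn.functional import softmax

__all__ = [
    "AttentionConfig", "WindowSet", "RelativeBiasTable",
    "block_partition", "unblock", "grid_partition", "ungrid",
    "relative_attention", "FeedForward",
    "BlockAttentionLayer", "GridAttentionLayer", "MaxViTBlock",
]


@dataclass(frozen=True)
class AttentionConfig:
    """Hyperparameters shared by all Max-SA stages.

    dim
        channels per token.
    head_dim
        channels per attention head; ``dim`` must divide evenly.
    window_p, grid_g
        block tile size P and grid coset count G.
    mlp_ratio
        hidden-width expansion of the position-wise MLP.
    """

    dim: int
    head_dim: int = 32
    window_p: int = 7
    grid_g: int = 7
    mlp_ratio: float = 4.0
    qkv_bias: bool = True

    def __post_init__(self):
        if self.dim % self.head_dim:
            raise ValueError(f"dim {self.dim} not divisible by head_dim {self.head_dim}")
        if self.window_p < 1 or self.grid_g < 1:
            raise ValueError("window_p and grid_g must be >= 1")
        if self.mlp_ratio <= 0:
            raise ValueError("mlp_ratio must be positive")

    @property
    def num_heads(self) -> int:
        return self.dim // self.head_dim


@dataclass
class WindowSet:
    """A batch of token groups plus the bookkeeping needed to reverse it."""

    windows: object  # (N, n_groups, group_size, C), Tensor or ndarray
    origin_shape: tuple[int, ...]  # (H, W, C) of the source map
    mode: str  # "block" | "grid"
    size: int  # P or G
    batched: bool  # whether the source had a leading batch axis


def _with_batch(x):
    """Normalize (H,W,C) / (N,H,W,C) input; returns (x4d, was_batched)."""
    if x.ndim == 3:
        return x.reshape(1, *x.shape), False
    if x.ndim == 4:
        return x, True
    raise ValueError(f"expected a rank-3 or rank-4 feature map, got rank {x.ndim}")


def block_partition(x, p: int) -> WindowSet:
    """Split into non-overlapping p x p tiles, row-major in tiles and in-tile."""
    x4, batched = _with_batch(x)
    n, h, w, c = x4.shape
    if h % p or w % p:
        raise ValueError(f"extent ({h},{w}) not divisible by window size {p}")
    t = x4.reshape(n, h // p, p, w // p, p, c)
    t = t.transpose((0, 1, 3, 2, 4, 5))
    win = t.reshape(n, (h // p) * (w // p), p * p, c)
    return WindowSet(win, (h, w, c), "block", p, batched)


def unblock(ws: WindowSet):
    """Exact inverse of :func:`block_partition`."""
    h, w, c = ws.origin_shape
    p = ws.size
    win = ws.windows
    n, groups, size, cw = win.shape
    if ws.mode != "block" or groups * size != h * w or cw != c:
        raise ValueError("window set inconsistent with its origin shape")
    t = win.reshape(n, h // p, w // p, p, p, c)
    t = t.transpose((0, 1, 3, 2, 4, 5))
    x = t.reshape(n, h, w, c)
    return x if ws.batched else x.reshape(h, w, c)


def grid_partition(x, g: int) -> WindowSet:
    """Split each axis into g strided cosets; one group per intra-cell offset.

    Group k contains the g*g tokens at positions (a*(H/g)+r, b*(W/g)+s) for
    a,b in [0,g), where (r,s) is the group's offset — a dilated sampling
    pattern with stride (H/g, W/g).
    """
    x4, batched = _with_batch(x)
    n, h, w, c = x4.shape
    if h % g or w % g:
        raise ValueError(f"extent ({h},{w}) not divisible by grid size {g}")
    t = x4.reshape(n, g, h // g, g, w // g, c)
    t = t.transpose((0, 2, 4, 1, 3, 5))
    win = t.reshape(n, (h // g) * (w // g), g * g, c)
    return WindowSet(win, (h, w, c), "grid", g, batched)


def ungrid(ws: WindowSet):
    """Exact inverse of :func:`grid_partition`."""
    h, w, c = ws.origin_shape
    g = ws.size
    win = ws.windows
    n, groups, size, cw = win.shape
    if ws.mode != "grid" or groups * size != h * w or cw != c:
        raise ValueError("window set inconsistent with its origin shape")
    t = win.reshape(n, h // g, w // g, g, g, c)
    t = t.transpose((0, 3, 1, 4, 2, 5))
    x = t.reshape(n, h, w, c)
    return x if ws.batched else x.reshape(h, w, c)


def relative_index_map(p: int) -> np.ndarray:
    """(p*p, p*p) map from a token pair to its relative-offset table slot."""
    coords = np.stack(np.meshgrid(np.arange(p), np.arange(p), indexing="ij"), -1).reshape(-1, 2)
    rel = coords[:, None, :] - coords[None, :, :] + (p - 1)  # offsets in [0, 2p-2]
    return (rel[..., 0] * (2 * p - 1) + rel[..., 1]).astype(np.int64)


class RelativeBiasTable(Module):
    """Learned additive attention bias indexed by 2D token-pair offset.

    Stores one value per head per relative offset — (2p-1)^2 entries for a
    p x p group — and expands to the full (heads, p*p, p*p) bias matrix.
    Initialized to zero, so attention starts unbiased.
    """

    def __init__(self, window: int, num_heads: int):
        super().__init__()
        self.window = window
        self.num_heads = num_heads
        self.table = Parameter(np.zeros((num_heads, (2 * window - 1) ** 2)))
        self.index_map = relative_index_map(window)

    def matrix(self) -> Tensor:
        return index_select_last(self.table, self.index_map)

    forward = matrix


def relative_attention(q, k, v, bias, head_dim: int) -> Tensor:
    """softmax(Q K^T / sqrt(d) + B) V per head, heads merged (no projection).

    q, k, v: (..., n, dim) token groups; bias: (heads, n, n) or an array
    broadcastable to the attention logits. Rejects NaN inputs.
    """
    q, k, v = (t if isinstance(t, Tensor) else Tensor(t) for t in (q, k, v))
    for name, t in (("q", q), ("k", k), ("v", v)):
        if np.isnan(t.data).any():
            raise ValueError(f"relative_attention: NaN in {name}")
    if not (q.shape == k.shape == v.shape):
        raise ValueError("q, k, v must share a shape")
    *lead, n, dim = q.shape
    if dim % head_dim:
        raise ValueError(f"dim {dim} not divisible by head_dim {head_dim}")
    heads = dim // head_dim
    b = int(np.prod(lead)) if lead else 1

    def split(t):  # (..., n, dim) -> (b, heads, n, head_dim)
        return t.reshape(b, n, heads, head_dim).transpose((0, 2, 1, 3))

    qh, kh, vh = split(q), split(k), split(v)
    logits = qh @ kh.transpose((0, 1, 3, 2)) * (1.0 / math.sqrt(head_dim))
    if bias is not None:
        bias = bias if isinstance(bias, Tensor) else Tensor(bias)
        logits = logits + bias
    attn = softmax(logits, axis=-1)
    out = attn @ vh  # (b, heads, n, head_dim)
    out = out.transpose((0, 2, 1, 3)).reshape(*lead, n, dim)
    return out


class FeedForward(Module):
    """Position-wise two-layer MLP: W2 GELU(W1 x)."""

    def __init__(self, dim: int, mlp_ratio: float = 4.0,
                 rng: np.random.Generator | None = None):
        super().__init__()
        hidden = int(dim * mlp_ratio)
        self.net = Sequential([Linear(dim, hidden, rng=rng), GELU(),
                               Linear(hidden, dim, rng=rng)])

    def forward(self, x):
        return self.net(x)


class _AxisAttentionLayer(Module):
    """Shared machinery of the block- and grid-attention layers.

    x <- x + Merge(RelAttention(Partition(LN(x))))
    x <- x + MLP(LN(x))
    """

    mode = "block"

    def __init__(self, cfg: AttentionConfig, rng: np.random.Generator | None = None):
        super().__init__()
        self.cfg = cfg
        size = cfg.window_p if self.mode == "block" else cfg.grid_g
        self.size = size
        self.norm1 = LayerNorm(cfg.dim)
        self.qkv = Linear(cfg.dim, 3 * cfg.dim, bias=cfg.qkv_bias, rng=rng)
        self.bias_table = RelativeBiasTable(size, cfg.num_heads)
        self.proj = Linear(cfg.dim, cfg.dim, rng=rng)
        self.norm2 = LayerNorm(cfg.dim)
        self.mlp = FeedForward(cfg.dim, cfg.mlp_ratio, rng=rng)
        self.last_group_size: int | None = None  # attention-cost bookkeeping

    def _partition(self, x) -> WindowSet:
        if self.mode == "block":
            return block_partition(x, self.size)
        return grid_partition(x, self.size)

    def _merge(self, ws: WindowSet):
        return unblock(ws) if ws.mode == "block" else ungrid(ws)

    def forward(self, x):
        d = self.cfg.dim
        ws = self._partition(self.norm1(x))
        tokens = ws.windows
        self.last_group_size = tokens.shape[-2]
        qkv = self.qkv(tokens)
        q = qkv.narrow(-1, 0, d)
        k = qkv.narrow(-1, d, d)
        v = qkv.narrow(-1, 2 * d, d)
        attended = relative_attention(q, k, v, self.bias_table.matrix(), self.cfg.head_dim)
        attended = self.proj(attended)
        ws_out = WindowSet(attended.reshape(*tokens.shape), ws.origin_shape,
                           ws.mode, ws.size, ws.batched)
        x = x + self._merge(ws_out)
        x = x + self.mlp(self.norm2(x))
        return x


class BlockAttentionLayer(_AxisAttentionLayer):
    """Local windowed attention within P x P tiles, plus its MLP."""

    mode = "block"


class GridAttentionLayer(_AxisAttentionLayer):
    """Global dilated attention across the G x G coset lattice, plus its MLP."""

    mode = "grid"


class MaxViTBlock(Module):
    """One Max-SA block: block attention followed by grid attention."""

    def __init__(self, cfg: AttentionConfig, rng: np.random.Generator | None = None):
        super().__init__()
        self.block_attn = BlockAttentionLayer(cfg, rng=rng)
        self.grid_attn = GridAttentionLayer(cfg, rng=rng)

    def forward(self, x):
        return self.grid_attn(self.block_attn(x))
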