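"""Neural-network functional ops on the autodiff Tensor.

Feature maps are laid out channels-last: (N, H, W, C). Convolutions are
implemented by im2col (patch extraction with stride tricks) plus a matrix
product; the backward pass scatters patch gradients back with a small
kernel-sized loop.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .tensor import Tensor, as_tensor

__all__ = ["conv2d", "depthwise_conv2d", "avg_pool2d", "softmax", "log_softmax"]


def _extract_patches(x: np.ndarray, kh: int, kw: int, stride: int, padding: int):
    """(N,H,W,C) -> patches (N, OH, OW, KH, KW, C) plus the padded input shape."""
    if padding:
        x = np.pad(x, ((0, 0), (padding, padding), (padding, padding), (0, 0)))
    win = sliding_window_view(x, (kh, kw), axis=(1, 2))  # (N, H', W', C, KH, KW)
    win = win[:, ::stride, ::stride]
    patches = np.ascontiguousarray(win.transpose(0, 1, 2, 4, 5, 3))
    return patches, x.shape


def _scatter_patches(gpatches: np.ndarray, padded_shape, stride: int, padding: int,
                     out_hw) -> np.ndarray:
    """Adjoint of _extract_patches: accumulate patch grads into an image grad."""
    n, hp, wp, c = padded_shape
    oh, ow = out_hw
    kh, kw = gpatches.shape[3], gpatches.shape[4]
    gx = np.zeros(padded_shape, dtype=gpatches.dtype)
    for ki in range(kh):
        for kj in range(kw):
            gx[:, ki:ki + stride * oh:stride, kj:kj + stride * ow:stride, :] += gpatches[:, :, :, ki, kj, :]
    if padding:
        gx = gx[:, padding:hp - padding, padding:wp - padding, :]
    return gx


def conv2d(x: Tensor, weight: Tensor, bias: Tensor | None = None,
           stride: int = 1, padding: int = 0) -> Tensor:
    """Dense 2D convolution; weight laid out (KH, KW, Cin, Cout)."""
    x = as_tensor(x)
    kh, kw, cin, cout = weight.shape
    if x.shape[-1] != cin:
        raise ValueError(f"conv2d: input has {x.shape[-1]} channels, weight expects {cin}")
    patches, padded_shape = _extract_patches(x.data, kh, kw, stride, padding)
    n, oh, ow = patches.shape[:3]
    cols = patches.reshape(n * oh * ow, kh * kw * cin)
    wmat = weight.data.reshape(kh * kw * cin, cout)
    out_data = (cols @ wmat).reshape(n, oh, ow, cout)
    if bias is not None:
        out_data = out_data + bias.data

    parents = (x, weight) if bias is None else (x, weight, bias)

    def backward(g):
        gcols = g.reshape(n * oh * ow, cout)
        if weight.requires_grad:
            weight._accumulate((cols.T @ gcols).reshape(weight.shape))
        if bias is not None and bias.requires_grad:
            bias._accumulate(gcols.sum(axis=0))
        if x.requires_grad:
            gpatch = (gcols @ wmat.T).reshape(n, oh, ow, kh, kw, cin)
            x._accumulate(_scatter_patches(gpatch, padded_shape, stride, padding, (oh, ow)))

    return Tensor._make(out_data, parents, backward)


def depthwise_conv2d(x: Tensor, weight: Tensor, bias: Tensor | None = None,
                     stride: int = 1, padding: int = 0) -> Tensor:
    """Per-channel 2D convolution; weight laid out (KH, KW, C)."""
    x = as_tensor(x)
    kh, kw, c = weight.shape
    if x.shape[-1] != c:
        raise ValueError(f"depthwise_conv2d: input has {x.shape[-1]} channels, weight expects {c}")
    patches, padded_shape = _extract_patches(x.data, kh, kw, stride, padding)
    n, oh, ow = patches.shape[:3]
    out_data = np.einsum("nhwijc,ijc->nhwc", patches, weight.data, optimize=True)
    if bias is not None:
        out_data = out_data + bias.data

    parents = (x, weight) if bias is None else (x, weight, bias)

    def backward(g):
        if weight.requires_grad:
            weight._accumulate(np.einsum("nhwijc,nhwc->ijc", patches, g, optimize=True))
        if bias is not None and bias.requires_grad:
            bias._accumulate(g.sum(axis=(0, 1, 2)))
        if x.requires_grad:
            gpatch = np.einsum("nhwc,ijc->nhwijc", g, weight.data, optimize=True)
            x._accumulate(_scatter_patches(gpatch, padded_shape, stride, padding, (oh, ow)))

    return Tensor._make(out_data, parents, backward)


def avg_pool2d(x: Tensor, factor: int = 2) -> Tensor:
    """Non-overlapping average pooling; H and W must divide by `factor`."""
    n, h, w, c = x.shape
    if h % factor or w % factor:
        raise ValueError(f"avg_pool2d: extent ({h},{w}) not divisible by {factor}")
    y = x.reshape(n, h // factor, factor, w // factor, factor, c)
    return y.mean(axis=(2, 4))


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    shifted = x - Tensor(x.data.max(axis=axis, keepdims=True))
    e = shifted.exp()
    return e / e.sum(axis=axis, keepdims=True)


def log_softmax(x: Tensor, axis: int = -1) -> Tensor:
    shifted = x - Tensor(x.data.max(axis=axis, keepdims=True))
    return shifted - shifted.exp().sum(axis=axis, keepdims=True).log()
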