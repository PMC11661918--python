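"""Minimal module/parameter system over the autodiff Tensor."""

from __future__ import annotations

import math
from collections import OrderedDict

import numpy as np

from . import functional as F
from .tensor import Tensor

__all__ = [
    "Parameter", "Module", "ModuleList", "Sequential", "Identity",
    "Linear", "Conv2d", "DepthwiseConv2d", "BatchNorm2d", "LayerNorm", "GELU",
    "trunc_normal_",
]


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(np.asarray(data, dtype=np.float32), requires_grad=True)


def trunc_normal_(param: Parameter, std: float = 0.02, rng: np.random.Generator | None = None):
    """Fill with N(0, std) truncated at ±2 std (resampling rejection)."""
    rng = rng or np.random.default_rng()
    shape = param.shape
    vals = rng.normal(0.0, std, size=shape)
    bad = np.abs(vals) > 2 * std
    while bad.any():
        vals[bad] = rng.normal(0.0, std, size=int(bad.sum()))
        bad = np.abs(vals) > 2 * std
    param.data = vals.astype(np.float32)
    return param


class Module:
    def __init__(self):
        object.__setattr__(self, "_params", OrderedDict())
        object.__setattr__(self, "_modules", OrderedDict())
        object.__setattr__(self, "training", True)

    def __setattr__(self, name, value):
        if isinstance(value, Parameter):
            self._params[name] = value
        elif isinstance(value, Module):
            self._modules[name] = value
        object.__setattr__(self, name, value)

    def named_parameters(self, prefix: str = ""):
        for name, p in self._params.items():
            yield (prefix + name, p)
        for name, m in self._modules.items():
            yield from m.named_parameters(prefix + name + ".")

    def parameters(self):
        seen: set[int] = set()  # modules may alias (share) a parameter
        for _, p in self.named_parameters():
            if id(p) not in seen:
                seen.add(id(p))
                yield p

    def modules(self):
        yield self
        for m in self._modules.values():
            yield from m.modules()

    def num_parameters(self) -> int:
        return sum(p.size for p in self.parameters())

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def train(self, mode: bool = True):
        for m in self.modules():
            object.__setattr__(m, "training", mode)
        return self

    def eval(self):
        return self.train(False)

    # -- (de)serialization ----------------------------------------------------

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {name: p.data.copy() for name, p in self.named_parameters()}
        for name, buf in self.named_buffers():
            state[name] = buf.copy()
        return state

    def named_buffers(self, prefix: str = ""):
        for name in getattr(self, "_buffer_names", ()):
            yield (prefix + name, getattr(self, name))
        for name, m in self._modules.items():
            yield from m.named_buffers(prefix + name + ".")

    def load_state_dict(self, state: dict[str, np.ndarray]):
        own = dict(self.named_parameters())
        bufs = dict(self.named_buffers())
        for key, value in state.items():
            if key in own:
                if own[key].shape != value.shape:
                    raise ValueError(f"shape mismatch for {key}: {own[key].shape} vs {value.shape}")
                own[key].data = np.asarray(value, dtype=np.float32).copy()
            elif key in bufs:
                np.copyto(bufs[key], value)
            else:
                raise KeyError(f"unexpected state entry {key!r}")
        missing = (set(own) | set(bufs)) - set(state)
        if missing:
            raise KeyError(f"missing state entries: {sorted(missing)}")

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)

    def forward(self, *args, **kwargs):  # pragma: no cover - abstract
        raise NotImplementedError


class ModuleList(Module):
    def __init__(self, mods=()):
        super().__init__()
        self._items = []
        for m in mods:
            self.append(m)

    def append(self, m: Module):
        setattr(self, str(len(self._items)), m)
        self._items.append(m)
        return self

    def __iter__(self):
        return iter(self._items)

    def __len__(self):
        return len(self._items)

    def __getitem__(self, i):
        return self._items[i]


class Sequential(ModuleList):
    def forward(self, x):
        for m in self:
            x = m(x)
        return x


class Identity(Module):
    def forward(self, x):
        return x


class GELU(Module):
    def forward(self, x):
        return x.gelu()


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, bias: bool = True,
                 rng: np.random.Generator | None = None):
        super().__init__()
        self.in_features = in_features
        self.out_features = out_features
        self.weight = trunc_normal_(Parameter(np.zeros((in_features, out_features))), 0.02, rng)
        self.bias = Parameter(np.zeros(out_features)) if bias else None

    def forward(self, x):
        y = x @ self.weight
        if self.bias is not None:
            y = y + self.bias
        return y


class Conv2d(Module):
    """Dense conv, weight (KH, KW, Cin, Cout), He-style truncated-normal init."""

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 stride: int = 1, padding: int = 0, bias: bool = True,
                 rng: np.random.Generator | None = None):
        super().__init__()
        self.stride, self.padding = stride, padding
        fan_in = kernel_size * kernel_size * in_channels
        std = math.sqrt(2.0 / fan_in)
        self.weight = trunc_normal_(
            Parameter(np.zeros((kernel_size, kernel_size, in_channels, out_channels))), std, rng)
        self.bias = Parameter(np.zeros(out_channels)) if bias else None

    def forward(self, x):
        return F.conv2d(x, self.weight, self.bias, self.stride, self.padding)


class DepthwiseConv2d(Module):
    def __init__(self, channels: int, kernel_size: int, stride: int = 1,
                 padding: int = 0, bias: bool = True,
                 rng: np.random.Generator | None = None):
        super().__init__()
        self.stride, self.padding = stride, padding
        std = math.sqrt(2.0 / (kernel_size * kernel_size))
        self.weight = trunc_normal_(
            Parameter(np.zeros((kernel_size, kernel_size, channels))), std, rng)
        self.bias = Parameter(np.zeros(channels)) if bias else None

    def forward(self, x):
        return F.depthwise_conv2d(x, self.weight, self.bias, self.stride, self.padding)


class BatchNorm2d(Module):
    """Batch normalization over (N, H, W) per channel, channels-last layout."""

    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.eps, self.momentum = eps, momentum
        self.weight = Parameter(np.ones(channels))
        self.bias = Parameter(np.zeros(channels))
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)
        self._buffer_names = ("running_mean", "running_var")

    def forward(self, x):
        if self.training:
            mu = x.mean(axis=(0, 1, 2), keepdims=True)
            var = ((x - mu) ** 2).mean(axis=(0, 1, 2), keepdims=True)
            m = self.momentum
            n = x.data.shape[0] * x.data.shape[1] * x.data.shape[2]
            unbiased = var.data.ravel() * (n / max(n - 1, 1))
            self.running_mean *= (1 - m)
            self.running_mean += m * mu.data.ravel()
            self.running_var *= (1 - m)
            self.running_var += m * unbiased.astype(np.float32)
            xhat = (x - mu) * (var + self.eps) ** -0.5
        else:
            xhat = (x - Tensor(self.running_mean)) * Tensor(
                1.0 / np.sqrt(self.running_var + self.eps))
        return xhat * self.weight + self.bias


class LayerNorm(Module):
    """Normalization over the trailing channel axis."""

    def __init__(self, dim: int, eps: float = 1e-6):
        super().__init__()
        self.eps = eps
        self.weight = Parameter(np.ones(dim))
        self.bias = Parameter(np.zeros(dim))

    def forward(self, x):
        mu = x.mean(axis=-1, keepdims=True)
        var = ((x - mu) ** 2).mean(axis=-1, keepdims=True)
        return (x - mu) * (var + self.eps) ** -0.5 * self.weight + self.bias
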