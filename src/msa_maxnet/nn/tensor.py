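"""Reverse-mode automatic differentiation on numpy arrays.

A deliberately small engine: exactly the operations the segmentation
network needs (broadcasted arithmetic, batched matmul, reshapes and
transposes, reductions, the activations used by the blocks, a gather for
relative-position tables and a concatenate for attention-map pooling).
Gradients are accumulated by topological traversal of the recorded graph.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.special import erf, expit

__all__ = ["Tensor", "as_tensor", "concat", "index_select_last", "no_grad"]

_GRAD_ENABLED = True


class no_grad:
    """Context manager disabling graph recording (inference / stats updates)."""

    def __enter__(self):
        global _GRAD_ENABLED
        self._prev = _GRAD_ENABLED
        _GRAD_ENABLED = False
        return self

    def __exit__(self, *exc):
        global _GRAD_ENABLED
        _GRAD_ENABLED = self._prev
        return False


def grad_enabled() -> bool:
    return _GRAD_ENABLED


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    axes = tuple(i for i, (g, s) in enumerate(zip(grad.shape, shape)) if s == 1 and g != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A numpy array with an optional gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False, _parents=(), _backward=None):
        data = np.asarray(data)
        if data.dtype.kind != "f":
            data = data.astype(np.float32)
        self.data = data
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad and _GRAD_ENABLED
        self._parents = _parents if self.requires_grad or _parents else ()
        self._backward = _backward

    # -- construction helpers -------------------------------------------------

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    @property
    def dtype(self):
        return self.data.dtype

    @property
    def size(self) -> int:
        return self.data.size

    def numpy(self) -> np.ndarray:
        return self.data

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def __repr__(self):
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"

    # -- graph machinery ------------------------------------------------------

    @staticmethod
    def _make(data, parents, backward) -> "Tensor":
        req = _GRAD_ENABLED and any(p.requires_grad for p in parents)
        out = Tensor(data, requires_grad=req)
        if req:
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def _accumulate(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = grad.astype(self.data.dtype, copy=True)
        else:
            self.grad += grad

    def backward(self, grad: np.ndarray | None = None) -> None:
        if not self.requires_grad:
            raise RuntimeError("backward() on a tensor that does not require grad")
        if grad is None:
            if self.size != 1:
                raise RuntimeError("backward() without a gradient requires a scalar output")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative DFS: deep graphs exceed Python recursion limits
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if p.requires_grad and id(p) not in seen:
                    stack.append((p, False))
        self._accumulate(np.asarray(grad, dtype=self.data.dtype))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- arithmetic -----------------------------------------------------------

    def __add__(self, other):
        other = as_tensor(other, like=self)

        def backward(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g, other.shape))

        return Tensor._make(self.data + other.data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(g):
            self._accumulate(-g)

        return Tensor._make(-self.data, (self,), backward)

    def __sub__(self, other):
        return self + (-as_tensor(other, like=self))

    def __rsub__(self, other):
        return as_tensor(other, like=self) + (-self)

    def __mul__(self, other):
        other = as_tensor(other, like=self)

        def backward(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g * other.data, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g * self.data, other.shape))

        return Tensor._make(self.data * other.data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        if isinstance(other, (int, float)):
            return self * (1.0 / other)
        return self * as_tensor(other, like=self) ** -1.0

    def __rtruediv__(self, other):
        return as_tensor(other, like=self) * self ** -1.0

    def __pow__(self, exponent: float):
        if not isinstance(exponent, (int, float)):
            raise TypeError("only scalar exponents are supported")
        out_data = self.data ** exponent

        def backward(g):
            self._accumulate(g * exponent * self.data ** (exponent - 1))

        return Tensor._make(out_data, (self,), backward)

    def __matmul__(self, other):
        other = as_tensor(other, like=self)

        def backward(g):
            if self.requires_grad:
                ga = g @ np.swapaxes(other.data, -1, -2)
                self._accumulate(_unbroadcast(ga, self.shape))
            if other.requires_grad:
                gb = np.swapaxes(self.data, -1, -2) @ g
                other._accumulate(_unbroadcast(gb, other.shape))

        return Tensor._make(self.data @ other.data, (self, other), backward)

    # -- shape ops ------------------------------------------------------------

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old = self.shape

        def backward(g):
            self._accumulate(g.reshape(old))

        return Tensor._make(self.data.reshape(shape), (self,), backward)

    def transpose(self, axes):
        axes = tuple(axes)
        inv = tuple(np.argsort(axes))

        def backward(g):
            self._accumulate(g.transpose(inv))

        return Tensor._make(self.data.transpose(axes), (self,), backward)

    def narrow(self, axis: int, start: int, length: int) -> "Tensor":
        """Contiguous slice along one axis."""
        idx = [slice(None)] * self.ndim
        idx[axis] = slice(start, start + length)
        idx = tuple(idx)

        def backward(g):
            gx = np.zeros_like(self.data)
            gx[idx] = g
            self._accumulate(gx)

        return Tensor._make(self.data[idx], (self,), backward)

    # -- reductions -----------------------------------------------------------

    def sum(self, axis=None, keepdims: bool = False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)
        shape = self.shape

        def backward(g):
            if axis is None:
                self._accumulate(np.broadcast_to(g, shape).copy())
                return
            if not keepdims:
                g = np.expand_dims(g, axis)
            self._accumulate(np.broadcast_to(g, shape).copy())

        return Tensor._make(out_data, (self,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            n = self.size
        else:
            axes = axis if isinstance(axis, tuple) else (axis,)
            n = int(np.prod([self.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) / n

    def max(self, axis, keepdims: bool = False):
        """Max over `axis`; ties share the incoming gradient equally."""
        out_data = self.data.max(axis=axis, keepdims=True)
        mask = (self.data == out_data)
        counts = mask.sum(axis=axis, keepdims=True)

        def backward(g):
            if not keepdims:
                g = np.expand_dims(g, axis) if not isinstance(axis, tuple) else g.reshape(counts.shape)
            self._accumulate(mask * (g / counts))

        res = out_data if keepdims else np.squeeze(out_data, axis=axis)
        return Tensor._make(res, (self,), backward)

    # -- elementwise nonlinearities -------------------------------------------

    def exp(self):
        out_data = np.exp(self.data)

        def backward(g):
            self._accumulate(g * out_data)

        return Tensor._make(out_data, (self,), backward)

    def log(self):
        def backward(g):
            self._accumulate(g / self.data)

        return Tensor._make(np.log(self.data), (self,), backward)

    def sigmoid(self):
        out_data = expit(self.data)

        def backward(g):
            self._accumulate(g * out_data * (1.0 - out_data))

        return Tensor._make(out_data, (self,), backward)

    def relu(self):
        mask = self.data > 0

        def backward(g):
            self._accumulate(g * mask)

        return Tensor._make(self.data * mask, (self,), backward)

    def gelu(self):
        """Exact (erf-based) GELU."""
        x = self.data
        cdf = 0.5 * (1.0 + erf(x / math.sqrt(2.0)))

        def backward(g):
            pdf = np.exp(-0.5 * x * x) / math.sqrt(2.0 * math.pi)
            self._accumulate(g * (cdf + x * pdf))

        return Tensor._make(x * cdf, (self,), backward)

    def sqrt(self):
        return self ** 0.5


def as_tensor(value, like: Tensor | None = None) -> Tensor:
    if isinstance(value, Tensor):
        return value
    dtype = like.data.dtype if like is not None else np.float32
    return Tensor(np.asarray(value, dtype=dtype))


def concat(tensors: list[Tensor], axis: int) -> Tensor:
    tensors = [t if isinstance(t, Tensor) else Tensor(t) for t in tensors]
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                idx = [slice(None)] * g.ndim
                idx[axis] = slice(lo, hi)
                t._accumulate(g[tuple(idx)])

    return Tensor._make(np.concatenate([t.data for t in tensors], axis=axis), tensors, backward)


def index_select_last(table: Tensor, index: np.ndarray) -> Tensor:
    """Gather entries of `table` (..., L) at integer positions `index`.

    Output shape is table.shape[:-1] + index.shape; used to expand a
    relative-position bias table into a full pairwise bias matrix.
    """
    index = np.asarray(index)
    out_data = table.data[..., index.ravel()].reshape(table.shape[:-1] + index.shape)

    def backward(g):
        gt = np.zeros_like(table.data)
        lead = int(np.prod(table.shape[:-1])) if table.ndim > 1 else 1
        g2 = g.reshape(lead, index.size)
        gt2 = gt.reshape(lead, table.shape[-1])
        np.add.at(gt2, (np.arange(lead)[:, None], index.ravel()[None, :]), g2)
        table._accumulate(gt)

    return Tensor._make(out_data, (table,), backward)
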