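"""Reverse-mode automatic differentiation over numpy arrays.

A deliberately small tape-based engine: every operation records its inputs
and a closure that maps the output gradient to input gradients.  It supports
exactly the primitives the brain-age network needs — broadcasting arithmetic,
matmul, elementwise nonlinearities, reductions (including max with argmax
routing), reshaping, concatenation, zero-padding and flat gather/scatter
(the latter two carry im2col-style convolution and patch reassembly).

Gradients are held as plain numpy arrays in ``Tensor.grad`` after
``Tensor.backward()``.
"""

from __future__ import annotations

import contextlib
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "Tensor",
    "no_grad",
    "is_grad_enabled",
    "concatenate",
    "matmul",
    "exp",
    "log",
    "sqrt",
    "sigmoid",
    "tanh",
    "relu",
    "leaky_relu",
    "clip_max",
    "take_flat",
    "scatter_add_flat",
    "pad_nd",
    "maximum",
]

_grad_enabled = True


@contextlib.contextmanager
def no_grad():
    """Disable graph recording inside the ``with`` block."""
    global _grad_enabled
    prev = _grad_enabled
    _grad_enabled = False
    try:
        yield
    finally:
        _grad_enabled = prev


def is_grad_enabled() -> bool:
    return _grad_enabled


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Reduce ``grad`` back to ``shape`` after numpy broadcasting."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A numpy array plus the bookkeeping needed for reverse-mode autodiff."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad) and _grad_enabled
        self._backward = None
        self._prev: tuple = ()

    # -- construction helpers -------------------------------------------------

    @staticmethod
    def _make(data, parents: Sequence["Tensor"], backward) -> "Tensor":
        out = Tensor(data)
        if _grad_enabled and any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._prev = tuple(parents)
            out._backward = backward
        return out

    # -- basic introspection --------------------------------------------------

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def size(self):
        return self.data.size

    @property
    def dtype(self):
        return self.data.dtype

    def __repr__(self):
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"

    def numpy(self) -> np.ndarray:
        return self.data

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def item(self) -> float:
        return float(self.data)

    # -- autodiff core --------------------------------------------------------

    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._prev:
                if p.requires_grad and id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.asarray(grad, dtype=self.data.dtype)
        for node in reversed(topo):
            if node._backward is None or node.grad is None:
                continue
            for parent, pgrad in node._backward(node.grad):
                if not parent.requires_grad or pgrad is None:
                    continue
                pgrad = pgrad.astype(parent.data.dtype, copy=False)
                if parent.grad is None:
                    parent.grad = pgrad.copy() if pgrad.base is not None else pgrad
                else:
                    parent.grad = parent.grad + pgrad

    def zero_grad(self) -> None:
        self.grad = None

    # -- arithmetic -----------------------------------------------------------

    @staticmethod
    def _coerce(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    def __add__(self, other):
        other = Tensor._coerce(other)
        out_data = self.data + other.data

        def backward(g):
            return (
                (self, _unbroadcast(g, self.shape)),
                (other, _unbroadcast(g, other.shape)),
            )

        return Tensor._make(out_data, (self, other), backward)

    __radd__ = __add__

    def __mul__(self, other):
        other = Tensor._coerce(other)
        out_data = self.data * other.data

        def backward(g):
            return (
                (self, _unbroadcast(g * other.data, self.shape)),
                (other, _unbroadcast(g * self.data, other.shape)),
            )

        return Tensor._make(out_data, (self, other), backward)

    __rmul__ = __mul__

    def __neg__(self):
        def backward(g):
            return ((self, -g),)

        return Tensor._make(-self.data, (self,), backward)

    def __sub__(self, other):
        other = Tensor._coerce(other)
        out_data = self.data - other.data

        def backward(g):
            return (
                (self, _unbroadcast(g, self.shape)),
                (other, _unbroadcast(-g, other.shape)),
            )

        return Tensor._make(out_data, (self, other), backward)

    def __rsub__(self, other):
        return Tensor._coerce(other) - self

    def __truediv__(self, other):
        other = Tensor._coerce(other)
        out_data = self.data / other.data

        def backward(g):
            return (
                (self, _unbroadcast(g / other.data, self.shape)),
                (other, _unbroadcast(-g * self.data / (other.data**2), other.shape)),
            )

        return Tensor._make(out_data, (self, other), backward)

    def __rtruediv__(self, other):
        return Tensor._coerce(other) / self

    def __pow__(self, p: float):
        assert np.isscalar(p)
        out_data = self.data**p

        def backward(g):
            return ((self, g * p * self.data ** (p - 1)),)

        return Tensor._make(out_data, (self,), backward)

    def __matmul__(self, other):
        return matmul(self, other)

    # -- reductions -----------------------------------------------------------

    def sum(self, axis=None, keepdims: bool = False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def backward(g):
            if axis is None:
                grad = np.broadcast_to(g, self.shape)
            else:
                axes = (axis,) if np.isscalar(axis) else tuple(axis)
                gg = g if keepdims else np.expand_dims(g, axes)
                grad = np.broadcast_to(gg, self.shape)
            return ((self, grad),)

        return Tensor._make(out_data, (self,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.size if axis is None else np.prod(
            [self.shape[a] for a in ((axis,) if np.isscalar(axis) else axis)]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def max(self, axis: int | None = None, keepdims: bool = False):
        if axis is None:
            flat = self.reshape((self.size,))
            out = flat.max(axis=0)
            return out if not keepdims else out.reshape((1,) * self.ndim)
        out_data = self.data.max(axis=axis, keepdims=keepdims)
        arg = np.argmax(self.data, axis=axis)

        def backward(g):
            # ties route the full gradient to the first argmax, matching np.argmax
            grad = np.zeros_like(self.data)
            gg = g if keepdims else np.expand_dims(g, axis)
            np.put_along_axis(grad, np.expand_dims(arg, axis), gg, axis)
            return ((self, grad),)

        return Tensor._make(out_data, (self,), backward)

    # -- shaping --------------------------------------------------------------

    def reshape(self, shape):
        out_data = self.data.reshape(shape)
        orig = self.shape

        def backward(g):
            return ((self, g.reshape(orig)),)

        return Tensor._make(out_data, (self,), backward)

    def transpose(self, axes):
        out_data = self.data.transpose(axes)
        inv = np.argsort(axes)

        def backward(g):
            return ((self, g.transpose(inv)),)

        return Tensor._make(out_data, (self,), backward)

    def swapaxes(self, a: int, b: int):
        axes = list(range(self.ndim))
        axes[a], axes[b] = axes[b], axes[a]
        return self.transpose(tuple(axes))

    def __getitem__(self, key):
        out_data = self.data[key]

        def backward(g):
            grad = np.zeros_like(self.data)
            np.add.at(grad, key, g)
            return ((self, grad),)

        return Tensor._make(out_data, (self,), backward)


# -- free functions -----------------------------------------------------------


def matmul(a: Tensor, b: Tensor) -> Tensor:
    a, b = Tensor._coerce(a), Tensor._coerce(b)
    out_data = a.data @ b.data

    def backward(g):
        if a.ndim == 1 and b.ndim == 1:
            return ((a, g * b.data), (b, g * a.data))
        if b.ndim == 1:
            ga = np.expand_dims(g, -1) * b.data
            gb = _unbroadcast(
                (np.expand_dims(g, -1) * a.data).reshape(-1, a.shape[-1]).sum(0)
                if a.ndim > 2
                else g @ a.data,
                b.shape,
            )
            return ((a, _unbroadcast(ga, a.shape)), (b, gb))
        if a.ndim == 1:
            ga = _unbroadcast((b.data * np.expand_dims(g, -2)).sum(-1), a.shape)
            gb = _unbroadcast(np.expand_dims(a.data, -1) * np.expand_dims(g, -2), b.shape)
            return ((a, ga), (b, gb))
        ga = _unbroadcast(g @ np.swapaxes(b.data, -1, -2), a.shape)
        gb = _unbroadcast(np.swapaxes(a.data, -1, -2) @ g, b.shape)
        return ((a, ga), (b, gb))

    return Tensor._make(out_data, (a, b), backward)


def _elementwise(x: Tensor, fwd, dfdx) -> Tensor:
    x = Tensor._coerce(x)
    out_data = fwd(x.data)

    def backward(g):
        return ((x, g * dfdx(x.data, out_data)),)

    return Tensor._make(out_data, (x,), backward)


def exp(x: Tensor) -> Tensor:
    return _elementwise(x, np.exp, lambda d, o: o)


def log(x: Tensor) -> Tensor:
    return _elementwise(x, np.log, lambda d, o: 1.0 / d)


def sqrt(x: Tensor) -> Tensor:
    return _elementwise(x, np.sqrt, lambda d, o: 0.5 / o)


def sigmoid(x: Tensor) -> Tensor:
    def fwd(d):
        out = np.empty_like(d)
        pos = d >= 0
        out[pos] = 1.0 / (1.0 + np.exp(-d[pos]))
        e = np.exp(d[~pos])
        out[~pos] = e / (1.0 + e)
        return out

    return _elementwise(x, fwd, lambda d, o: o * (1.0 - o))


def tanh(x: Tensor) -> Tensor:
    return _elementwise(x, np.tanh, lambda d, o: 1.0 - o**2)


def relu(x: Tensor) -> Tensor:
    return _elementwise(x, lambda d: np.maximum(d, 0), lambda d, o: (d > 0).astype(d.dtype))


def leaky_relu(x: Tensor, slope: float = 0.2) -> Tensor:
    return _elementwise(
        x,
        lambda d: np.where(d >= 0, d, slope * d),
        lambda d, o: np.where(d >= 0, 1.0, slope).astype(d.dtype),
    )


def clip_max(x: Tensor, hi: float) -> Tensor:
    """min(x, hi); gradient is 1 where x < hi and 0 where clipped."""
    return _elementwise(
        x,
        lambda d: np.minimum(d, hi),
        lambda d, o: (d < hi).astype(d.dtype),
    )


def maximum(a: Tensor, b: Tensor) -> Tensor:
    a, b = Tensor._coerce(a), Tensor._coerce(b)
    out_data = np.maximum(a.data, b.data)

    def backward(g):
        mask = (a.data >= b.data).astype(g.dtype)
        return (
            (a, _unbroadcast(g * mask, a.shape)),
            (b, _unbroadcast(g * (1.0 - mask), b.shape)),
        )

    return Tensor._make(out_data, (a, b), backward)


def concatenate(tensors: Iterable[Tensor], axis: int = 0) -> Tensor:
    tensors = [Tensor._coerce(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        pieces = np.split(g, splits, axis=axis)
        return tuple(zip(tensors, pieces))

    return Tensor._make(out_data, tuple(tensors), backward)


def take_flat(x: Tensor, idx: np.ndarray) -> Tensor:
    """Gather ``x.ravel()[idx]``; the backward pass scatter-adds.

    ``idx`` may have any shape; the output has ``idx.shape``.  This is the
    workhorse behind im2col convolution and patch extraction.
    """
    x = Tensor._coerce(x)
    flat = x.data.reshape(-1)
    out_data = flat[idx]
    n = flat.size

    def backward(g):
        acc = np.bincount(idx.reshape(-1), weights=g.reshape(-1).astype(np.float64), minlength=n)
        return ((x, acc.reshape(x.shape)),)

    return Tensor._make(out_data, (x,), backward)


def scatter_add_flat(x: Tensor, idx: np.ndarray, size: int) -> Tensor:
    """Flat scatter-add: out[k] = sum of x at positions where idx == k.

    Inverse-adjoint of :func:`take_flat`; used to reassemble overlapping
    patches into a feature map (followed by division by the coverage count).
    """
    x = Tensor._coerce(x)
    out_data = np.bincount(
        idx.reshape(-1), weights=x.data.reshape(-1).astype(np.float64), minlength=size
    ).astype(x.dtype)

    def backward(g):
        return ((x, g.reshape(-1)[idx.reshape(-1)].reshape(x.shape)),)

    return Tensor._make(out_data, (x,), backward)


def pad_nd(x: Tensor, widths: Sequence[tuple], value: float = 0.0) -> Tensor:
    """Constant-pad with per-axis (before, after) widths."""
    x = Tensor._coerce(x)
    out_data = np.pad(x.data, widths, constant_values=value)
    slices = tuple(slice(b, b + s) for (b, _), s in zip(widths, x.shape))

    def backward(g):
        return ((x, g[slices]),)

    return Tensor._make(out_data, (x,), backward)
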