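"""Reverse-mode automatic differentiation over numpy arrays.

A deliberately small tape-based engine: every :class:`Tensor` wraps a float64
numpy array; operations record a backward closure, and :meth:`Tensor.backward`
runs the tape in reverse topological order.  It supports exactly the operator
set the narrow-band losses and the encoder–decoder networks need —
broadcast-aware arithmetic, elementwise transcendentals, reductions, slicing,
axis gathers (used for replicate padding and shifts), concatenation and
interleaving (used by the bilinear up-sampler).

Convolution, pooling and normalization live in :mod:`nbac.nn`; they are built
from these primitives plus two dedicated ops defined there.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np

__all__ = ["Tensor", "as_tensor", "maximum", "concatenate", "interleave"]


class Tensor:
    """An array node on the autodiff tape."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    # make numpy defer to the reflected operators below
    __array_ufunc__ = None

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = bool(requires_grad)
        self.grad: np.ndarray | None = None
        self._backward = None
        self._parents: tuple[Tensor, ...] = ()

    # ---- basic introspection -------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def size(self):
        return self.data.size

    def item(self) -> float:
        return float(self.data)

    def __float__(self) -> float:
        return float(self.data)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    def zero_grad(self) -> None:
        self.grad = None

    # ---- autograd core --------------------------------------------------
    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def backward(self, grad: np.ndarray | None = None) -> None:
        """Backpropagate from this node (default seed: ones)."""
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        if grad is None:
            grad = np.ones_like(self.data)
        self._accumulate(np.asarray(grad, dtype=np.float64))
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad)

    # ---- arithmetic ------------------------------------------------------
    def __add__(self, other):
        return _binary(self, other, np.add, lambda a, b, g: (g, g))

    __radd__ = __add__

    def __sub__(self, other):
        return _binary(self, other, np.subtract, lambda a, b, g: (g, -g))

    def __rsub__(self, other):
        return as_tensor(other) - self

    def __mul__(self, other):
        return _binary(self, other, np.multiply, lambda a, b, g: (g * b, g * a))

    __rmul__ = __mul__

    def __truediv__(self, other):
        return _binary(
            self, other, np.divide, lambda a, b, g: (g / b, -g * a / (b * b))
        )

    def __rtruediv__(self, other):
        return as_tensor(other) / self

    def __neg__(self):
        return _unary(self, -self.data, lambda g: -g)

    def __pow__(self, exponent: float):
        p = float(exponent)
        out = self.data**p
        if p == 0:
            return _unary(self, out, lambda g: np.zeros_like(g))
        base = self.data

        def grad_fn(g):
            with np.errstate(divide="ignore", invalid="ignore"):
                d = p * base ** (p - 1)
            return g * np.where(np.isfinite(d), d, 0.0)

        return _unary(self, out, grad_fn)

    # ---- elementwise -----------------------------------------------------
    def log(self):
        return _unary(self, np.log(self.data), lambda g: g / self.data)

    def exp(self):
        out = np.exp(self.data)
        return _unary(self, out, lambda g: g * out)

    def sqrt(self):
        """Square root with a zero subgradient at 0 (keeps edge maps finite)."""
        out = np.sqrt(self.data)

        def grad_fn(g):
            with np.errstate(divide="ignore"):
                d = 0.5 / out
            return g * np.where(out > 0, d, 0.0)

        return _unary(self, out, grad_fn)

    def arctan(self):
        return _unary(
            self, np.arctan(self.data), lambda g: g / (1.0 + self.data**2)
        )

    def abs(self):
        return _unary(self, np.abs(self.data), lambda g: g * np.sign(self.data))

    def relu(self):
        mask = self.data > 0
        return _unary(self, self.data * mask, lambda g: g * mask)

    def leaky_relu(self, alpha: float = 0.01):
        mask = self.data > 0
        slope = np.where(mask, 1.0, alpha)
        return _unary(self, self.data * slope, lambda g: g * slope)

    def clip(self, lo: float, hi: float):
        """Clamp; gradient is passed only where the input is strictly inside."""
        inside = (self.data > lo) & (self.data < hi)
        return _unary(self, np.clip(self.data, lo, hi), lambda g: g * inside)

    # ---- reductions ------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out = self.data.sum(axis=axis, keepdims=keepdims)
        shape, nd = self.data.shape, self.data.ndim
        axes = _norm_axes(axis, nd)

        def grad_fn(g):
            g = np.asarray(g)
            if not keepdims and axes is not None:
                g = np.expand_dims(g, tuple(axes))
            return np.broadcast_to(g, shape).copy()

        return _unary(self, out, grad_fn)

    def mean(self, axis=None, keepdims: bool = False):
        axes = _norm_axes(axis, self.data.ndim)
        if axes is None:
            n = self.data.size
        else:
            n = int(np.prod([self.data.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) / n

    # ---- shape ops -------------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old = self.data.shape
        return _unary(self, self.data.reshape(shape), lambda g: g.reshape(old))

    def moveaxis(self, src, dst):
        return _unary(
            self, np.moveaxis(self.data, src, dst), lambda g: np.moveaxis(g, dst, src)
        )

    def __getitem__(self, idx):
        out = self.data[idx]
        shape = self.data.shape

        def grad_fn(g):
            full = np.zeros(shape, dtype=np.float64)
            full[idx] = g
            return full

        return _unary(self, out, grad_fn)

    def take(self, indices, axis: int):
        """Gather along one axis (indices may repeat; backward scatters-adds)."""
        indices = np.asarray(indices, dtype=np.intp)
        out = np.take(self.data, indices, axis=axis)
        shape = self.data.shape

        def grad_fn(g):
            full = np.zeros(shape, dtype=np.float64)
            sl: list = [slice(None)] * len(shape)
            # scatter-add via np.add.at on the gather axis
            idx_obj = [slice(None)] * len(shape)
            idx_obj[axis] = indices
            np.add.at(full, tuple(idx_obj), g)
            return full

        return _unary(self, out, grad_fn)


# ---------------------------------------------------------------------------
# constructors and free functions
# ---------------------------------------------------------------------------


def as_tensor(x, requires_grad: bool = False) -> Tensor:
    if isinstance(x, Tensor):
        return x
    return Tensor(x, requires_grad=requires_grad)


def _norm_axes(axis, ndim):
    if axis is None:
        return None
    if isinstance(axis, int):
        axis = (axis,)
    return tuple(a % ndim for a in axis)


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum a gradient down to ``shape`` (adjoint of numpy broadcasting)."""
    g = grad
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for i, s in enumerate(shape):
        if s == 1 and g.shape[i] != 1:
            g = g.sum(axis=i, keepdims=True)
    return g


def _make(data, parents: Sequence[Tensor], backward):
    req = any(p.requires_grad for p in parents)
    out = Tensor(data, requires_grad=req)
    if req:
        out._parents = tuple(parents)
        out._backward = backward
    return out


def _unary(x: Tensor, data, grad_fn):
    def backward(g):
        if x.requires_grad:
            x._accumulate(grad_fn(g))

    return _make(data, (x,), backward)


def _binary(a, b, fwd, grads):
    a, b = as_tensor(a), as_tensor(b)
    data = fwd(a.data, b.data)

    def backward(g):
        ga, gb = grads(a.data, b.data, g)
        if a.requires_grad:
            a._accumulate(_unbroadcast(ga, a.data.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(gb, b.data.shape))

    return _make(data, (a, b), backward)


def maximum(a, b) -> Tensor:
    """Elementwise maximum; ties split the gradient equally."""
    a, b = as_tensor(a), as_tensor(b)
    data = np.maximum(a.data, b.data)

    def backward(g):
        wa = np.where(a.data > b.data, 1.0, np.where(a.data == b.data, 0.5, 0.0))
        if a.requires_grad:
            a._accumulate(_unbroadcast(g * wa, a.data.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(g * (1.0 - wa), b.data.shape))

    return _make(data, (a, b), backward)


def concatenate(tensors: Iterable[Tensor], axis: int = 0) -> Tensor:
    ts = [as_tensor(t) for t in tensors]
    data = np.concatenate([t.data for t in ts], axis=axis)
    sizes = [t.data.shape[axis] for t in ts]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        parts = np.split(g, splits, axis=axis)
        for t, p in zip(ts, parts):
            if t.requires_grad:
                t._accumulate(p)

    return _make(data, ts, backward)


def interleave(a: Tensor, b: Tensor, axis: int) -> Tensor:
    """Alternate slices of ``a`` and ``b`` along ``axis`` (a first).

    Output length along ``axis`` is ``2n``; used by the ×2 bilinear up-sampler.
    """
    a, b = as_tensor(a), as_tensor(b)
    if a.data.shape != b.data.shape:
        raise ValueError("interleave operands must share a shape")
    shape = list(a.data.shape)
    shape[axis] *= 2
    data = np.empty(shape, dtype=np.float64)
    sl_a = [slice(None)] * len(shape)
    sl_b = [slice(None)] * len(shape)
    sl_a[axis] = slice(0, None, 2)
    sl_b[axis] = slice(1, None, 2)
    data[tuple(sl_a)] = a.data
    data[tuple(sl_b)] = b.data

    def backward(g):
        if a.requires_grad:
            a._accumulate(g[tuple(sl_a)])
        if b.requires_grad:
            b._accumulate(g[tuple(sl_b)])

    return _make(data, (a, b), backward)
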