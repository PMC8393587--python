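"""Neural-network layers and optimization on top of :mod:`nbac.autodiff`.

Implements exactly what the two-branch encoder–decoder backbones need:
N-d convolution (2D and 3D spatial), batch/instance normalization, ReLU /
leaky-ReLU, 2× max pooling, 2× bilinear up-sampling, and the Adam optimizer.
Layers follow the familiar ``Module`` idiom (parameters collected
recursively, ``train()``/``eval()`` modes, ``state_dict`` round-trip).
"""

from __future__ import annotations

from typing import Iterator

import numpy as np

from .autodiff import Tensor, _make, interleave

__all__ = [
    "Module",
    "Sequential",
    "Conv",
    "BatchNorm",
    "InstanceNorm",
    "ReLU",
    "LeakyReLU",
    "MaxPool",
    "UpsampleBilinear",
    "Adam",
    "conv_nd",
    "max_pool",
    "upsample_bilinear",
]


# ---------------------------------------------------------------------------
# functional ops
# ---------------------------------------------------------------------------


def _pad_same(x: np.ndarray, k: tuple) -> np.ndarray:
    pads = [(0, 0), (0, 0)] + [((kk - 1) // 2, (kk - 1) // 2) for kk in k]
    return np.pad(x, pads)


def _conv_forward(x: np.ndarray, w: np.ndarray, nd: int) -> tuple[np.ndarray, np.ndarray]:
    """'Same' stride-1 cross-correlation: x (N,Cin,*sp), w (Cout,Cin,*k).

    Accumulated offset by offset — each kernel tap is one small channel
    contraction — which avoids materializing an im2col buffer.
    """
    k = w.shape[2:]
    xp = _pad_same(x, k)
    out_sp = x.shape[2:]
    out = None
    for off in np.ndindex(*k):
        sl = tuple(slice(o, o + s) for o, s in zip(off, out_sp))
        xs = xp[(slice(None), slice(None)) + sl]  # (N, Cin, *sp)
        term = np.tensordot(xs, w[(Ellipsis,) + off], axes=([1], [1]))
        out = term if out is None else out + term
    # out: (N, *sp, Cout) -> (N, Cout, *sp)
    return np.ascontiguousarray(np.moveaxis(out, -1, 1)), xp


def conv_nd(x: Tensor, w: Tensor, b: Tensor | None, nd: int) -> Tensor:
    """Stride-1 'same' convolution with odd kernels, as an autodiff op."""
    out, xp = _conv_forward(x.data, w.data, nd)
    if b is not None:
        out = out + b.data.reshape((1, -1) + (1,) * nd)
    sp_axes = list(range(2, 2 + nd))
    k = w.data.shape[2:]
    out_sp = x.data.shape[2:]

    def backward(g):
        if b is not None and b.requires_grad:
            b._accumulate(g.sum(axis=tuple([0] + sp_axes)))
        if w.requires_grad:
            gw = np.empty_like(w.data)
            for off in np.ndindex(*k):
                sl = tuple(slice(o, o + s) for o, s in zip(off, out_sp))
                xs = xp[(slice(None), slice(None)) + sl]
                gw[(Ellipsis,) + off] = np.tensordot(
                    g, xs, axes=([0] + sp_axes, [0] + sp_axes)
                )
            w._accumulate(gw)
        if x.requires_grad:
            wt = np.swapaxes(w.data, 0, 1)  # (Cin, Cout, *k)
            wt = np.flip(wt, axis=tuple(range(2, 2 + nd)))
            gx, _ = _conv_forward(g, wt, nd)
            x._accumulate(gx)

    parents = (x, w) if b is None else (x, w, b)
    return _make(out, parents, backward)


def max_pool(x: Tensor, nd: int, size: int = 2) -> Tensor:
    """Non-overlapping window maximum (ties share the gradient equally)."""
    shape = x.data.shape
    for s in shape[2:]:
        if s % size:
            raise ValueError(f"spatial size {s} not divisible by pool size {size}")
    view_shape = shape[:2] + sum(((s // size, size) for s in shape[2:]), ())
    xv = x.data.reshape(view_shape)
    red_axes = tuple(3 + 2 * i for i in range(nd))
    out = xv.max(axis=red_axes)

    def backward(g):
        if not x.requires_grad:
            return
        out_e = np.expand_dims(out, red_axes)
        g_e = np.expand_dims(g, red_axes)
        mask = (xv == out_e).astype(np.float64)
        mask /= mask.sum(axis=red_axes, keepdims=True)
        x._accumulate((g_e * mask).reshape(shape))

    return _make(out, (x,), backward)


def _upsample_axis(x: Tensor, axis: int) -> Tensor:
    n = x.shape[axis]
    prev = np.clip(np.arange(n) - 1, 0, n - 1)
    nxt = np.clip(np.arange(n) + 1, 0, n - 1)
    lo = 0.75 * x + 0.25 * x.take(prev, axis=axis)
    hi = 0.75 * x + 0.25 * x.take(nxt, axis=axis)
    return interleave(lo, hi, axis=axis)


def upsample_bilinear(x: Tensor, nd: int) -> Tensor:
    """×2 bilinear up-sampling (edge-replicated, half-pixel aligned)."""
    out = x
    for a in range(x.ndim - nd, x.ndim):
        out = _upsample_axis(out, a)
    return out


# ---------------------------------------------------------------------------
# modules
# ---------------------------------------------------------------------------


class Module:
    """Base class: recursive parameter collection and train/eval switching."""

    def __init__(self):
        self.training = True

    def forward(self, x):  # pragma: no cover - abstract
        raise NotImplementedError

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)

    def children(self) -> Iterator["Module"]:
        for v in self.__dict__.values():
            if isinstance(v, Module):
                yield v
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        yield item

    def parameters(self) -> list[Tensor]:
        params = []
        for v in self.__dict__.values():
            if isinstance(v, Tensor) and v.requires_grad:
                params.append(v)
        for child in self.children():
            params.extend(child.parameters())
        return params

    def named_state(self, prefix: str = "") -> dict[str, np.ndarray]:
        state: dict[str, np.ndarray] = {}
        for name, v in self.__dict__.items():
            key = f"{prefix}{name}"
            if isinstance(v, Tensor):
                state[key] = v.data
            elif isinstance(v, np.ndarray):
                state[key] = v
            elif isinstance(v, Module):
                state.update(v.named_state(f"{key}."))
            elif isinstance(v, (list, tuple)):
                for i, item in enumerate(v):
                    if isinstance(item, Module):
                        state.update(item.named_state(f"{key}.{i}."))
        return state

    def load_state(self, state: dict[str, np.ndarray], prefix: str = "") -> None:
        for name, v in self.__dict__.items():
            key = f"{prefix}{name}"
            if isinstance(v, Tensor):
                v.data = np.asarray(state[key], dtype=np.float64).reshape(v.data.shape)
            elif isinstance(v, np.ndarray):
                self.__dict__[name] = np.asarray(state[key], dtype=np.float64)
            elif isinstance(v, Module):
                v.load_state(state, f"{key}.")
            elif isinstance(v, (list, tuple)):
                for i, item in enumerate(v):
                    if isinstance(item, Module):
                        item.load_state(state, f"{key}.{i}.")

    def train(self) -> "Module":
        self.training = True
        for c in self.children():
            c.train()
        return self

    def eval(self) -> "Module":
        self.training = False
        for c in self.children():
            c.eval()
        return self

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.zero_grad()


class Sequential(Module):
    def __init__(self, *layers: Module):
        super().__init__()
        self.layers = list(layers)

    def forward(self, x):
        for layer in self.layers:
            x = layer(x)
        return x


class Conv(Module):
    """Stride-1 'same' convolution with He-normal initialization."""

    def __init__(self, in_ch: int, out_ch: int, kernel: int, nd: int, rng: np.random.Generator):
        super().__init__()
        self.nd = nd
        fan_in = in_ch * kernel**nd
        std = np.sqrt(2.0 / fan_in)
        shape = (out_ch, in_ch) + (kernel,) * nd
        self.weight = Tensor(rng.normal(0.0, std, size=shape), requires_grad=True)
        self.bias = Tensor(np.zeros(out_ch), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        return conv_nd(x, self.weight, self.bias, self.nd)


class _Norm(Module):
    def __init__(self, channels: int, nd: int, eps: float = 1e-5):
        super().__init__()
        self.nd = nd
        self.eps = eps
        shape = (1, channels) + (1,) * nd
        self.gamma = Tensor(np.ones(shape), requires_grad=True)
        self.beta = Tensor(np.zeros(shape), requires_grad=True)


class BatchNorm(_Norm):
    """Batch normalization over (batch, spatial); running stats for eval."""

    def __init__(self, channels: int, nd: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__(channels, nd, eps)
        self.momentum = momentum
        self.running_mean = np.zeros((1, channels) + (1,) * nd)
        self.running_var = np.ones((1, channels) + (1,) * nd)

    def forward(self, x: Tensor) -> Tensor:
        axes = tuple([0] + list(range(2, 2 + self.nd)))
        if self.training:
            mean = x.mean(axis=axes, keepdims=True)
            var = ((x - mean) * (x - mean)).mean(axis=axes, keepdims=True)
            self.running_mean = (
                (1 - self.momentum) * self.running_mean + self.momentum * mean.data
            )
            self.running_var = (
                (1 - self.momentum) * self.running_var + self.momentum * var.data
            )
        else:
            mean, var = Tensor(self.running_mean), Tensor(self.running_var)
        xhat = (x - mean) / ((var + self.eps).sqrt())
        return xhat * self.gamma + self.beta


class InstanceNorm(_Norm):
    """Per-sample, per-channel normalization over spatial axes."""

    def forward(self, x: Tensor) -> Tensor:
        axes = tuple(range(2, 2 + self.nd))
        mean = x.mean(axis=axes, keepdims=True)
        var = ((x - mean) * (x - mean)).mean(axis=axes, keepdims=True)
        xhat = (x - mean) / ((var + self.eps).sqrt())
        return xhat * self.gamma + self.beta


class ReLU(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.relu()


class LeakyReLU(Module):
    def __init__(self, alpha: float = 0.01):
        super().__init__()
        self.alpha = alpha

    def forward(self, x: Tensor) -> Tensor:
        return x.leaky_relu(self.alpha)


class MaxPool(Module):
    def __init__(self, nd: int, size: int = 2):
        super().__init__()
        self.nd = nd
        self.size = size

    def forward(self, x: Tensor) -> Tensor:
        return max_pool(x, self.nd, self.size)


class UpsampleBilinear(Module):
    def __init__(self, nd: int):
        super().__init__()
        self.nd = nd

    def forward(self, x: Tensor) -> Tensor:
        return upsample_bilinear(x, self.nd)


# ---------------------------------------------------------------------------
# optimizer
# ---------------------------------------------------------------------------


class Adam:
    """Adam with optional L2 weight decay (added to the gradient)."""

    def __init__(
        self,
        params: list[Tensor],
        lr: float = 1e-2,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
        weight_decay: float = 0.0,
    ):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()
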