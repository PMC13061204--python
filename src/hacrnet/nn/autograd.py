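"""Reverse-mode automatic differentiation on numpy arrays.

A deliberately small tape-based engine: each :class:`Tensor` records the
operation that produced it and a closure that pushes gradients to its
parents.  ``backward()`` on a scalar runs the tape in reverse topological
order.  Only the operations needed by the super-resolution network are
implemented (convolution, PReLU, sigmoid, pooling, pixel shuffle,
element-wise arithmetic with broadcasting, concatenation, reductions).

All convolutions are stride-1 with zero padding; the heavy lifting is an
im2col matrix multiply so throughput is bounded by BLAS, not Python loops.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Tensor",
    "no_grad",
    "add",
    "mul",
    "sub",
    "concat",
    "sigmoid",
    "prelu",
    "conv2d",
    "global_avg_pool",
    "pixel_shuffle",
    "mean_abs",
    "mean_sq",
]


class Tensor:
    """An ndarray plus an optional gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data)
        if self.data.dtype.kind != "f":
            self.data = self.data.astype(np.float32)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._parents: tuple[Tensor, ...] = ()

    # -- construction helpers -------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def dtype(self):
        return self.data.dtype

    def zero_grad(self) -> None:
        self.grad = None

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # -- autograd core --------------------------------------------------------
    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = g.astype(self.data.dtype, copy=True)
        else:
            self.grad += g

    def backward(self) -> None:
        """Backpropagate from a scalar tensor through the recorded tape."""
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar tensor")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative DFS; deep graphs overflow recursion limits
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- operator sugar -------------------------------------------------------
    def __add__(self, other):
        return add(self, _as_tensor(other))

    def __radd__(self, other):
        return add(_as_tensor(other), self)

    def __sub__(self, other):
        return sub(self, _as_tensor(other))

    def __mul__(self, other):
        return mul(self, _as_tensor(other))

    def __rmul__(self, other):
        return mul(_as_tensor(other), self)


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


_GRAD_ENABLED = True


class no_grad:
    """Context manager disabling tape recording (inference mode).

    Without it every convolution would keep its im2col buffer alive for the
    backward pass, which at full slice resolution costs gigabytes.
    """

    def __enter__(self):
        global _GRAD_ENABLED
        self._prev = _GRAD_ENABLED
        _GRAD_ENABLED = False
        return self

    def __exit__(self, *exc):
        global _GRAD_ENABLED
        _GRAD_ENABLED = self._prev
        return False


def _needs_grad(*ts: Tensor) -> bool:
    return _GRAD_ENABLED and any(t.requires_grad or t._parents for t in ts)


def _make(data: np.ndarray, parents: Iterable[Tensor], backward) -> Tensor:
    parents = tuple(parents)
    out = Tensor(data)
    if _needs_grad(*parents):
        out._parents = parents
        out._backward = backward
    return out


def _unbroadcast(g: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum gradient ``g`` down to ``shape`` (inverse of numpy broadcasting)."""
    if g.shape == shape:
        return g
    extra = g.ndim - len(shape)
    if extra:
        g = g.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and g.shape[i] != 1)
    if axes:
        g = g.sum(axis=axes, keepdims=True)
    return g


# -- elementwise ---------------------------------------------------------------

def add(a: Tensor, b: Tensor) -> Tensor:
    data = a.data + b.data

    def backward(g):
        a._accumulate(_unbroadcast(g, a.data.shape))
        b._accumulate(_unbroadcast(g, b.data.shape))

    return _make(data, (a, b), backward)


def sub(a: Tensor, b: Tensor) -> Tensor:
    data = a.data - b.data

    def backward(g):
        a._accumulate(_unbroadcast(g, a.data.shape))
        b._accumulate(-_unbroadcast(g, b.data.shape))

    return _make(data, (a, b), backward)


def mul(a: Tensor, b: Tensor) -> Tensor:
    data = a.data * b.data

    def backward(g):
        a._accumulate(_unbroadcast(g * b.data, a.data.shape))
        b._accumulate(_unbroadcast(g * a.data, b.data.shape))

    return _make(data, (a, b), backward)


def sigmoid(x: Tensor) -> Tensor:
    # numerically stable logistic
    d = x.data
    out = np.empty_like(d)
    pos = d >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-d[pos]))
    ex = np.exp(d[~pos])
    out[~pos] = ex / (1.0 + ex)

    def backward(g):
        x._accumulate(g * out * (1.0 - out))

    return _make(out, (x,), backward)


def prelu(x: Tensor, slope: Tensor) -> Tensor:
    """PReLU with per-channel slopes; ``slope`` has shape (C,), x is B×C×H×W
    (or B×C×1×1 for pooled descriptors)."""
    s = slope.data.reshape(1, -1, *([1] * (x.data.ndim - 2)))
    neg = x.data < 0
    data = np.where(neg, s * x.data, x.data)

    def backward(g):
        gx = np.where(neg, s, 1.0) * g
        x._accumulate(gx)
        gs = np.where(neg, x.data, 0.0) * g
        axes = (0,) + tuple(range(2, x.data.ndim))
        slope._accumulate(gs.sum(axis=axes).reshape(slope.data.shape))

    return _make(data, (x, slope), backward)


# -- structural ----------------------------------------------------------------

def concat(tensors: Sequence[Tensor], axis: int = 1) -> Tensor:
    data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            t._accumulate(piece)

    return _make(data, tensors, backward)


def global_avg_pool(x: Tensor) -> Tensor:
    """Spatial mean per channel: B×C×H×W → B×C×1×1."""
    b, c, h, w = x.data.shape
    data = x.data.mean(axis=(2, 3), keepdims=True)

    def backward(g):
        x._accumulate(np.broadcast_to(g / (h * w), x.data.shape).copy())

    return _make(data, (x,), backward)


def pixel_shuffle(x: Tensor, r: int) -> Tensor:
    """Rearrange B×(C·r²)×H×W → B×C×rH×rW, sub-pixel blocks row-major."""
    b, crr, h, w = x.data.shape
    if crr % (r * r):
        raise ValueError(f"channel count {crr} not divisible by r^2={r * r}")
    c = crr // (r * r)
    data = (
        x.data.reshape(b, c, r, r, h, w)
        .transpose(0, 1, 4, 2, 5, 3)
        .reshape(b, c, h * r, w * r)
    )

    def backward(g):
        gx = (
            g.reshape(b, c, h, r, w, r)
            .transpose(0, 1, 3, 5, 2, 4)
            .reshape(b, crr, h, w)
        )
        x._accumulate(gx)

    return _make(data, (x,), backward)


# -- convolution ---------------------------------------------------------------

def conv2d(x: Tensor, weight: Tensor, bias: Tensor | None, padding: int) -> Tensor:
    """Stride-1 2-D cross-correlation with zero padding.

    x: B×Cin×H×W, weight: Cout×Cin×kh×kw, bias: (Cout,) or None.
    """
    b, cin, h, w = x.data.shape
    cout, cin_w, kh, kw = weight.data.shape
    if cin != cin_w:
        raise ValueError(f"input has {cin} channels, weight expects {cin_w}")
    p = padding
    xp = np.pad(x.data, ((0, 0), (0, 0), (p, p), (p, p))) if p else x.data
    ho, wo = xp.shape[2] - kh + 1, xp.shape[3] - kw + 1
    # cols: (B, Ho, Wo, Cin*kh*kw)
    win = sliding_window_view(xp, (kh, kw), axis=(2, 3))
    cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(b * ho * wo, cin * kh * kw)
    wmat = weight.data.reshape(cout, -1)
    out = cols @ wmat.T
    if bias is not None:
        out += bias.data
    data = out.reshape(b, ho, wo, cout).transpose(0, 3, 1, 2)

    def backward(g):
        gmat = g.transpose(0, 2, 3, 1).reshape(b * ho * wo, cout)
        weight._accumulate((gmat.T @ cols).reshape(weight.data.shape))
        if bias is not None:
            bias._accumulate(gmat.sum(axis=0))
        gcols = gmat @ wmat  # (B*Ho*Wo, Cin*kh*kw)
        gcols = gcols.reshape(b, ho, wo, cin, kh, kw).transpose(0, 3, 4, 5, 1, 2)
        gxp = np.zeros((b, cin, h + 2 * p, w + 2 * p), dtype=g.dtype)
        for i in range(kh):
            for j in range(kw):
                gxp[:, :, i : i + ho, j : j + wo] += gcols[:, :, i, j]
        x._accumulate(gxp[:, :, p : p + h, p : p + w] if p else gxp)

    parents = (x, weight) if bias is None else (x, weight, bias)
    return _make(data, parents, backward)


# -- reductions ----------------------------------------------------------------

def mean_abs(x: Tensor) -> Tensor:
    """Mean absolute value over all elements (the L1 objective kernel)."""
    data = np.abs(x.data).mean()

    def backward(g):
        x._accumulate(g * np.sign(x.data) / x.data.size)

    return _make(np.asarray(data, dtype=x.data.dtype), (x,), backward)


def mean_sq(x: Tensor) -> Tensor:
    data = np.square(x.data).mean()

    def backward(g):
        x._accumulate(g * 2.0 * x.data / x.data.size)

    return _make(np.asarray(data, dtype=x.data.dtype), (x,), backward)
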