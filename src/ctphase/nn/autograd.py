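"""Reverse-mode automatic differentiation on numpy arrays.

A `Tensor` wraps a float64 ndarray plus an optional gradient; ops build a
DAG whose backward pass runs in reverse topological order.  Only the ops
used by the network are implemented.  Gradients for broadcast operands
are reduced back to the operand's shape.
"""

from __future__ import annotations

from itertools import product

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = bool(requires_grad)
        self.grad: np.ndarray | None = None
        self._parents: tuple[Tensor, ...] = ()
        self._backward = None

    @property
    def shape(self):
        return self.data.shape

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    # graph construction -------------------------------------------------
    @staticmethod
    def _wrap(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def backward(self) -> None:
        """Backpropagate from this (typically scalar) tensor."""
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, done = stack.pop()
            if done:
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

    # operator sugar ------------------------------------------------------
    def __add__(self, other):
        return add(self, self._wrap(other))

    __radd__ = __add__

    def __mul__(self, other):
        return mul(self, self._wrap(other))

    __rmul__ = __mul__

    def __neg__(self):
        return mul(self, Tensor(-1.0))

    def __sub__(self, other):
        return add(self, -self._wrap(other))

    def __rsub__(self, other):
        return add(self._wrap(other), -self)

    def __matmul__(self, other):
        return matmul(self, self._wrap(other))


def _needs(*ts: Tensor) -> bool:
    return any(t.requires_grad for t in ts)


def _node(data: np.ndarray, parents: tuple[Tensor, ...], backward) -> Tensor:
    out = Tensor(data, requires_grad=_needs(*parents))
    if out.requires_grad:
        out._parents = parents
        out._backward = backward
    return out


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum a gradient over axes that were broadcast."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


# ---------------------------------------------------------------------------
# elementwise & linear algebra

def add(a: Tensor, b: Tensor) -> Tensor:
    def bwd(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g, a.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(g, b.shape))

    return _node(a.data + b.data, (a, b), bwd)


def mul(a: Tensor, b: Tensor) -> Tensor:
    def bwd(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g * b.data, a.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(g * a.data, b.shape))

    return _node(a.data * b.data, (a, b), bwd)


def matmul(a: Tensor, b: Tensor) -> Tensor:
    """2D (or batched trailing-2D) matrix product."""

    def bwd(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g @ np.swapaxes(b.data, -1, -2), a.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(np.swapaxes(a.data, -1, -2) @ g, b.shape))

    return _node(a.data @ b.data, (a, b), bwd)


def relu(a: Tensor) -> Tensor:
    mask = a.data > 0

    def bwd(g):
        if a.requires_grad:
            a._accumulate(g * mask)

    return _node(np.where(mask, a.data, 0.0), (a,), bwd)


def exp(a: Tensor) -> Tensor:
    out_data = np.exp(a.data)

    def bwd(g):
        if a.requires_grad:
            a._accumulate(g * out_data)

    return _node(out_data, (a,), bwd)


def log(a: Tensor, eps: float = 0.0) -> Tensor:
    base = a.data + eps

    def bwd(g):
        if a.requires_grad:
            a._accumulate(g / base)

    return _node(np.log(base), (a,), bwd)


def pow_const(a: Tensor, exponent: float) -> Tensor:
    def bwd(g):
        if a.requires_grad:
            a._accumulate(g * exponent * np.power(a.data, exponent - 1.0))

    return _node(np.power(a.data, exponent), (a,), bwd)


def reshape(a: Tensor, shape: tuple[int, ...]) -> Tensor:
    old = a.shape

    def bwd(g):
        if a.requires_grad:
            a._accumulate(g.reshape(old))

    return _node(a.data.reshape(shape), (a,), bwd)


def transpose(a: Tensor, axes: tuple[int, ...]) -> Tensor:
    inv = tuple(np.argsort(axes))

    def bwd(g):
        if a.requires_grad:
            a._accumulate(g.transpose(inv))

    return _node(a.data.transpose(axes), (a,), bwd)


def sum_all(a: Tensor) -> Tensor:
    def bwd(g):
        if a.requires_grad:
            a._accumulate(np.broadcast_to(g, a.shape).copy())

    return _node(a.data.sum(), (a,), bwd)


def mean_axes(a: Tensor, axes: tuple[int, ...]) -> Tensor:
    axes = tuple(axes)
    n = int(np.prod([a.shape[ax] for ax in axes]))

    def bwd(g):
        if a.requires_grad:
            gg = np.expand_dims(g, axes)
            a._accumulate(np.broadcast_to(gg, a.shape) / n)

    return _node(a.data.mean(axis=axes), (a,), bwd)


def softmax(a: Tensor, axis: int = -1) -> Tensor:
    shifted = a.data - a.data.max(axis=axis, keepdims=True)
    e = np.exp(shifted)
    s = e / e.sum(axis=axis, keepdims=True)

    def bwd(g):
        if a.requires_grad:
            dot = (g * s).sum(axis=axis, keepdims=True)
            a._accumulate(s * (g - dot))

    return _node(s, (a,), bwd)


def index0(a: Tensor, i: int) -> Tensor:
    """Select entry ``i`` along axis 0, keeping the axis (shape (1, ...))."""

    def bwd(g):
        if a.requires_grad:
            full = np.zeros_like(a.data)
            full[i : i + 1] = g
            a._accumulate(full)

    return _node(a.data[i : i + 1], (a,), bwd)


def concat0(tensors: list[Tensor]) -> Tensor:
    sizes = [t.shape[0] for t in tensors]
    offs = np.cumsum([0] + sizes)

    def bwd(g):
        for t, lo, hi in zip(tensors, offs[:-1], offs[1:]):
            if t.requires_grad:
                t._accumulate(g[lo:hi])

    return _node(np.concatenate([t.data for t in tensors], axis=0), tuple(tensors), bwd)


# ---------------------------------------------------------------------------
# 3D convolution via im2col

def _im2col(x: np.ndarray, k: int, stride: int, pad: int):
    """(B, C, D, H, W) -> columns (B, N, C*k^3) and the output grid shape."""
    B, C = x.shape[:2]
    xp = np.pad(x, ((0, 0), (0, 0)) + ((pad, pad),) * 3)
    win = sliding_window_view(xp, (k, k, k), axis=(2, 3, 4))
    win = win[:, :, ::stride, ::stride, ::stride]
    out_sp = win.shape[2:5]
    cols = win.transpose(0, 2, 3, 4, 1, 5, 6, 7).reshape(
        B, int(np.prod(out_sp)), C * k**3
    )
    return np.ascontiguousarray(cols), out_sp


def _col2im(gcols: np.ndarray, x_shape, k: int, stride: int, pad: int, out_sp):
    """Scatter-add column gradients back onto the (padded) input grid."""
    B, C, D, H, W = x_shape
    Do, Ho, Wo = out_sp
    gx = np.zeros((B, C, D + 2 * pad, H + 2 * pad, W + 2 * pad))
    g = gcols.reshape(B, Do, Ho, Wo, C, k, k, k).transpose(0, 4, 1, 2, 3, 5, 6, 7)
    for i, j, l in product(range(k), range(k), range(k)):
        gx[:, :,
           i : i + stride * Do : stride,
           j : j + stride * Ho : stride,
           l : l + stride * Wo : stride] += g[..., i, j, l]
    if pad:
        gx = gx[:, :, pad:-pad, pad:-pad, pad:-pad]
    return gx


def conv3d(x: Tensor, w: Tensor, b: Tensor | None, stride: int = 1,
           pad: int | None = None) -> Tensor:
    """3D convolution: x (B, Cin, D, H, W), w (Cout, Cin, k, k, k)."""
    Cout, Cin, k = w.shape[0], w.shape[1], w.shape[2]
    if x.shape[1] != Cin:
        raise ValueError(f"channel mismatch: input {x.shape[1]}, weight {Cin}")
    if pad is None:
        pad = k // 2
    cols, out_sp = _im2col(x.data, k, stride, pad)
    wmat = w.data.reshape(Cout, Cin * k**3)
    y = cols @ wmat.T  # (B, N, Cout)
    if b is not None:
        y = y + b.data
    B = x.shape[0]
    out_data = y.transpose(0, 2, 1).reshape(B, Cout, *out_sp)

    parents = (x, w) if b is None else (x, w, b)

    def bwd(g):
        g2 = g.reshape(B, Cout, -1).transpose(0, 2, 1)  # (B, N, Cout)
        if b is not None and b.requires_grad:
            b._accumulate(g2.sum(axis=(0, 1)))
        if w.requires_grad:
            gw = g2.reshape(-1, Cout).T @ cols.reshape(-1, cols.shape[-1])
            w._accumulate(gw.reshape(w.shape))
        if x.requires_grad:
            gcols = g2 @ wmat  # (B, N, Cin*k^3)
            x._accumulate(_col2im(gcols, x.shape, k, stride, pad, out_sp))

    return _node(out_data, parents, bwd)
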