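"""Minimal reverse-mode automatic differentiation over numpy arrays.

A :class:`Tensor` wraps an ``ndarray`` and records the operations that
produced it; :meth:`Tensor.backward` walks the graph in reverse
topological order and accumulates gradients.  The op set is exactly what
the distance-map network needs: broadcast arithmetic, matmul, reshapes,
reductions, the SiLU/Softplus family, same-padding 2D convolutions
(full and depthwise), axis normalisation, a numerically stable
log-cosh, and the selective-scan recurrence (see ``scan.py``).

Everything runs in float64 on CPU, which keeps finite-difference
gradient checks tight and training bitwise reproducible.
"""

from __future__ import annotations

import math
from contextlib import contextmanager

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

_GRAD_ENABLED = [True]


@contextmanager
def no_grad():
    """Disable graph construction (inference mode)."""
    _GRAD_ENABLED.append(False)
    try:
        yield
    finally:
        _GRAD_ENABLED.pop()


def grad_enabled() -> bool:
    return _GRAD_ENABLED[-1]


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = requires_grad
        self.grad: np.ndarray | None = None
        self._backward = None
        self._parents: tuple[Tensor, ...] = ()

    # -- graph bookkeeping -------------------------------------------------

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without gradient requires a scalar")
            grad = np.ones_like(self.data)
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
        self.grad = np.asarray(grad, dtype=np.float64)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def zero_grad(self) -> None:
        self.grad = None

    # -- operator sugar ----------------------------------------------------

    def __add__(self, other):
        return add(self, _as_tensor(other))

    __radd__ = __add__

    def __sub__(self, other):
        return add(self, neg(_as_tensor(other)))

    def __rsub__(self, other):
        return add(_as_tensor(other), neg(self))

    def __mul__(self, other):
        return mul(self, _as_tensor(other))

    __rmul__ = __mul__

    def __truediv__(self, other):
        return div(self, _as_tensor(other))

    def __rtruediv__(self, other):
        return div(_as_tensor(other), self)

    def __neg__(self):
        return neg(self)

    def __matmul__(self, other):
        return matmul(self, _as_tensor(other))

    def reshape(self, *shape):
        return reshape(self, shape)

    def transpose(self, axes):
        return transpose(self, axes)

    def sum(self, axis=None, keepdims=False):
        return reduce_sum(self, axis, keepdims)

    def mean(self, axis=None, keepdims=False):
        return reduce_mean(self, axis, keepdims)

    def item(self) -> float:
        return float(self.data)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Reduce a broadcast gradient back to the source shape."""
    if grad.shape == shape:
        return grad
    n_extra = grad.ndim - len(shape)
    if n_extra > 0:
        grad = grad.sum(axis=tuple(range(n_extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


def _make(data: np.ndarray, parents: tuple[Tensor, ...], backward) -> Tensor:
    req = grad_enabled() and any(p.requires_grad for p in parents)
    out = Tensor(data, requires_grad=req)
    if req:
        out._parents = tuple(p for p in parents if p.requires_grad)
        out._backward = backward
    return out


def _accum(t: Tensor, g: np.ndarray) -> None:
    if not t.requires_grad:
        return
    if t.grad is None:
        t.grad = g.copy() if g.base is not None or not g.flags.owndata else g
    else:
        t.grad = t.grad + g


# ---------------------------------------------------------------------------
# arithmetic
# ---------------------------------------------------------------------------

def add(a: Tensor, b: Tensor) -> Tensor:
    data = a.data + b.data

    def backward(g):
        _accum(a, _unbroadcast(g, a.data.shape))
        _accum(b, _unbroadcast(g, b.data.shape))

    return _make(data, (a, b), backward)


def neg(a: Tensor) -> Tensor:
    def backward(g):
        _accum(a, -g)

    return _make(-a.data, (a,), backward)


def mul(a: Tensor, b: Tensor) -> Tensor:
    data = a.data * b.data

    def backward(g):
        _accum(a, _unbroadcast(g * b.data, a.data.shape))
        _accum(b, _unbroadcast(g * a.data, b.data.shape))

    return _make(data, (a, b), backward)


def div(a: Tensor, b: Tensor) -> Tensor:
    data = a.data / b.data

    def backward(g):
        _accum(a, _unbroadcast(g / b.data, a.data.shape))
        _accum(b, _unbroadcast(-g * a.data / (b.data**2), b.data.shape))

    return _make(data, (a, b), backward)


def matmul(a: Tensor, b: Tensor) -> Tensor:
    data = a.data @ b.data

    def backward(g):
        if b.requires_grad:
            ga = a.data
            if ga.ndim == 1:
                gb = np.outer(ga, g) if g.ndim == 1 else ga[:, None] * g
            else:
                gb = np.swapaxes(ga, -1, -2) @ g
            _accum(b, _unbroadcast(gb, b.data.shape))
        if a.requires_grad:
            gb_ = b.data
            if gb_.ndim == 1:
                gaa = np.outer(g, gb_) if g.ndim == 1 else g * gb_
            else:
                gaa = g @ np.swapaxes(gb_, -1, -2)
            _accum(a, _unbroadcast(gaa, a.data.shape))

    return _make(data, (a, b), backward)


# ---------------------------------------------------------------------------
# shape ops
# ---------------------------------------------------------------------------

def reshape(a: Tensor, shape) -> Tensor:
    shape = tuple(shape[0]) if len(shape) == 1 and isinstance(shape[0], (tuple, list)) else tuple(shape)
    old = a.data.shape

    def backward(g):
        _accum(a, g.reshape(old))

    return _make(a.data.reshape(shape), (a,), backward)


def transpose(a: Tensor, axes) -> Tensor:
    axes = tuple(axes)
    inv = tuple(np.argsort(axes))

    def backward(g):
        _accum(a, g.transpose(inv))

    return _make(a.data.transpose(axes), (a,), backward)


def concat(tensors: list[Tensor], axis: int = 0) -> Tensor:
    data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, start, stop in zip(tensors, offsets[:-1], offsets[1:]):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(start, stop)
            _accum(t, g[tuple(sl)])

    return _make(data, tuple(tensors), backward)


# ---------------------------------------------------------------------------
# reductions
# ---------------------------------------------------------------------------

def _expand_reduced(g, shape, axis, keepdims):
    if axis is None:
        return np.broadcast_to(g, shape)
    if not keepdims:
        axes = axis if isinstance(axis, tuple) else (axis,)
        axes = tuple(a % len(shape) for a in axes)
        g = np.expand_dims(g, axes)
    return np.broadcast_to(g, shape)


def reduce_sum(a: Tensor, axis=None, keepdims=False) -> Tensor:
    data = a.data.sum(axis=axis, keepdims=keepdims)

    def backward(g):
        _accum(a, _expand_reduced(g, a.data.shape, axis, keepdims).copy())

    return _make(data, (a,), backward)


def reduce_mean(a: Tensor, axis=None, keepdims=False) -> Tensor:
    data = a.data.mean(axis=axis, keepdims=keepdims)
    count = a.data.size / data.size

    def backward(g):
        _accum(a, _expand_reduced(g, a.data.shape, axis, keepdims) / count)

    return _make(data, (a,), backward)


# ---------------------------------------------------------------------------
# elementwise nonlinearities
# ---------------------------------------------------------------------------

def exp(a: Tensor) -> Tensor:
    data = np.exp(a.data)

    def backward(g):
        _accum(a, g * data)

    return _make(data, (a,), backward)


def log(a: Tensor) -> Tensor:
    def backward(g):
        _accum(a, g / a.data)

    return _make(np.log(a.data), (a,), backward)


def sqrt(a: Tensor) -> Tensor:
    data = np.sqrt(a.data)

    def backward(g):
        _accum(a, g / (2.0 * data))

    return _make(data, (a,), backward)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def sigmoid(a: Tensor) -> Tensor:
    s = _sigmoid(a.data)

    def backward(g):
        _accum(a, g * s * (1.0 - s))

    return _make(s, (a,), backward)


def tanh(a: Tensor) -> Tensor:
    t = np.tanh(a.data)

    def backward(g):
        _accum(a, g * (1.0 - t**2))

    return _make(t, (a,), backward)


def relu(a: Tensor) -> Tensor:
    mask = a.data > 0

    def backward(g):
        _accum(a, g * mask)

    return _make(a.data * mask, (a,), backward)


def silu(a: Tensor) -> Tensor:
    s = _sigmoid(a.data)
    data = a.data * s

    def backward(g):
        _accum(a, g * (s + a.data * s * (1.0 - s)))

    return _make(data, (a,), backward)


def _softplus(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0.0) + np.log1p(np.exp(-np.abs(x)))


def softplus(a: Tensor) -> Tensor:
    data = _softplus(a.data)
    s = _sigmoid(a.data)

    def backward(g):
        _accum(a, g * s)

    return _make(data, (a,), backward)


def log_cosh(a: Tensor) -> Tensor:
    """Numerically stable log(cosh(x)): |x| + log1p(exp(-2|x|)) - log 2."""
    ax = np.abs(a.data)
    data = ax + np.log1p(np.exp(-2.0 * ax)) - math.log(2.0)
    t = np.tanh(a.data)

    def backward(g):
        _accum(a, g * t)

    return _make(data, (a,), backward)


# ---------------------------------------------------------------------------
# normalisation
# ---------------------------------------------------------------------------

def normalize(a: Tensor, gamma: Tensor, beta: Tensor, axes, eps: float = 1e-5) -> Tensor:
    """Affine normalisation over ``axes`` (layer/instance norm share this)."""
    axes = axes if isinstance(axes, tuple) else (axes,)
    mu = a.data.mean(axis=axes, keepdims=True)
    var = a.data.var(axis=axes, keepdims=True)
    inv_std = 1.0 / np.sqrt(var + eps)
    xhat = (a.data - mu) * inv_std
    data = xhat * gamma.data + beta.data

    def backward(g):
        if gamma.requires_grad:
            _accum(gamma, _unbroadcast(g * xhat, gamma.data.shape))
        if beta.requires_grad:
            _accum(beta, _unbroadcast(g, beta.data.shape))
        if a.requires_grad:
            gy = g * gamma.data
            m1 = gy.mean(axis=axes, keepdims=True)
            m2 = (gy * xhat).mean(axis=axes, keepdims=True)
            _accum(a, (gy - m1 - xhat * m2) * inv_std)

    return _make(data, (a, gamma, beta), backward)


# ---------------------------------------------------------------------------
# convolutions (stride 1, same padding)
# ---------------------------------------------------------------------------

def _same_pads(k: int) -> tuple[int, int]:
    before = (k - 1) // 2
    return before, k - 1 - before


def _pad_hw(x: np.ndarray, ph: tuple[int, int], pw: tuple[int, int]) -> np.ndarray:
    return np.pad(x, ((0, 0), (0, 0), ph, pw))


def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None) -> Tensor:
    """Full cross-correlation, stride 1, same padding.

    x: (B, C, H, W); w: (O, C, kh, kw); b: (O,).
    """
    B, C, H, W = x.data.shape
    O, Cw, kh, kw = w.data.shape
    if Cw != C:
        raise ValueError(f"conv2d channel mismatch: input {C}, weight {Cw}")
    ph, pw = _same_pads(kh), _same_pads(kw)
    xp = _pad_hw(x.data, ph, pw)
    patches = sliding_window_view(xp, (kh, kw), axis=(2, 3))      # (B,C,H,W,kh,kw)
    pm = patches.transpose(0, 2, 3, 1, 4, 5).reshape(B * H * W, C * kh * kw)
    wm = w.data.reshape(O, C * kh * kw)
    y = (pm @ wm.T).reshape(B, H, W, O).transpose(0, 3, 1, 2)
    if b is not None:
        y = y + b.data[None, :, None, None]

    def backward(g):
        gm = g.transpose(0, 2, 3, 1).reshape(B * H * W, O)
        if w.requires_grad:
            _accum(w, (gm.T @ pm).reshape(O, C, kh, kw))
        if b is not None and b.requires_grad:
            _accum(b, g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            # gradient wrt input: correlate padded g with the flipped kernel
            gp = _pad_hw(g, (ph[1], ph[0]), (pw[1], pw[0]))
            gpatches = sliding_window_view(gp, (kh, kw), axis=(2, 3))
            gpm = gpatches.transpose(0, 2, 3, 1, 4, 5).reshape(B * H * W, O * kh * kw)
            wf = w.data[:, :, ::-1, ::-1].transpose(1, 0, 2, 3).reshape(C, O * kh * kw)
            _accum(x, (gpm @ wf.T).reshape(B, H, W, C).transpose(0, 3, 1, 2))

    parents = (x, w) if b is None else (x, w, b)
    return _make(y, parents, backward)


def depthwise_conv2d(x: Tensor, w: Tensor, b: Tensor | None = None) -> Tensor:
    """Depthwise (per-channel) correlation, stride 1, same padding.

    x: (B, C, H, W); w: (C, kh, kw); b: (C,).
    """
    B, C, H, W = x.data.shape
    Cw, kh, kw = w.data.shape
    if Cw != C:
        raise ValueError(f"depthwise conv channel mismatch: input {C}, weight {Cw}")
    ph, pw = _same_pads(kh), _same_pads(kw)
    xp = _pad_hw(x.data, ph, pw)
    patches = sliding_window_view(xp, (kh, kw), axis=(2, 3))
    y = np.einsum("bchwij,cij->bchw", patches, w.data, optimize=True)
    if b is not None:
        y = y + b.data[None, :, None, None]

    def backward(g):
        if w.requires_grad:
            _accum(w, np.einsum("bchwij,bchw->cij", patches, g, optimize=True))
        if b is not None and b.requires_grad:
            _accum(b, g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            gp = _pad_hw(g, (ph[1], ph[0]), (pw[1], pw[0]))
            gpatches = sliding_window_view(gp, (kh, kw), axis=(2, 3))
            wf = w.data[:, ::-1, ::-1]
            _accum(x, np.einsum("bchwij,cij->bchw", gpatches, wf, optimize=True))

    parents = (x, w) if b is None else (x, w, b)
    return _make(y, parents, backward)


def conv_transpose2d(x: Tensor, w: Tensor, b: Tensor | None = None) -> Tensor:
    """Stride-1 transposed convolution (the adjoint of same-padding conv2d).

    At constant spatial resolution this is a correlation with the
    spatially flipped kernel and swapped channel axes; it acts as a
    learned channel mixer.  w: (C_in, C_out, kh, kw).
    """
    B, C, H, W = x.data.shape
    Ci, Co, kh, kw = w.data.shape
    if Ci != C:
        raise ValueError(f"conv_transpose2d channel mismatch: input {C}, weight {Ci}")
    ph, pw = _same_pads(kh), _same_pads(kw)
    wflip = w.data[:, :, ::-1, ::-1]                              # (C, O, kh, kw)
    # pad with swapped before/after, matching the adjoint of conv2d
    xp = _pad_hw(x.data, (ph[1], ph[0]), (pw[1], pw[0]))
    patches = sliding_window_view(xp, (kh, kw), axis=(2, 3))
    pm = patches.transpose(0, 2, 3, 1, 4, 5).reshape(B * H * W, C * kh * kw)
    wm = wflip.transpose(1, 0, 2, 3).reshape(Co, C * kh * kw)
    y = (pm @ wm.T).reshape(B, H, W, Co).transpose(0, 3, 1, 2)
    if b is not None:
        y = y + b.data[None, :, None, None]

    def backward(g):
        gm = g.transpose(0, 2, 3, 1).reshape(B * H * W, Co)
        if w.requires_grad:
            gw = (gm.T @ pm).reshape(Co, C, kh, kw)               # grad wrt wflip^T layout
            _accum(w, gw.transpose(1, 0, 2, 3)[:, :, ::-1, ::-1])
        if b is not None and b.requires_grad:
            _accum(b, g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            gp = _pad_hw(g, ph, pw)
            gpatches = sliding_window_view(gp, (kh, kw), axis=(2, 3))
            gpm = gpatches.transpose(0, 2, 3, 1, 4, 5).reshape(B * H * W, Co * kh * kw)
            wb = w.data.transpose(0, 1, 2, 3).reshape(C, Co * kh * kw)
            _accum(x, (gpm @ wb.T).reshape(B, H, W, C).transpose(0, 3, 1, 2))

    parents = (x, w) if b is None else (x, w, b)
    return _make(y, parents, backward)


__all__ = [
    "Tensor",
    "no_grad",
    "grad_enabled",
    "add",
    "neg",
    "mul",
    "div",
    "matmul",
    "reshape",
    "transpose",
    "concat",
    "reduce_sum",
    "reduce_mean",
    "exp",
    "log",
    "sqrt",
    "sigmoid",
    "tanh",
    "relu",
    "silu",
    "softplus",
    "log_cosh",
    "normalize",
    "conv2d",
    "depthwise_conv2d",
    "conv_transpose2d",
]
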