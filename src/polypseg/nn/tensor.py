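"""Reverse-mode automatic differentiation on NumPy arrays.

This is the compute core of the package: a small tape-based autodiff
engine exposing exactly the operations the segmentation model needs
(elementwise arithmetic, matmul, reductions, 2-D convolution, bilinear
resampling, softmax and friends).  All tensors are float32.

Gradients are accumulated into ``Tensor.grad`` by :meth:`Tensor.backward`,
which walks the recorded graph in reverse topological order.  Graph
recording can be suspended with :func:`no_grad` (used for evaluation).
"""

from __future__ import annotations

import contextlib
from typing import Callable, Sequence

import numpy as np

_GRAD_ENABLED = True


@contextlib.contextmanager
def no_grad():
    """Context manager that disables graph recording."""
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (adjoint of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    ndiff = grad.ndim - len(shape)
    if ndiff > 0:
        grad = grad.sum(axis=tuple(range(ndiff)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A float32 array with an optional gradient tape entry."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float32)
        self.requires_grad = bool(requires_grad)
        self.grad: np.ndarray | None = None
        self._parents: tuple[Tensor, ...] = ()
        self._backward: Callable[[np.ndarray], None] | None = None

    # -- basic introspection -------------------------------------------------
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    @property
    def size(self) -> int:
        return self.data.size

    def item(self) -> float:
        return float(self.data)

    def numpy(self) -> np.ndarray:
        return self.data

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"

    # -- graph plumbing ------------------------------------------------------
    def zero_grad(self) -> None:
        self.grad = None

    def backward(self, grad: np.ndarray | None = None) -> None:
        """Backpropagate from this tensor through the recorded graph."""
        if grad is None:
            if self.size != 1:
                raise ValueError("backward() without grad requires a scalar tensor")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
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
        grads: dict[int, np.ndarray] = {id(self): np.asarray(grad, dtype=np.float32)}
        for node in reversed(topo):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node.requires_grad and not node._parents:
                node.grad = g if node.grad is None else node.grad + g
            if node._backward is not None:
                for parent, pg in node._backward(g):
                    if id(parent) in grads:
                        grads[id(parent)] += pg
                    else:
                        grads[id(parent)] = pg
                # leaf-with-op tensors (e.g. parameters are leaves, skip)

    # -- operator sugar ------------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __neg__(self):
        return mul(self, -1.0)

    def __sub__(self, other):
        return add(self, mul(_ensure(other), -1.0))

    def __rsub__(self, other):
        return add(_ensure(other), mul(self, -1.0))

    def __truediv__(self, other):
        return mul(self, power(_ensure(other), -1.0))

    def __rtruediv__(self, other):
        return mul(_ensure(other), power(self, -1.0))

    def __pow__(self, p):
        return power(self, p)

    def __matmul__(self, other):
        return matmul(self, other)

    # convenience methods
    def reshape(self, *shape):
        return reshape(self, shape if len(shape) > 1 else shape[0])

    def transpose(self, *axes):
        return transpose(self, axes)

    def sum(self, axis=None, keepdims=False):
        return tsum(self, axis=axis, keepdims=keepdims)

    def mean(self, axis=None, keepdims=False):
        return tmean(self, axis=axis, keepdims=keepdims)


def _ensure(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _make(data: np.ndarray, parents: Sequence[Tensor], backward) -> Tensor:
    """Build an op output, recording the tape entry only when needed."""
    out = Tensor(data)
    if _GRAD_ENABLED and any(p.requires_grad or p._parents for p in parents):
        out._parents = tuple(parents)
        out._backward = backward
        # mark as needing grad flow so downstream ops keep recording
        out.requires_grad = False
    return out


# ---------------------------------------------------------------------------
# elementwise ops
# ---------------------------------------------------------------------------

def add(a, b) -> Tensor:
    a, b = _ensure(a), _ensure(b)
    data = a.data + b.data

    def backward(g):
        return ((a, _unbroadcast(g, a.shape)), (b, _unbroadcast(g, b.shape)))

    return _make(data, (a, b), backward)


def mul(a, b) -> Tensor:
    a, b = _ensure(a), _ensure(b)
    data = a.data * b.data

    def backward(g):
        return (
            (a, _unbroadcast(g * b.data, a.shape)),
            (b, _unbroadcast(g * a.data, b.shape)),
        )

    return _make(data, (a, b), backward)


def power(a, p: float) -> Tensor:
    a = _ensure(a)
    if isinstance(p, Tensor):
        raise TypeError("power supports scalar exponents only")
    data = np.power(a.data, p)

    def backward(g):
        return ((a, g * p * np.power(a.data, p - 1.0)),)

    return _make(data, (a,), backward)


def exp(a) -> Tensor:
    a = _ensure(a)
    data = np.exp(a.data)

    def backward(g):
        return ((a, g * data),)

    return _make(data, (a,), backward)


def log(a) -> Tensor:
    a = _ensure(a)
    data = np.log(a.data)

    def backward(g):
        return ((a, g / a.data),)

    return _make(data, (a,), backward)


def sqrt(a) -> Tensor:
    return power(a, 0.5)


def clip(a, lo: float, hi: float) -> Tensor:
    """Clamp with straight-through gradient inside the interval."""
    a = _ensure(a)
    data = np.clip(a.data, lo, hi)
    inside = ((a.data >= lo) & (a.data <= hi)).astype(np.float32)

    def backward(g):
        return ((a, g * inside),)

    return _make(data, (a,), backward)


def relu(a) -> Tensor:
    a = _ensure(a)
    mask = (a.data > 0).astype(np.float32)
    data = a.data * mask

    def backward(g):
        return ((a, g * mask),)

    return _make(data, (a,), backward)


def sigmoid(a) -> Tensor:
    a = _ensure(a)
    data = 1.0 / (1.0 + np.exp(-a.data))

    def backward(g):
        return ((a, g * data * (1.0 - data)),)

    return _make(data, (a,), backward)


def tanh(a) -> Tensor:
    a = _ensure(a)
    data = np.tanh(a.data)

    def backward(g):
        return ((a, g * (1.0 - data * data)),)

    return _make(data, (a,), backward)


_GELU_C = float(np.sqrt(2.0 / np.pi))


def gelu(a) -> Tensor:
    """GELU via the tanh approximation (composite, autodiffed)."""
    a = _ensure(a)
    inner = mul(tanh(mul(add(a, mul(power(a, 3.0), 0.044715)), _GELU_C)), 1.0)
    return mul(mul(a, add(inner, 1.0)), 0.5)


# ---------------------------------------------------------------------------
# shape ops
# ---------------------------------------------------------------------------

def reshape(a, shape) -> Tensor:
    a = _ensure(a)
    data = a.data.reshape(shape)
    orig = a.shape

    def backward(g):
        return ((a, g.reshape(orig)),)

    return _make(data, (a,), backward)


def transpose(a, axes) -> Tensor:
    a = _ensure(a)
    axes = tuple(axes)
    data = a.data.transpose(axes)
    inv = tuple(np.argsort(axes))

    def backward(g):
        return ((a, g.transpose(inv)),)

    return _make(data, (a,), backward)


def concatenate(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    tensors = [_ensure(t) for t in tensors]
    data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        parts = np.split(g, splits, axis=axis)
        return tuple(zip(tensors, parts))

    return _make(data, tuple(tensors), backward)


def tsum(a, axis=None, keepdims=False) -> Tensor:
    a = _ensure(a)
    data = a.data.sum(axis=axis, keepdims=keepdims)

    def backward(g):
        if axis is None:
            return ((a, np.broadcast_to(g, a.shape).astype(np.float32)),)
        if not keepdims:
            ax = axis if isinstance(axis, tuple) else (axis,)
            ax = tuple(x % a.ndim for x in ax)
            shape = tuple(1 if i in ax else s for i, s in enumerate(a.shape))
            g = g.reshape(shape)
        return ((a, np.broadcast_to(g, a.shape).astype(np.float32)),)

    return _make(data, (a,), backward)


def tmean(a, axis=None, keepdims=False) -> Tensor:
    a = _ensure(a)
    if axis is None:
        n = a.size
    else:
        ax = axis if isinstance(axis, tuple) else (axis,)
        n = int(np.prod([a.shape[x % a.ndim] for x in ax]))
    return mul(tsum(a, axis=axis, keepdims=keepdims), 1.0 / n)


# ---------------------------------------------------------------------------
# linear algebra
# ---------------------------------------------------------------------------

def matmul(a, b) -> Tensor:
    a, b = _ensure(a), _ensure(b)
    data = np.matmul(a.data, b.data)

    def backward(g):
        ga = np.matmul(g, np.swapaxes(b.data, -1, -2))
        gb = np.matmul(np.swapaxes(a.data, -1, -2), g)
        return ((a, _unbroadcast(ga, a.shape)), (b, _unbroadcast(gb, b.shape)))

    return _make(data, (a, b), backward)


def softmax(a, axis: int = -1) -> Tensor:
    """Numerically stabilised softmax (row-max subtracted as a constant)."""
    a = _ensure(a)
    shifted = add(a, Tensor(-a.data.max(axis=axis, keepdims=True)))
    e = exp(shifted)
    return mul(e, power(tsum(e, axis=axis, keepdims=True), -1.0))


# ---------------------------------------------------------------------------
# 2-D convolution (im2col) and resampling
# ---------------------------------------------------------------------------

def _im2col(xp: np.ndarray, kh: int, kw: int, stride: int):
    """(B,C,Hp,Wp) -> (B, Ho*Wo, C*kh*kw) patch matrix."""
    b, c, hp, wp = xp.shape
    ho = (hp - kh) // stride + 1
    wo = (wp - kw) // stride + 1
    win = np.lib.stride_tricks.sliding_window_view(xp, (kh, kw), axis=(2, 3))
    win = win[:, :, ::stride, ::stride]  # (B,C,Ho,Wo,kh,kw)
    cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(b, ho * wo, c * kh * kw)
    return np.ascontiguousarray(cols), ho, wo


def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None,
           stride: int = 1, padding: int = 0) -> Tensor:
    """Cross-correlation of NCHW input with (Cout,Cin,kh,kw) kernel."""
    x, w = _ensure(x), _ensure(w)
    bsz, cin, h, wd = x.shape
    cout, cin_w, kh, kw = w.shape
    if cin != cin_w:
        raise ValueError(f"conv2d channel mismatch: input {cin}, kernel {cin_w}")
    if padding:
        xp = np.pad(x.data, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
    else:
        xp = x.data
    cols, ho, wo = _im2col(xp, kh, kw, stride)
    wmat = w.data.reshape(cout, cin * kh * kw)
    out = cols @ wmat.T  # (B, L, Cout)
    if b is not None:
        out = out + b.data.reshape(1, 1, cout)
    data = out.transpose(0, 2, 1).reshape(bsz, cout, ho, wo)
    parents = (x, w) if b is None else (x, w, b)

    def backward(g):
        gmat = g.reshape(bsz, cout, ho * wo).transpose(0, 2, 1)  # (B,L,Cout)
        gw = np.tensordot(gmat, cols, axes=([0, 1], [0, 1])).reshape(w.shape)
        gcols = gmat @ wmat  # (B, L, C*kh*kw)
        gcols = gcols.reshape(bsz, ho, wo, cin, kh, kw).transpose(0, 3, 1, 2, 4, 5)
        gxp = np.zeros_like(xp)
        for i in range(kh):
            for j in range(kw):
                gxp[:, :, i:i + stride * ho:stride, j:j + stride * wo:stride] += \
                    gcols[:, :, :, :, i, j]
        gx = gxp[:, :, padding:padding + h, padding:padding + wd] if padding else gxp
        grads = [(x, gx), (w, gw)]
        if b is not None:
            grads.append((b, gmat.sum(axis=(0, 1))))
        return tuple(grads)

    return _make(data, parents, backward)


def _resize_matrix(n_out: int, n_in: int, mode: str) -> np.ndarray:
    """Interpolation matrix M (n_out x n_in): y = M x along one axis."""
    m = np.zeros((n_out, n_in), dtype=np.float32)
    if mode == "nearest":
        src = np.minimum((np.arange(n_out) * n_in // n_out), n_in - 1)
        m[np.arange(n_out), src] = 1.0
        return m
    # bilinear, half-pixel centres
    src = (np.arange(n_out) + 0.5) * n_in / n_out - 0.5
    src = np.clip(src, 0, n_in - 1)
    lo = np.floor(src).astype(int)
    hi = np.minimum(lo + 1, n_in - 1)
    frac = (src - lo).astype(np.float32)
    np.add.at(m, (np.arange(n_out), lo), 1.0 - frac)
    np.add.at(m, (np.arange(n_out), hi), frac)
    return m


_RESIZE_CACHE: dict[tuple, np.ndarray] = {}


def _cached_resize_matrix(n_out: int, n_in: int, mode: str) -> np.ndarray:
    key = (n_out, n_in, mode)
    if key not in _RESIZE_CACHE:
        _RESIZE_CACHE[key] = _resize_matrix(n_out, n_in, mode)
    return _RESIZE_CACHE[key]


def resize2d(x: Tensor, size: tuple[int, int], mode: str = "bilinear") -> Tensor:
    """Resample NCHW maps to ``size`` by separable interpolation matrices."""
    x = _ensure(x)
    b, c, h, w = x.shape
    oh, ow = size
    if oh <= 0 or ow <= 0:
        raise ValueError(f"resize2d target must be positive, got {size}")
    if (oh, ow) == (h, w):
        return x
    a_mat = _cached_resize_matrix(oh, h, mode)  # (oh, h)
    b_mat = _cached_resize_matrix(ow, w, mode)  # (ow, w)
    data = np.einsum("oh,bchw,pw->bcop", a_mat, x.data, b_mat, optimize=True)

    def backward(g):
        gx = np.einsum("oh,bcop,pw->bchw", a_mat, g, b_mat, optimize=True)
        return ((x, gx.astype(np.float32)),)

    return _make(data.astype(np.float32), (x,), backward)
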