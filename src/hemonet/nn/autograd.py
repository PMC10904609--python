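"""Minimal reverse-mode automatic differentiation on NumPy arrays.

Supports exactly the operations the package's network architectures need:
broadcast arithmetic, matmul, 1-D convolution and max-pooling with "same"
padding, pointwise nonlinearities, reductions, concatenation, time reversal,
and a fused softmax cross-entropy loss.  Gradients are accumulated by
topological traversal of the recorded graph.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "add", "sub", "mul", "neg", "matmul", "power", "concat", "reshape",
    "flip_time", "mean", "sum_", "relu", "leaky_relu", "sigmoid", "tanh",
    "conv1d_same", "maxpool1d_same", "softmax", "softmax_cross_entropy",
]


class Tensor:
    """A node in the autodiff graph."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=float)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._parents: tuple[Tensor, ...] = ()
        self._backward = None

    @property
    def shape(self):
        return self.data.shape

    def backward(self, grad: np.ndarray | None = None) -> None:
        """Backpropagate from this node (default seed: ones)."""
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
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))

        self.grad = np.ones_like(self.data) if grad is None else np.asarray(grad, float)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def zero_grad(self) -> None:
        self.grad = None

    # convenience operators -------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    def __sub__(self, other):
        return sub(self, other)

    def __mul__(self, other):
        return mul(self, other)

    def __neg__(self):
        return neg(self)

    def __matmul__(self, other):
        return matmul(self, other)


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _accum(t: Tensor, g: np.ndarray) -> None:
    if not t.requires_grad and t._backward is None and not t._parents:
        return
    t.grad = g if t.grad is None else t.grad + g


def _needs_graph(*ts: Tensor) -> bool:
    return any(t.requires_grad or t._parents for t in ts)


def _make(data, parents, backward) -> Tensor:
    out = Tensor(data)
    if _needs_graph(*parents):
        out._parents = tuple(parents)
        out._backward = backward
        out.requires_grad = True
    return out


def _unbroadcast(g: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum gradient ``g`` down to ``shape`` (reverse of NumPy broadcasting)."""
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for ax, s in enumerate(shape):
        if s == 1 and g.shape[ax] != 1:
            g = g.sum(axis=ax, keepdims=True)
    return g


# ---------------------------------------------------------------------------
# arithmetic
# ---------------------------------------------------------------------------

def add(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)

    def bw(g):
        _accum(a, _unbroadcast(g, a.shape))
        _accum(b, _unbroadcast(g, b.shape))

    return _make(a.data + b.data, (a, b), bw)


def sub(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)

    def bw(g):
        _accum(a, _unbroadcast(g, a.shape))
        _accum(b, _unbroadcast(-g, b.shape))

    return _make(a.data - b.data, (a, b), bw)


def neg(a) -> Tensor:
    a = _as_tensor(a)

    def bw(g):
        _accum(a, -g)

    return _make(-a.data, (a,), bw)


def mul(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)

    def bw(g):
        _accum(a, _unbroadcast(g * b.data, a.shape))
        _accum(b, _unbroadcast(g * a.data, b.shape))

    return _make(a.data * b.data, (a, b), bw)


def power(a, p: float) -> Tensor:
    a = _as_tensor(a)

    def bw(g):
        _accum(a, g * p * a.data ** (p - 1))

    return _make(a.data**p, (a,), bw)


def matmul(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)

    def bw(g):
        _accum(a, g @ b.data.T)
        _accum(b, a.data.T @ g)

    return _make(a.data @ b.data, (a, b), bw)


# ---------------------------------------------------------------------------
# shape ops
# ---------------------------------------------------------------------------

def reshape(a, shape) -> Tensor:
    a = _as_tensor(a)
    old = a.shape

    def bw(g):
        _accum(a, g.reshape(old))

    return _make(a.data.reshape(shape), (a,), bw)


def concat(tensors, axis: int = 1) -> Tensor:
    ts = [_as_tensor(t) for t in tensors]
    sizes = [t.shape[axis] for t in ts]
    splits = np.cumsum(sizes)[:-1]

    def bw(g):
        for t, piece in zip(ts, np.split(g, splits, axis=axis)):
            _accum(t, piece)

    return _make(np.concatenate([t.data for t in ts], axis=axis), tuple(ts), bw)


def flip_time(a) -> Tensor:
    """Reverse the last axis (time)."""
    a = _as_tensor(a)

    def bw(g):
        _accum(a, g[..., ::-1])

    return _make(a.data[..., ::-1].copy(), (a,), bw)


def mean(a, axis=None, keepdims: bool = False) -> Tensor:
    a = _as_tensor(a)
    n = a.data.size if axis is None else np.prod(
        [a.shape[ax] for ax in (axis if isinstance(axis, tuple) else (axis,))]
    )

    def bw(g):
        gg = np.asarray(g)
        if axis is not None and not keepdims:
            gg = np.expand_dims(gg, axis)
        _accum(a, np.broadcast_to(gg, a.shape) / n)

    return _make(a.data.mean(axis=axis, keepdims=keepdims), (a,), bw)


def sum_(a, axis=None, keepdims: bool = False) -> Tensor:
    a = _as_tensor(a)

    def bw(g):
        gg = np.asarray(g)
        if axis is not None and not keepdims:
            gg = np.expand_dims(gg, axis)
        _accum(a, np.broadcast_to(gg, a.shape).copy())

    return _make(a.data.sum(axis=axis, keepdims=keepdims), (a,), bw)


# ---------------------------------------------------------------------------
# nonlinearities
# ---------------------------------------------------------------------------

def relu(a) -> Tensor:
    a = _as_tensor(a)
    mask = a.data > 0

    def bw(g):
        _accum(a, g * mask)

    return _make(a.data * mask, (a,), bw)


def leaky_relu(a, alpha: float = 0.01) -> Tensor:
    a = _as_tensor(a)
    mask = a.data > 0
    slope = np.where(mask, 1.0, alpha)

    def bw(g):
        _accum(a, g * slope)

    return _make(a.data * slope, (a,), bw)


def sigmoid(a) -> Tensor:
    a = _as_tensor(a)
    s = 1.0 / (1.0 + np.exp(-np.clip(a.data, -500, 500)))

    def bw(g):
        _accum(a, g * s * (1 - s))

    return _make(s, (a,), bw)


def tanh(a) -> Tensor:
    a = _as_tensor(a)
    t = np.tanh(a.data)

    def bw(g):
        _accum(a, g * (1 - t * t))

    return _make(t, (a,), bw)


# ---------------------------------------------------------------------------
# 1-D convolution / pooling ("same" padding, stride 1)
# ---------------------------------------------------------------------------

def _same_pads(k: int) -> tuple[int, int]:
    return (k - 1) // 2, k // 2


def conv1d_same(x, w, b=None) -> Tensor:
    """x: (B, C, L), w: (O, C, K), optional bias (O,) -> (B, O, L)."""
    x, w = _as_tensor(x), _as_tensor(w)
    B, C, L = x.shape
    O, C2, K = w.shape
    if C != C2:
        raise ValueError(f"channel mismatch: input {C}, kernel {C2}")
    pl, pr = _same_pads(K)
    xp = np.pad(x.data, ((0, 0), (0, 0), (pl, pr)))
    win = np.lib.stride_tricks.sliding_window_view(xp, K, axis=2)  # (B,C,L,K)
    out = np.einsum("bclk,ock->bol", win, w.data, optimize=True)
    bias = _as_tensor(b) if b is not None else None
    if bias is not None:
        out = out + bias.data[None, :, None]

    parents = (x, w) if bias is None else (x, w, bias)

    def bw(g):
        _accum(w, np.einsum("bclk,bol->ock", win, g, optimize=True))
        gxp = np.zeros_like(xp)
        for k in range(K):
            gxp[:, :, k:k + L] += np.einsum("bol,oc->bcl", g, w.data[:, :, k], optimize=True)
        _accum(x, gxp[:, :, pl:pl + L])
        if bias is not None:
            _accum(bias, g.sum(axis=(0, 2)))

    return _make(out, parents, bw)


def maxpool1d_same(x, k: int = 3) -> Tensor:
    """Stride-1 max pooling with "same" padding over the last axis."""
    x = _as_tensor(x)
    B, C, L = x.shape
    pl, pr = _same_pads(k)
    xp = np.pad(x.data, ((0, 0), (0, 0), (pl, pr)), constant_values=-np.inf)
    win = np.lib.stride_tricks.sliding_window_view(xp, k, axis=2)  # (B,C,L,k)
    idx = win.argmax(axis=-1)
    out = np.take_along_axis(win, idx[..., None], axis=-1)[..., 0]

    def bw(g):
        gxp = np.zeros((B, C, L + pl + pr))
        b_i, c_i, l_i = np.indices(idx.shape)
        np.add.at(gxp, (b_i, c_i, l_i + idx), g)
        _accum(x, gxp[:, :, pl:pl + L])

    return _make(out, (x,), bw)


# ---------------------------------------------------------------------------
# softmax / loss
# ---------------------------------------------------------------------------

def _softmax_np(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def softmax(a) -> Tensor:
    a = _as_tensor(a)
    p = _softmax_np(a.data)

    def bw(g):
        dot = (g * p).sum(axis=-1, keepdims=True)
        _accum(a, p * (g - dot))

    return _make(p, (a,), bw)


def softmax_cross_entropy(logits, labels: np.ndarray) -> Tensor:
    """Mean multi-class cross-entropy; ``labels`` are integer class ids."""
    logits = _as_tensor(logits)
    labels = np.asarray(labels, dtype=int)
    p = _softmax_np(logits.data)
    n = logits.shape[0]
    loss = -np.mean(np.log(p[np.arange(n), labels] + 1e-300))

    def bw(g):
        grad = p.copy()
        grad[np.arange(n), labels] -= 1.0
        _accum(logits, g * grad / n)

    return _make(loss, (logits,), bw)
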