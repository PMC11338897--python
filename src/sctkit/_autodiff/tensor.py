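"""Minimal reverse-mode automatic differentiation over numpy arrays.

A :class:`Tensor` wraps an ``np.ndarray`` and records the operations applied
to it on a dynamic tape; :meth:`Tensor.backward` replays the tape in reverse
topological order and accumulates gradients into ``.grad``.  Only the small
set of operations needed by the synthesis/registration networks and their
losses is implemented.  All computation is float32 by default and fully
deterministic.
"""

from __future__ import annotations

import numpy as np

DTYPE = np.float32


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    ndim_extra = grad.ndim - len(shape)
    if ndim_extra:
        grad = grad.sum(axis=tuple(range(ndim_extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        if isinstance(data, Tensor):
            data = data.data
        self.data = np.asarray(data, dtype=DTYPE)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._parents = ()

    # ------------------------------------------------------------------ infra
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def size(self):
        return self.data.size

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def item(self) -> float:
        return float(self.data)

    def numpy(self) -> np.ndarray:
        return self.data

    def zero_grad(self):
        self.grad = None

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def _accum(self, g: np.ndarray):
        if self.grad is None:
            self.grad = g.astype(DTYPE, copy=True) if g.dtype != DTYPE else g.copy()
        else:
            self.grad += g

    def backward(self, grad: np.ndarray | None = None):
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without gradient requires a scalar")
            grad = np.ones_like(self.data)
        self.grad = np.asarray(grad, dtype=DTYPE).reshape(self.data.shape)

        # iterative topological sort
        topo, visited, stack = [], set(), [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in visited:
                continue
            visited.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in visited:
                    stack.append((p, False))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # ------------------------------------------------------------- arithmetic
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __neg__(self):
        return mul(self, -1.0)

    def __sub__(self, other):
        return add(self, mul(_t(other), -1.0))

    def __rsub__(self, other):
        return add(_t(other), mul(self, -1.0))

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = _t(other)
        return mul(self, power(other, -1.0))

    def __rtruediv__(self, other):
        return mul(_t(other), power(self, -1.0))

    def __pow__(self, p):
        return power(self, p)

    def __matmul__(self, other):
        return matmul(self, other)

    def __getitem__(self, idx):
        return getitem(self, idx)

    def sum(self, axis=None, keepdims=False):
        return tsum(self, axis, keepdims)

    def mean(self, axis=None, keepdims=False):
        return tmean(self, axis, keepdims)

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        return reshape(self, shape)

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        return transpose(self, axes or None)

    def exp(self):
        return exp(self)

    def log(self):
        return log(self)

    def sqrt(self):
        return sqrt(self)

    def tanh(self):
        return tanh(self)


def _t(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _make(data, parents, backward) -> Tensor:
    out = Tensor(data)
    if any(p.requires_grad for p in parents):
        out.requires_grad = True
        out._parents = tuple(parents)
        out._backward = backward
    return out


# ------------------------------------------------------------------ primitives
def add(a, b):
    a, b = _t(a), _t(b)
    out_data = a.data + b.data

    def backward(g):
        if a.requires_grad:
            a._accum(_unbroadcast(g, a.data.shape))
        if b.requires_grad:
            b._accum(_unbroadcast(g, b.data.shape))

    return _make(out_data, (a, b), backward)


def mul(a, b):
    a, b = _t(a), _t(b)
    out_data = a.data * b.data

    def backward(g):
        if a.requires_grad:
            a._accum(_unbroadcast(g * b.data, a.data.shape))
        if b.requires_grad:
            b._accum(_unbroadcast(g * a.data, b.data.shape))

    return _make(out_data, (a, b), backward)


def power(a, p: float):
    a = _t(a)
    out_data = a.data ** p

    def backward(g):
        if a.requires_grad:
            a._accum(g * (p * a.data ** (p - 1.0)))

    return _make(out_data, (a,), backward)


def matmul(a, b):
    a, b = _t(a), _t(b)
    out_data = a.data @ b.data

    def backward(g):
        if a.requires_grad:
            ga = g @ np.swapaxes(b.data, -1, -2)
            a._accum(_unbroadcast(ga, a.data.shape))
        if b.requires_grad:
            gb = np.swapaxes(a.data, -1, -2) @ g
            b._accum(_unbroadcast(gb, b.data.shape))

    return _make(out_data, (a, b), backward)


def tsum(a, axis=None, keepdims=False):
    a = _t(a)
    out_data = a.data.sum(axis=axis, keepdims=keepdims)

    def backward(g):
        if not a.requires_grad:
            return
        if axis is None:
            a._accum(np.broadcast_to(g, a.data.shape))
        else:
            if not keepdims:
                g = np.expand_dims(g, axis)
            a._accum(np.broadcast_to(g, a.data.shape).copy())

    return _make(out_data, (a,), backward)


def tmean(a, axis=None, keepdims=False):
    a = _t(a)
    if axis is None:
        n = a.data.size
    else:
        axes = axis if isinstance(axis, tuple) else (axis,)
        n = int(np.prod([a.data.shape[ax] for ax in axes]))
    return mul(tsum(a, axis, keepdims), 1.0 / n)


def exp(a):
    a = _t(a)
    out_data = np.exp(a.data)

    def backward(g):
        if a.requires_grad:
            a._accum(g * out_data)

    return _make(out_data, (a,), backward)


def log(a):
    a = _t(a)
    out_data = np.log(a.data)

    def backward(g):
        if a.requires_grad:
            a._accum(g / a.data)

    return _make(out_data, (a,), backward)


def sqrt(a):
    a = _t(a)
    out_data = np.sqrt(a.data)

    def backward(g):
        if a.requires_grad:
            a._accum(g * (0.5 / out_data))

    return _make(out_data, (a,), backward)


def tanh(a):
    a = _t(a)
    out_data = np.tanh(a.data)

    def backward(g):
        if a.requires_grad:
            a._accum(g * (1.0 - out_data * out_data))

    return _make(out_data, (a,), backward)


def leaky_relu(a, slope: float = 0.2):
    a = _t(a)
    mask = a.data >= 0
    out_data = np.where(mask, a.data, slope * a.data)

    def backward(g):
        if a.requires_grad:
            a._accum(g * np.where(mask, 1.0, slope).astype(DTYPE))

    return _make(out_data, (a,), backward)


def gelu(a):
    """tanh-approximation GELU."""
    a = _t(a)
    c = np.float32(np.sqrt(2.0 / np.pi))
    x = a.data
    inner = c * (x + 0.044715 * x ** 3)
    t = np.tanh(inner)
    out_data = 0.5 * x * (1.0 + t)

    def backward(g):
        if a.requires_grad:
            dinner = c * (1.0 + 3 * 0.044715 * x ** 2)
            da = 0.5 * (1.0 + t) + 0.5 * x * (1.0 - t * t) * dinner
            a._accum(g * da)

    return _make(out_data, (a,), backward)


def reshape(a, shape):
    a = _t(a)
    out_data = a.data.reshape(shape)

    def backward(g):
        if a.requires_grad:
            a._accum(g.reshape(a.data.shape))

    return _make(out_data, (a,), backward)


def transpose(a, axes=None):
    a = _t(a)
    out_data = np.transpose(a.data, axes)
    if axes is None:
        inv = None
    else:
        inv = tuple(np.argsort(axes))

    def backward(g):
        if a.requires_grad:
            a._accum(np.transpose(g, inv))

    return _make(out_data, (a,), backward)


def getitem(a, idx):
    a = _t(a)
    out_data = a.data[idx]

    def backward(g):
        if a.requires_grad:
            ga = np.zeros_like(a.data)
            np.add.at(ga, idx, g)
            a._accum(ga)

    return _make(out_data, (a,), backward)


def concat(tensors, axis=0):
    tensors = [_t(x) for x in tensors]
    out_data = np.concatenate([x.data for x in tensors], axis=axis)
    sizes = [x.data.shape[axis] for x in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for x, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if x.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                x._accum(g[tuple(sl)])

    return _make(out_data, tensors, backward)


def _pad_index(n: int, p: int, mode: str) -> np.ndarray:
    """Source index for each position of a 1-D axis padded by p on both sides."""
    idx = np.arange(-p, n + p)
    if mode == "reflect":
        # mirror without repeating the edge sample
        idx = np.abs(idx)
        idx = np.where(idx >= n, 2 * (n - 1) - idx, idx)
    elif mode == "edge":
        idx = np.clip(idx, 0, n - 1)
    else:
        raise ValueError(mode)
    return idx


def pad2d(a, ph: int, pw: int, mode: str = "constant"):
    """Pad the last two axes of ``a`` by (ph, pw) on both sides."""
    a = _t(a)
    if ph == 0 and pw == 0:
        return a
    width = [(0, 0)] * (a.ndim - 2) + [(ph, ph), (pw, pw)]
    H, W = a.data.shape[-2:]
    if mode == "constant":
        out_data = np.pad(a.data, width, mode="constant")

        def backward(g):
            if a.requires_grad:
                a._accum(g[..., ph:ph + H, pw:pw + W])

    else:
        out_data = np.pad(a.data, width, mode=mode)
        # 0/1 selection matrices; backward is their transpose applied to g
        Sr = np.zeros((H + 2 * ph, H), dtype=DTYPE)
        Sr[np.arange(H + 2 * ph), _pad_index(H, ph, mode)] = 1.0
        Sc = np.zeros((W + 2 * pw, W), dtype=DTYPE)
        Sc[np.arange(W + 2 * pw), _pad_index(W, pw, mode)] = 1.0

        def backward(g):
            if a.requires_grad:
                a._accum(Sr.T @ g @ Sc)

    return _make(out_data, (a,), backward)


def softmax(a, axis=-1):
    a = _t(a)
    shifted = a.data - a.data.max(axis=axis, keepdims=True)
    e = np.exp(shifted)
    out_data = e / e.sum(axis=axis, keepdims=True)

    def backward(g):
        if a.requires_grad:
            dot = (g * out_data).sum(axis=axis, keepdims=True)
            a._accum(out_data * (g - dot))

    return _make(out_data, (a,), backward)


def clip_value(a, lo: float, hi: float):
    a = _t(a)
    out_data = np.clip(a.data, lo, hi)
    mask = ((a.data >= lo) & (a.data <= hi)).astype(DTYPE)

    def backward(g):
        if a.requires_grad:
            a._accum(g * mask)

    return _make(out_data, (a,), backward)
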