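"""Minimal reverse-mode automatic differentiation over numpy arrays.

Just enough machinery for the encoder-decoder model in this package:
broadcasting arithmetic, matmul, pointwise nonlinearities, reductions,
concatenation, row gather/scatter (for embeddings and message passing)
and a numerically stable log-softmax. All floating math is float32.

Gradient correctness is established by finite-difference checks in the
test suite rather than by construction, so keep ops simple and explicit.
"""

from __future__ import annotations

import numpy as np

DTYPE = np.float32


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum a broadcast gradient back down to `shape`."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, size in enumerate(shape):
        if size == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad: bool = False, prev=()):
        self.data = np.asarray(data, dtype=DTYPE)
        self.grad = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in prev)
        self._backward = None
        self._prev = prev

    # -- helpers ---------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    def _accum(self, g):
        if self.grad is None:
            self.grad = np.zeros_like(self.data, dtype=np.float64)
        self.grad += g

    @staticmethod
    def _wrap(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=DTYPE))

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    # -- arithmetic ------------------------------------------------------
    def __add__(self, other):
        other = self._wrap(other)
        out = Tensor(self.data + other.data, prev=(self, other))

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.shape))
        out._backward = backward
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, prev=(self,))
        out._backward = lambda g: self.requires_grad and self._accum(-g)
        return out

    def __sub__(self, other):
        return self + (-self._wrap(other))

    def __rsub__(self, other):
        return self._wrap(other) + (-self)

    def __mul__(self, other):
        other = self._wrap(other)
        out = Tensor(self.data * other.data, prev=(self, other))

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.shape))
        out._backward = backward
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        if isinstance(other, Tensor):
            raise TypeError("division by Tensor not supported; multiply by reciprocal")
        return self * (1.0 / float(other))

    def __matmul__(self, other):
        other = self._wrap(other)
        out = Tensor(self.data @ other.data, prev=(self, other))

        def backward(g):
            if self.requires_grad:
                self._accum(g @ other.data.T)
            if other.requires_grad:
                other._accum(self.data.T @ g)
        out._backward = backward
        return out

    # -- nonlinearities --------------------------------------------------
    def tanh(self):
        y = np.tanh(self.data)
        out = Tensor(y, prev=(self,))
        out._backward = lambda g: self.requires_grad and self._accum(g * (1.0 - y * y))
        return out

    def sigmoid(self):
        x = np.clip(self.data, -60.0, 60.0)
        y = 1.0 / (1.0 + np.exp(-x))
        out = Tensor(y, prev=(self,))
        out._backward = lambda g: self.requires_grad and self._accum(g * y * (1.0 - y))
        return out

    def relu(self):
        mask = self.data > 0
        out = Tensor(self.data * mask, prev=(self,))
        out._backward = lambda g: self.requires_grad and self._accum(g * mask)
        return out

    def exp(self):
        y = np.exp(self.data)
        out = Tensor(y, prev=(self,))
        out._backward = lambda g: self.requires_grad and self._accum(g * y)
        return out

    def log(self):
        out = Tensor(np.log(self.data), prev=(self,))
        out._backward = lambda g: self.requires_grad and self._accum(g / self.data)
        return out

    # -- reductions / reshaping -----------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), prev=(self,))

        def backward(g):
            if not self.requires_grad:
                return
            if axis is None:
                self._accum(np.broadcast_to(g, self.shape).copy())
            else:
                gg = g if keepdims else np.expand_dims(g, axis)
                self._accum(np.broadcast_to(gg, self.shape).copy())
        out._backward = backward
        return out

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) / n

    def reshape(self, *shape):
        out = Tensor(self.data.reshape(*shape), prev=(self,))
        out._backward = lambda g: self.requires_grad and self._accum(g.reshape(self.shape))
        return out

    def __getitem__(self, key):
        out = Tensor(self.data[key], prev=(self,))

        def backward(g):
            if self.requires_grad:
                full = np.zeros(self.shape, dtype=np.float64)
                np.add.at(full, key, g)
                self._accum(full)
        out._backward = backward
        return out

    def gather_rows(self, idx: np.ndarray):
        """Rows self[idx]; duplicated indices accumulate gradient."""
        idx = np.asarray(idx)
        out = Tensor(self.data[idx], prev=(self,))

        def backward(g):
            if self.requires_grad:
                full = np.zeros(self.shape, dtype=np.float64)
                np.add.at(full, idx, g)
                self._accum(full)
        out._backward = backward
        return out

    # -- softmax family --------------------------------------------------
    def log_softmax(self, axis: int = -1):
        shift = self.data.max(axis=axis, keepdims=True)  # constant shift
        z = self - Tensor(shift)
        lse = z.exp().sum(axis=axis, keepdims=True).log()
        return z - lse

    def softmax(self, axis: int = -1):
        return self.log_softmax(axis=axis).exp()

    # -- backprop --------------------------------------------------------
    def backward(self):
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar output")
        topo, seen = [], set()

        def build(t):
            if id(t) in seen:
                return
            seen.add(id(t))
            for p in t._prev:
                build(p)
            topo.append(t)
        build(self)
        self.grad = np.ones_like(self.data, dtype=np.float64)
        for t in reversed(topo):
            if t._backward is not None and t.requires_grad:
                t._backward(t.grad if t.grad is not None else np.zeros_like(t.data, dtype=np.float64))


def concat(tensors: list[Tensor], axis: int = -1) -> Tensor:
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis), prev=tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._accum(g[tuple(sl)])
    out._backward = backward
    return out


def scatter_add(src: Tensor, idx: np.ndarray, n_rows: int) -> Tensor:
    """out[idx[e]] += src[e] — the aggregation step of message passing."""
    idx = np.asarray(idx)
    data = np.zeros((n_rows,) + src.data.shape[1:], dtype=DTYPE)
    np.add.at(data, idx, src.data)
    out = Tensor(data, prev=(src,))
    out._backward = lambda g: src.requires_grad and src._accum(g[idx])
    return out


def zeros(*shape) -> Tensor:
    return Tensor(np.zeros(shape, dtype=DTYPE))


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(data, requires_grad=True)


def glorot(rng: np.random.Generator, fan_in: int, fan_out: int, shape=None) -> Parameter:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    shape = shape or (fan_in, fan_out)
    return Parameter(rng.uniform(-limit, limit, size=shape))
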