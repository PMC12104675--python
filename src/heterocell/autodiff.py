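"""Minimal reverse-mode automatic differentiation over numpy arrays.

Supports exactly the operations the graph neural networks in
:mod:`heterocell.models` need: dense and sparse matrix products, elementwise
nonlinearities, row gather / segment-sum scatter (for edge-wise message
passing), concatenation, and fused classification losses. Gradients are
accumulated by topological traversal of the operation graph; correctness is
checked against numeric differentiation in the test suite.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp

__all__ = [
    "Tensor",
    "parameter",
    "concat",
    "gather",
    "segment_sum",
    "spmm",
    "softmax_cross_entropy",
    "bce_with_logits",
    "Adam",
    "uniform_fan_in",
]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` over axes that were broadcast from `shape`."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """A numpy array plus the closure that propagates its gradient."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad=False, parents=(), backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = bool(requires_grad) or any(
            p.requires_grad for p in parents
        )
        self._parents = parents
        self._backward = backward
        self.grad = None

    @property
    def shape(self):
        return self.data.shape

    # -- graph traversal ----------------------------------------------------

    def backward(self):
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar tensor")
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        for t in topo:
            t.grad = np.zeros_like(t.data)
        self.grad = np.ones_like(self.data)
        for t in reversed(topo):
            if t._backward is not None:
                t._backward(t.grad)

    # -- elementwise arithmetic ---------------------------------------------

    def _coerce(self, other):
        return other if isinstance(other, Tensor) else Tensor(other)

    def __add__(self, other):
        other = self._coerce(other)
        out = Tensor(self.data + other.data, parents=(self, other))

        def bw(g):
            if self.requires_grad:
                self.grad += _unbroadcast(g, self.data.shape)
            if other.requires_grad:
                other.grad += _unbroadcast(g, other.data.shape)

        out._backward = bw
        return out

    __radd__ = __add__

    def __neg__(self):
        return self * -1.0

    def __sub__(self, other):
        return self + (-self._coerce(other))

    def __rsub__(self, other):
        return self._coerce(other) + (-self)

    def __mul__(self, other):
        other = self._coerce(other)
        out = Tensor(self.data * other.data, parents=(self, other))

        def bw(g):
            if self.requires_grad:
                self.grad += _unbroadcast(g * other.data, self.data.shape)
            if other.requires_grad:
                other.grad += _unbroadcast(g * self.data, other.data.shape)

        out._backward = bw
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._coerce(other)
        out = Tensor(self.data / other.data, parents=(self, other))

        def bw(g):
            if self.requires_grad:
                self.grad += _unbroadcast(g / other.data, self.data.shape)
            if other.requires_grad:
                other.grad += _unbroadcast(
                    -g * self.data / other.data**2, other.data.shape
                )

        out._backward = bw
        return out

    def __matmul__(self, other):
        other = self._coerce(other)
        out = Tensor(self.data @ other.data, parents=(self, other))

        def bw(g):
            if self.requires_grad:
                self.grad += g @ other.data.T
            if other.requires_grad:
                other.grad += self.data.T @ g

        out._backward = bw
        return out

    # -- nonlinearities ------------------------------------------------------

    def relu(self):
        mask = self.data > 0
        out = Tensor(self.data * mask, parents=(self,))

        def bw(g):
            if self.requires_grad:
                self.grad += g * mask

        out._backward = bw
        return out

    def leaky_relu(self, alpha: float = 0.2):
        slope = np.where(self.data > 0, 1.0, alpha)
        out = Tensor(self.data * slope, parents=(self,))

        def bw(g):
            if self.requires_grad:
                self.grad += g * slope

        out._backward = bw
        return out

    def sigmoid(self):
        s = 1.0 / (1.0 + np.exp(-np.clip(self.data, -60, 60)))
        out = Tensor(s, parents=(self,))

        def bw(g):
            if self.requires_grad:
                self.grad += g * s * (1.0 - s)

        out._backward = bw
        return out

    def exp(self):
        e = np.exp(np.clip(self.data, -700, 700))
        out = Tensor(e, parents=(self,))

        def bw(g):
            if self.requires_grad:
                self.grad += g * e

        out._backward = bw
        return out

    def log(self):
        out = Tensor(np.log(self.data), parents=(self,))

        def bw(g):
            if self.requires_grad:
                self.grad += g / self.data

        out._backward = bw
        return out

    def sum(self):
        out = Tensor(self.data.sum(), parents=(self,))

        def bw(g):
            if self.requires_grad:
                self.grad += np.full_like(self.data, float(g))

        out._backward = bw
        return out

    def mean(self):
        return self.sum() * (1.0 / self.data.size)


def parameter(data) -> Tensor:
    return Tensor(np.array(data, dtype=np.float64), requires_grad=True)


def concat(tensors, axis: int = 1) -> Tensor:
    tensors = list(tensors)
    out = Tensor(
        np.concatenate([t.data for t in tensors], axis=axis), parents=tuple(tensors)
    )
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bw(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t.grad += g[tuple(sl)]

    out._backward = bw
    return out


def gather(t: Tensor, idx: np.ndarray) -> Tensor:
    """Row selection t[idx]; the gradient scatter-adds back."""
    idx = np.asarray(idx, dtype=np.int64)
    out = Tensor(t.data[idx], parents=(t,))

    def bw(g):
        if t.requires_grad:
            np.add.at(t.grad, idx, g)

    out._backward = bw
    return out


def segment_sum(t: Tensor, segment_ids: np.ndarray, num_segments: int) -> Tensor:
    """Sum rows of `t` into `num_segments` buckets; gradient is a gather."""
    segment_ids = np.asarray(segment_ids, dtype=np.int64)
    acc = np.zeros((num_segments,) + t.data.shape[1:], dtype=np.float64)
    np.add.at(acc, segment_ids, t.data)
    out = Tensor(acc, parents=(t,))

    def bw(g):
        if t.requires_grad:
            t.grad += g[segment_ids]

    out._backward = bw
    return out


def spmm(matrix: sp.spmatrix, t: Tensor) -> Tensor:
    """Product of a constant sparse matrix with a dense tensor."""
    m = matrix.tocsr()
    out = Tensor(m @ t.data, parents=(t,))

    def bw(g):
        if t.requires_grad:
            t.grad += m.T @ g

    out._backward = bw
    return out


def softmax_cross_entropy(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean cross-entropy of row-wise softmax(logits) against integer labels."""
    labels = np.asarray(labels, dtype=np.int64)
    z = logits.data - logits.data.max(axis=1, keepdims=True)
    ez = np.exp(z)
    p = ez / ez.sum(axis=1, keepdims=True)
    n = logits.data.shape[0]
    nll = -np.mean(np.log(p[np.arange(n), labels] + 1e-300))
    out = Tensor(nll, parents=(logits,))

    def bw(g):
        if logits.requires_grad:
            d = p.copy()
            d[np.arange(n), labels] -= 1.0
            logits.grad += float(g) * d / n

    out._backward = bw
    return out


def bce_with_logits(logits: Tensor, targets: np.ndarray) -> Tensor:
    """Mean binary cross-entropy of sigmoid(logits) against 0/1 targets.

    Computed in the numerically stable log-sum-exp form.
    """
    y = np.asarray(targets, dtype=np.float64).reshape(logits.data.shape)
    x = logits.data
    loss = np.mean(np.maximum(x, 0) - x * y + np.log1p(np.exp(-np.abs(x))))
    out = Tensor(loss, parents=(logits,))

    def bw(g):
        if logits.requires_grad:
            s = 1.0 / (1.0 + np.exp(-np.clip(x, -60, 60)))
            logits.grad += float(g) * (s - y) / x.size

    out._backward = bw
    return out


def uniform_fan_in(rng: np.random.Generator, fan_in: int, shape) -> np.ndarray:
    """Uniform(-1/sqrt(fan_in), 1/sqrt(fan_in)) initialization."""
    bound = 1.0 / np.sqrt(max(fan_in, 1))
    return rng.uniform(-bound, bound, size=shape)


class Adam:
    """Adam with optional decoupled-from-nothing classic L2 weight decay."""

    def __init__(self, params, lr=0.01, weight_decay=0.0, betas=(0.9, 0.999), eps=1e-8):
        self.params = list(params)
        self.lr = lr
        self.weight_decay = weight_decay
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad + self.weight_decay * p.data
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
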