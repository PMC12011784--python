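"""Minimal reverse-mode automatic differentiation over numpy arrays.

Supports exactly the operations the transformer backbone and the fusion ANN
need: broadcasting arithmetic, (batched) matrix products, reshapes, slicing,
concatenation, ReLU/GELU, softmax, layer normalisation, reductions and a fused
softmax cross-entropy.  All computation is float64.

Gradients are accumulated by a topological backward sweep; every op records a
closure that adds its contribution into ``parent.grad``.  Broadcasting is
undone by summing gradients over the broadcast axes.
"""

from __future__ import annotations

import math
from typing import Iterable, Sequence

import numpy as np
from scipy.special import erf


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    """A numpy array with an optional gradient tape entry."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._parents: tuple[Tensor, ...] = ()
        self._backward = None

    # -- construction helpers ------------------------------------------------
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    # -- autodiff ------------------------------------------------------------
    def backward(self, grad: np.ndarray | None = None) -> None:
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, done = stack.pop()
            if done:
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
        self._accum(np.asarray(grad, dtype=np.float64))
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad)

    # -- operators -----------------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    def __radd__(self, other):
        return add(self, other)

    def __mul__(self, other):
        return mul(self, other)

    def __rmul__(self, other):
        return mul(self, other)

    def __sub__(self, other):
        return add(self, mul(other, -1.0))

    def __rsub__(self, other):
        return add(mul(self, -1.0), other)

    def __truediv__(self, other):
        if isinstance(other, Tensor):
            raise TypeError("tensor/tensor division not supported")
        return mul(self, 1.0 / float(other))

    def __matmul__(self, other):
        return matmul(self, other)

    def __getitem__(self, idx):
        return getitem(self, idx)

    def reshape(self, shape):
        return reshape(self, shape)

    def transpose(self, axes):
        return transpose(self, axes)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def parameter(data, rng: np.random.Generator | None = None, std: float | None = None) -> Tensor:
    """A trainable tensor; with ``std`` given, ``data`` is a shape tuple."""
    if std is not None:
        data = rng.normal(0.0, std, size=data)
    return Tensor(data, requires_grad=True)


def _make(data: np.ndarray, parents: Sequence[Tensor], backward) -> Tensor:
    out = Tensor(data)
    if any(p.requires_grad for p in parents):
        out.requires_grad = True
        out._parents = tuple(parents)
        out._backward = backward
    return out


# ---------------------------------------------------------------------------
# primitive ops
# ---------------------------------------------------------------------------

def add(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    out_data = a.data + b.data

    def backward(g):
        if a.requires_grad:
            a._accum(_unbroadcast(g, a.shape))
        if b.requires_grad:
            b._accum(_unbroadcast(g, b.shape))

    return _make(out_data, (a, b), backward)


def mul(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    out_data = a.data * b.data

    def backward(g):
        if a.requires_grad:
            a._accum(_unbroadcast(g * b.data, a.shape))
        if b.requires_grad:
            b._accum(_unbroadcast(g * a.data, b.shape))

    return _make(out_data, (a, b), backward)


def matmul(a, b) -> Tensor:
    """Batched matrix product with broadcasting over leading axes."""
    a, b = as_tensor(a), as_tensor(b)
    out_data = a.data @ b.data

    def backward(g):
        if a.requires_grad:
            ga = g @ np.swapaxes(b.data, -1, -2)
            a._accum(_unbroadcast(ga, a.shape))
        if b.requires_grad:
            gb = np.swapaxes(a.data, -1, -2) @ g
            b._accum(_unbroadcast(gb, b.shape))

    return _make(out_data, (a, b), backward)


def reshape(a, shape) -> Tensor:
    a = as_tensor(a)
    out_data = a.data.reshape(shape)

    def backward(g):
        a._accum(g.reshape(a.shape))

    return _make(out_data, (a,), backward)


def transpose(a, axes) -> Tensor:
    a = as_tensor(a)
    axes = tuple(axes)
    inv = tuple(np.argsort(axes))
    out_data = a.data.transpose(axes)

    def backward(g):
        a._accum(g.transpose(inv))

    return _make(out_data, (a,), backward)


def broadcast_to(a, shape) -> Tensor:
    a = as_tensor(a)
    out_data = np.broadcast_to(a.data, shape).copy()

    def backward(g):
        a._accum(_unbroadcast(g, a.shape))

    return _make(out_data, (a,), backward)


def concat(tensors: Iterable[Tensor], axis: int = 0) -> Tensor:
    ts = [as_tensor(t) for t in tensors]
    out_data = np.concatenate([t.data for t in ts], axis=axis)
    sizes = [t.shape[axis] for t in ts]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(ts, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                idx = [slice(None)] * g.ndim
                idx[axis] = slice(lo, hi)
                t._accum(g[tuple(idx)])

    return _make(out_data, ts, backward)


def getitem(a, idx) -> Tensor:
    a = as_tensor(a)
    out_data = a.data[idx]

    def backward(g):
        full = np.zeros_like(a.data)
        np.add.at(full, idx, g)
        a._accum(full)

    return _make(out_data, (a,), backward)


def relu(a) -> Tensor:
    a = as_tensor(a)
    mask = a.data > 0
    out_data = a.data * mask

    def backward(g):
        a._accum(g * mask)

    return _make(out_data, (a,), backward)


def gelu(a) -> Tensor:
    """Exact (erf-based) Gaussian error linear unit."""
    a = as_tensor(a)
    x = a.data
    cdf = 0.5 * (1.0 + erf(x / math.sqrt(2.0)))
    out_data = x * cdf

    def backward(g):
        pdf = np.exp(-0.5 * x * x) / math.sqrt(2.0 * math.pi)
        a._accum(g * (cdf + x * pdf))

    return _make(out_data, (a,), backward)


def softmax(a, axis: int = -1) -> Tensor:
    a = as_tensor(a)
    z = a.data - a.data.max(axis=axis, keepdims=True)
    e = np.exp(z)
    y = e / e.sum(axis=axis, keepdims=True)

    def backward(g):
        dot = (g * y).sum(axis=axis, keepdims=True)
        a._accum(y * (g - dot))

    return _make(y, (a,), backward)


def layer_norm(a, gamma, beta, eps: float = 1e-6) -> Tensor:
    """Normalise over the last axis; affine transform by gamma/beta."""
    a, gamma, beta = as_tensor(a), as_tensor(gamma), as_tensor(beta)
    mu = a.data.mean(axis=-1, keepdims=True)
    var = a.data.var(axis=-1, keepdims=True)
    sigma = np.sqrt(var + eps)
    xhat = (a.data - mu) / sigma
    out_data = gamma.data * xhat + beta.data

    def backward(g):
        if gamma.requires_grad:
            gamma._accum(_unbroadcast(g * xhat, gamma.shape))
        if beta.requires_grad:
            beta._accum(_unbroadcast(g, beta.shape))
        if a.requires_grad:
            gx = g * gamma.data
            m1 = gx.mean(axis=-1, keepdims=True)
            m2 = (gx * xhat).mean(axis=-1, keepdims=True)
            a._accum((gx - m1 - xhat * m2) / sigma)

    return _make(out_data, (a, gamma, beta), backward)


def sum_(a, axis=None) -> Tensor:
    a = as_tensor(a)
    out_data = a.data.sum(axis=axis)

    def backward(g):
        if axis is None:
            a._accum(np.full_like(a.data, g))
        else:
            a._accum(np.broadcast_to(np.expand_dims(g, axis), a.shape).copy())

    return _make(out_data, (a,), backward)


def mean_(a, axis=None) -> Tensor:
    a = as_tensor(a)
    n = a.data.size if axis is None else a.shape[axis]
    return mul(sum_(a, axis=axis), 1.0 / n)


def cross_entropy(logits: Tensor, targets: np.ndarray) -> Tensor:
    """Mean softmax cross-entropy; ``targets`` are integer class indices."""
    logits = as_tensor(logits)
    t = np.asarray(targets, dtype=np.intp)
    z = logits.data - logits.data.max(axis=-1, keepdims=True)
    logp = z - np.log(np.exp(z).sum(axis=-1, keepdims=True))
    n = t.shape[0]
    loss = -logp[np.arange(n), t].mean()

    def backward(g):
        p = np.exp(logp)
        p[np.arange(n), t] -= 1.0
        logits._accum(g * p / n)

    return _make(np.float64(loss), (logits,), backward)


def linear(x, w, b=None) -> Tensor:
    out = matmul(x, w)
    if b is not None:
        out = add(out, b)
    return out


# ---------------------------------------------------------------------------
# optimiser
# ---------------------------------------------------------------------------

class Adam:
    """Adaptive-moment gradient descent over a list of parameters."""

    def __init__(self, params: Iterable[Tensor], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
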