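"""Minimal reverse-mode automatic differentiation over numpy arrays.

The recurrent encoder-decoder in this package needs gradients through a few
thousand small dense operations per batch (GRU steps, attention products,
two heads, masked losses).  This module provides exactly the primitives that
model uses: elementwise arithmetic with broadcasting, 2-D matmul, the two
batched attention contractions, concatenation/stacking, the activation
functions, and reductions.  Gradients are accumulated by topological sweep
over the recorded tape; correctness is pinned by central-difference checks
in the test suite.
"""

from __future__ import annotations

import contextlib

import numpy as np

_GRAD_ENABLED = True


@contextlib.contextmanager
def no_grad():
    """Disable tape recording (inference / evaluation)."""
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (reverse of numpy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, s in enumerate(shape):
        if s == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "parents", "_backward", "requires_grad")

    # make numpy defer to the reflected operators instead of broadcasting
    __array_ufunc__ = None

    def __init__(self, data, parents=(), backward=None, requires_grad=False):
        self.data = np.asarray(data, dtype=float)
        self.grad = None
        self.parents = parents
        self._backward = backward
        self.requires_grad = requires_grad

    @property
    def shape(self):
        return self.data.shape

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # -- graph ------------------------------------------------------------
    def backward(self, grad=None):
        # iterative post-order DFS: graphs span thousands of recurrent steps
        topo, seen = [], set()
        stack = [(self, False)]
        while stack:
            t, expanded = stack.pop()
            if not t.requires_grad:
                continue
            if expanded:
                topo.append(t)
                continue
            if id(t) in seen:
                continue
            seen.add(id(t))
            stack.append((t, True))
            for p in t.parents:
                if id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data) if grad is None else np.asarray(grad, dtype=float)
        for t in reversed(topo):
            if t._backward is not None and t.grad is not None:
                t._backward(t.grad)

    def _accumulate(self, grad):
        if self.grad is None:
            self.grad = grad.copy()
        else:
            self.grad += grad

    # -- operators ---------------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __sub__(self, other):
        return add(self, mul(other, -1.0))

    def __rsub__(self, other):
        return add(mul(self, -1.0), other)

    def __matmul__(self, other):
        return matmul(self, other)

    def item(self):
        return float(self.data)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _make(data, parents, backward):
    req = _GRAD_ENABLED and any(p.requires_grad for p in parents)
    if not req:
        return Tensor(data)
    return Tensor(data, parents=tuple(parents), backward=backward, requires_grad=True)


def add(a, b):
    a, b = as_tensor(a), as_tensor(b)
    out_data = a.data + b.data

    def backward(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g, a.data.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(g, b.data.shape))

    return _make(out_data, (a, b), backward)


def mul(a, b):
    a, b = as_tensor(a), as_tensor(b)
    out_data = a.data * b.data

    def backward(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g * b.data, a.data.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(g * a.data, b.data.shape))

    return _make(out_data, (a, b), backward)


def matmul(a, b):
    a, b = as_tensor(a), as_tensor(b)
    out_data = a.data @ b.data

    def backward(g):
        if a.requires_grad:
            a._accumulate(g @ b.data.T)
        if b.requires_grad:
            b._accumulate(a.data.T @ g)

    return _make(out_data, (a, b), backward)


def concat(tensors, axis=-1):
    tensors = [as_tensor(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, o, s in zip(tensors, offsets, sizes):
            if t.requires_grad:
                idx = [slice(None)] * g.ndim
                idx[axis] = slice(o, o + s)
                t._accumulate(g[tuple(idx)])

    return _make(out_data, tensors, backward)


def stack(tensors, axis=0):
    tensors = [as_tensor(t) for t in tensors]
    out_data = np.stack([t.data for t in tensors], axis=axis)

    def backward(g):
        parts = np.moveaxis(g, axis, 0)
        for t, gp in zip(tensors, parts):
            if t.requires_grad:
                t._accumulate(gp)

    return _make(out_data, tensors, backward)


def sigmoid(x):
    x = as_tensor(x)
    s = 1.0 / (1.0 + np.exp(-x.data))

    def backward(g):
        if x.requires_grad:
            x._accumulate(g * s * (1.0 - s))

    return _make(s, (x,), backward)


def tanh(x):
    x = as_tensor(x)
    t = np.tanh(x.data)

    def backward(g):
        if x.requires_grad:
            x._accumulate(g * (1.0 - t * t))

    return _make(t, (x,), backward)


def elu(x, alpha=1.0):
    x = as_tensor(x)
    neg = alpha * (np.exp(np.minimum(x.data, 0.0)) - 1.0)
    out_data = np.where(x.data > 0, x.data, neg)

    def backward(g):
        if x.requires_grad:
            x._accumulate(g * np.where(x.data > 0, 1.0, neg + alpha))

    return _make(out_data, (x,), backward)


def softmax(x, axis=-1):
    x = as_tensor(x)
    z = x.data - x.data.max(axis=axis, keepdims=True)
    e = np.exp(z)
    s = e / e.sum(axis=axis, keepdims=True)

    def backward(g):
        if x.requires_grad:
            dot = (g * s).sum(axis=axis, keepdims=True)
            x._accumulate(s * (g - dot))

    return _make(s, (x,), backward)


def log_clipped(x, eps=1e-8):
    """log(max(x, eps)); gradient is zero where clipping is active."""
    x = as_tensor(x)
    clipped = np.maximum(x.data, eps)
    out_data = np.log(clipped)

    def backward(g):
        if x.requires_grad:
            x._accumulate(g * np.where(x.data > eps, 1.0 / clipped, 0.0))

    return _make(out_data, (x,), backward)


def reduce_sum(x, axis=None):
    x = as_tensor(x)
    out_data = x.data.sum(axis=axis)

    def backward(g):
        if x.requires_grad:
            if axis is None:
                x._accumulate(np.broadcast_to(g, x.data.shape).copy())
            else:
                x._accumulate(np.broadcast_to(np.expand_dims(g, axis), x.data.shape).copy())

    return _make(out_data, (x,), backward)


def reduce_mean(x, axis=None):
    n = x.data.size if axis is None else x.data.shape[axis]
    return mul(reduce_sum(x, axis=axis), 1.0 / n)


def time_index(x, t: int):
    """Select step ``t`` along axis 1: (N, L, H) -> (N, H)."""
    x = as_tensor(x)
    out_data = x.data[:, t, :]

    def backward(g):
        if x.requires_grad:
            full = np.zeros_like(x.data)
            full[:, t, :] = g
            x._accumulate(full)

    return _make(out_data, (x,), backward)


def linear3(x, W, b=None):
    """Dense layer over the last axis of a (N, T, i) tensor."""
    x, W = as_tensor(x), as_tensor(W)
    out_data = x.data @ W.data
    if b is not None:
        b = as_tensor(b)
        out_data = out_data + b.data
    parents = (x, W) if b is None else (x, W, b)

    def backward(g):
        if x.requires_grad:
            x._accumulate(g @ W.data.T)
        if W.requires_grad:
            W._accumulate(np.einsum("nti,nto->io", x.data, g))
        if b is not None and b.requires_grad:
            b._accumulate(g.sum(axis=(0, 1)))

    return _make(out_data, parents, backward)


def attention_scores3(q, enc):
    """Batched scores for all decoder steps: (N,T,H) x (N,L,H) -> (N,T,L)."""
    q, enc = as_tensor(q), as_tensor(enc)
    out_data = np.einsum("nth,nlh->ntl", q.data, enc.data)

    def backward(g):
        if q.requires_grad:
            q._accumulate(np.einsum("ntl,nlh->nth", g, enc.data))
        if enc.requires_grad:
            enc._accumulate(np.einsum("ntl,nth->nlh", g, q.data))

    return _make(out_data, (q, enc), backward)


def attention_context3(a, enc):
    """Batched contexts for all decoder steps: (N,T,L) x (N,L,H) -> (N,T,H)."""
    a, enc = as_tensor(a), as_tensor(enc)
    out_data = np.einsum("ntl,nlh->nth", a.data, enc.data)

    def backward(g):
        if a.requires_grad:
            a._accumulate(np.einsum("nth,nlh->ntl", g, enc.data))
        if enc.requires_grad:
            enc._accumulate(np.einsum("ntl,nth->nlh", a.data, g))

    return _make(out_data, (a, enc), backward)


def attention_scores(q, enc):
    """Batched score contraction: (N,H) x (N,L,H) -> (N,L)."""
    q, enc = as_tensor(q), as_tensor(enc)
    out_data = np.einsum("nh,nlh->nl", q.data, enc.data)

    def backward(g):
        if q.requires_grad:
            q._accumulate(np.einsum("nl,nlh->nh", g, enc.data))
        if enc.requires_grad:
            enc._accumulate(np.einsum("nl,nh->nlh", g, q.data))

    return _make(out_data, (q, enc), backward)


def attention_context(a, enc):
    """Weighted sum over encoder steps: (N,L) x (N,L,H) -> (N,H)."""
    a, enc = as_tensor(a), as_tensor(enc)
    out_data = np.einsum("nl,nlh->nh", a.data, enc.data)

    def backward(g):
        if a.requires_grad:
            a._accumulate(np.einsum("nh,nlh->nl", g, enc.data))
        if enc.requires_grad:
            enc._accumulate(np.einsum("nl,nh->nlh", a.data, g))

    return _make(out_data, (a, enc), backward)


class Parameter(Tensor):
    __slots__ = ("name",)

    def __init__(self, data, name=""):
        super().__init__(data, requires_grad=True)
        self.name = name


class Adam:
    """Adam optimizer (beta1=0.9, beta2=0.999, eps=1e-8)."""

    def __init__(self, params, lr=1e-3, betas=(0.9, 0.999), eps=1e-8):
        self.params = list(params)
        self.lr = lr
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
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
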