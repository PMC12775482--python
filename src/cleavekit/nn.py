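"""Compact reverse-mode autodiff on NumPy arrays, with the layers used by the
cleavage-score predictor and the peptide generator: linear, layer norm,
multi-head self-attention (optionally causal), bidirectional LSTM, embeddings,
sinusoidal positional encodings, Adam, and the warmup/inverse-sqrt learning
rate schedule.

The engine is deliberately small: tensors wrap ``np.ndarray``; each op records
a backward closure; ``Tensor.backward`` runs reverse topological order.
Inference code paths run inside ``no_grad()`` and build no graph.
"""

from __future__ import annotations

import math
from contextlib import contextmanager

import numpy as np

_GRAD_ENABLED = True


@contextmanager
def no_grad():
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of NumPy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, dim in enumerate(shape):
        if dim == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad=False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self.requires_grad = requires_grad
        self._backward = None
        self._prev: tuple = ()

    # -- graph bookkeeping --------------------------------------------------

    @property
    def shape(self):
        return self.data.shape

    @staticmethod
    def _wrap(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    @staticmethod
    def _make(data, parents, backward) -> "Tensor":
        out = Tensor(data)
        if _GRAD_ENABLED and any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._prev = tuple(parents)
            out._backward = backward
        return out

    def _accum(self, grad):
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += grad

    def backward(self):
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for p in t._prev:
                visit(p)
            topo.append(t)

        visit(self)
        self.grad = np.ones_like(self.data)
        for t in reversed(topo):
            if t._backward is not None:
                t._backward(t.grad)

    # -- arithmetic ---------------------------------------------------------

    def __add__(self, other):
        other = self._wrap(other)

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.shape))

        return self._make(self.data + other.data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(g):
            if self.requires_grad:
                self._accum(-g)

        return self._make(-self.data, (self,), backward)

    def __sub__(self, other):
        return self + (-self._wrap(other))

    def __rsub__(self, other):
        return self._wrap(other) + (-self)

    def __mul__(self, other):
        other = self._wrap(other)

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.shape))

        return self._make(self.data * other.data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        if isinstance(other, Tensor):
            return self * other ** -1.0
        return self * (1.0 / other)

    def __pow__(self, exponent: float):
        def backward(g):
            if self.requires_grad:
                self._accum(g * exponent * self.data ** (exponent - 1))

        return self._make(self.data ** exponent, (self,), backward)

    def __matmul__(self, other):
        other = self._wrap(other)

        def backward(g):
            if self.requires_grad:
                ga = np.matmul(g, np.swapaxes(other.data, -1, -2))
                self._accum(_unbroadcast(ga, self.shape))
            if other.requires_grad:
                gb = np.matmul(np.swapaxes(self.data, -1, -2), g)
                other._accum(_unbroadcast(gb, other.shape))

        return self._make(np.matmul(self.data, other.data), (self, other), backward)

    # -- shape ops ----------------------------------------------------------

    def reshape(self, *shape):
        old = self.shape

        def backward(g):
            if self.requires_grad:
                self._accum(g.reshape(old))

        return self._make(self.data.reshape(*shape), (self,), backward)

    def transpose(self, *axes):
        inv = np.argsort(axes)

        def backward(g):
            if self.requires_grad:
                self._accum(g.transpose(*inv))

        return self._make(self.data.transpose(*axes), (self,), backward)

    def __getitem__(self, key):
        def backward(g):
            if self.requires_grad:
                full = np.zeros_like(self.data)
                np.add.at(full, key, g)
                self._accum(full)

        return self._make(self.data[key], (self,), backward)

    # -- reductions & nonlinearities ----------------------------------------

    def sum(self, axis=None, keepdims=False):
        def backward(g):
            if not self.requires_grad:
                return
            if axis is None:
                self._accum(np.broadcast_to(g, self.shape).copy())
            else:
                gg = g if keepdims else np.expand_dims(g, axis)
                self._accum(np.broadcast_to(gg, self.shape).copy())

        return self._make(self.data.sum(axis=axis, keepdims=keepdims), (self,), backward)

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) / n

    def relu(self):
        mask = self.data > 0

        def backward(g):
            if self.requires_grad:
                self._accum(g * mask)

        return self._make(self.data * mask, (self,), backward)

    def tanh(self):
        out_data = np.tanh(self.data)

        def backward(g):
            if self.requires_grad:
                self._accum(g * (1 - out_data ** 2))

        return self._make(out_data, (self,), backward)

    def sigmoid(self):
        out_data = 1.0 / (1.0 + np.exp(-self.data))

        def backward(g):
            if self.requires_grad:
                self._accum(g * out_data * (1 - out_data))

        return self._make(out_data, (self,), backward)


def concat(tensors: list[Tensor], axis: int = 0) -> Tensor:
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._accum(g[tuple(sl)])

    return Tensor._make(
        np.concatenate([t.data for t in tensors], axis=axis), tuple(tensors), backward
    )


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    shifted = x.data - x.data.max(axis=axis, keepdims=True)
    e = np.exp(shifted)
    out_data = e / e.sum(axis=axis, keepdims=True)

    def backward(g):
        if x.requires_grad:
            dot = (g * out_data).sum(axis=axis, keepdims=True)
            x._accum(out_data * (g - dot))

    return Tensor._make(out_data, (x,), backward)


def log_softmax(x: Tensor, axis: int = -1) -> Tensor:
    shifted = x.data - x.data.max(axis=axis, keepdims=True)
    lse = np.log(np.exp(shifted).sum(axis=axis, keepdims=True))
    out_data = shifted - lse
    sm = np.exp(out_data)

    def backward(g):
        if x.requires_grad:
            x._accum(g - sm * g.sum(axis=axis, keepdims=True))

    return Tensor._make(out_data, (x,), backward)


def layer_norm(x: Tensor, gamma: Tensor, beta: Tensor, eps: float = 1e-5) -> Tensor:
    mu = x.data.mean(axis=-1, keepdims=True)
    var = x.data.var(axis=-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mu) * inv
    out_data = xhat * gamma.data + beta.data
    D = x.data.shape[-1]

    def backward(g):
        if gamma.requires_grad:
            gamma._accum(_unbroadcast(g * xhat, gamma.shape))
        if beta.requires_grad:
            beta._accum(_unbroadcast(g, beta.shape))
        if x.requires_grad:
            gx = g * gamma.data
            term = gx - gx.mean(axis=-1, keepdims=True) \
                - xhat * (gx * xhat).mean(axis=-1, keepdims=True)
            x._accum(term * inv)

    return Tensor._make(out_data, (x, gamma, beta), backward)


def embedding(weight: Tensor, idx: np.ndarray) -> Tensor:
    idx = np.asarray(idx)

    def backward(g):
        if weight.requires_grad:
            full = np.zeros_like(weight.data)
            np.add.at(full, idx, g)
            weight._accum(full)

    return Tensor._make(weight.data[idx], (weight,), backward)


def dropout(x: Tensor, p: float, rng: np.random.Generator, train: bool) -> Tensor:
    if not train or p <= 0:
        return x
    mask = (rng.random(x.shape) >= p) / (1.0 - p)
    return x * Tensor(mask)


# ---------------------------------------------------------------------------
# Layers
# ---------------------------------------------------------------------------


class Module:
    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        for value in self.__dict__.values():
            if isinstance(value, Tensor) and value.requires_grad:
                params.append(value)
            elif isinstance(value, Module):
                params.extend(value.parameters())
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
                    elif isinstance(item, Tensor) and item.requires_grad:
                        params.append(item)
        return params

    def state_arrays(self) -> list[np.ndarray]:
        return [p.data for p in self.parameters()]

    def load_state_arrays(self, arrays) -> None:
        params = self.parameters()
        if len(arrays) != len(params):
            raise ValueError("checkpoint parameter count mismatch")
        for p, a in zip(params, arrays):
            p.data = np.array(a, dtype=np.float64)


class Linear(Module):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator, bias=True):
        scale = 1.0 / math.sqrt(n_in)
        self.W = Tensor(rng.normal(0, scale, size=(n_in, n_out)), requires_grad=True)
        self.b = Tensor(np.zeros(n_out), requires_grad=True) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        out = x @ self.W
        return out + self.b if self.b is not None else out


class LayerNorm(Module):
    def __init__(self, dim: int):
        self.gamma = Tensor(np.ones(dim), requires_grad=True)
        self.beta = Tensor(np.zeros(dim), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return layer_norm(x, self.gamma, self.beta)


class MultiHeadAttention(Module):
    """Self-attention with ``n_heads`` heads of width ``head_dim``.

    ``model_dim`` need not be divisible by ``n_heads``: the internal width is
    ``n_heads * head_dim`` with an output projection back to ``model_dim``
    (this preserves the printed head counts for model dims 32 and 64).
    """

    def __init__(self, model_dim, n_heads, rng, causal=False, head_dim=None):
        self.n_heads = n_heads
        self.head_dim = head_dim or max(1, model_dim // n_heads)
        inner = n_heads * self.head_dim
        self.causal = causal
        self.Wq = Linear(model_dim, inner, rng, bias=False)
        self.Wk = Linear(model_dim, inner, rng, bias=False)
        self.Wv = Linear(model_dim, inner, rng, bias=False)
        self.Wo = Linear(inner, model_dim, rng, bias=True)

    def __call__(self, x: Tensor, key_valid: np.ndarray | None = None) -> Tensor:
        B, T, _ = x.shape
        H, hd = self.n_heads, self.head_dim

        def split(t: Tensor) -> Tensor:
            return t.reshape(B, T, H, hd).transpose(0, 2, 1, 3)  # (B,H,T,hd)

        q, k, v = split(self.Wq(x)), split(self.Wk(x)), split(self.Wv(x))
        scores = (q @ k.transpose(0, 1, 3, 2)) * (1.0 / math.sqrt(hd))  # (B,H,T,T)
        bias = np.zeros((B, 1, T, T))
        if key_valid is not None:
            bias = bias + np.where(key_valid[:, None, None, :], 0.0, -1e9)
        if self.causal:
            bias = bias + np.where(np.tril(np.ones((T, T), dtype=bool)), 0.0, -1e9)
        att = softmax(scores + Tensor(bias), axis=-1)
        out = (att @ v).transpose(0, 2, 1, 3).reshape(B, T, H * hd)
        return self.Wo(out)


class TransformerBlock(Module):
    """Post-norm transformer block (attention + position-wise feed-forward)."""

    def __init__(self, model_dim, n_heads, ff_dim, rng, causal=False, head_dim=None):
        self.attn = MultiHeadAttention(model_dim, n_heads, rng, causal, head_dim)
        self.ln1 = LayerNorm(model_dim)
        self.ff1 = Linear(model_dim, ff_dim, rng)
        self.ff2 = Linear(ff_dim, model_dim, rng)
        self.ln2 = LayerNorm(model_dim)

    def __call__(self, x: Tensor, key_valid=None, dropout_p: float = 0.0,
                 rng: np.random.Generator | None = None, train: bool = False) -> Tensor:
        a = self.attn(x, key_valid)
        if train and dropout_p > 0:
            a = dropout(a, dropout_p, rng, train)
        x = self.ln1(x + a)
        f = self.ff2(self.ff1(x).relu())
        if train and dropout_p > 0:
            f = dropout(f, dropout_p, rng, train)
        return self.ln2(x + f)


class LSTM(Module):
    """Single-direction LSTM layer returning the full hidden sequence."""

    def __init__(self, n_in, n_hidden, rng, reverse=False):
        scale = 1.0 / math.sqrt(n_in + n_hidden)
        self.n_hidden = n_hidden
        self.reverse = reverse
        self.Wx = Tensor(rng.normal(0, scale, size=(n_in, 4 * n_hidden)), requires_grad=True)
        self.Wh = Tensor(rng.normal(0, scale, size=(n_hidden, 4 * n_hidden)), requires_grad=True)
        self.b = Tensor(np.zeros(4 * n_hidden), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        B, T, _ = x.shape
        H = self.n_hidden
        h = Tensor(np.zeros((B, H)))
        c = Tensor(np.zeros((B, H)))
        steps = range(T - 1, -1, -1) if self.reverse else range(T)
        outputs: list[Tensor | None] = [None] * T
        for t in steps:
            xt = x[:, t, :]
            gates = xt @ self.Wx + h @ self.Wh + self.b
            i = gates[:, 0:H].sigmoid()
            f = gates[:, H:2 * H].sigmoid()
            g = gates[:, 2 * H:3 * H].tanh()
            o = gates[:, 3 * H:4 * H].sigmoid()
            c = f * c + i * g
            h = o * c.tanh()
            outputs[t] = h.reshape(B, 1, H)
        return concat(outputs, axis=1)  # type: ignore[arg-type]


def sinusoidal_positions(T: int, D: int) -> np.ndarray:
    """Fixed sinusoidal positional encodings, shape (T, D)."""
    pos = np.arange(T)[:, None]
    i = np.arange(D)[None, :]
    angle = pos / np.power(10000.0, (2 * (i // 2)) / D)
    enc = np.where(i % 2 == 0, np.sin(angle), np.cos(angle))
    return enc


# ---------------------------------------------------------------------------
# Optimization
# ---------------------------------------------------------------------------


class Adam:
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


def lr_at_step(model_dim: int, step: int, warmup_steps: int = 4000) -> float:
    """Warmup/inverse-square-root schedule:
    ``model_dim^-0.5 * min(step^-0.5, step * warmup_steps^-1.5)``."""
    if step < 1:
        raise ValueError("step must be >= 1")
    if warmup_steps < 1:
        raise ValueError("warmup_steps must be >= 1")
    return model_dim ** -0.5 * min(step ** -0.5, step * warmup_steps ** -1.5)
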