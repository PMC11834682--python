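"""Differentiable building blocks (forward + hand-written backward).

Conventions: activations have shape ``(batch, time, features)``;
``forward(..., train=True)`` caches what backward needs; ``backward``
accumulates parameter gradients into ``Param.grad`` and returns the
gradient with respect to its input(s).  Attention masks are additive
(0 where attending is allowed, a large negative number where not).
"""

from __future__ import annotations

import math
from typing import Iterator, List, Optional, Tuple

import numpy as np

NEG_INF = -1e9


class Param:
    """A trainable array with its gradient accumulator."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = np.asarray(value, dtype=np.float64)
        self.grad = np.zeros_like(self.value)

    def zero_grad(self) -> None:
        self.grad[...] = 0.0


class Module:
    def params(self) -> Iterator[Tuple[str, Param]]:
        for name, attr in vars(self).items():
            if isinstance(attr, Param):
                yield name, attr
            elif isinstance(attr, Module):
                for sub, p in attr.params():
                    yield f"{name}.{sub}", p
            elif isinstance(attr, (list, tuple)):
                for i, item in enumerate(attr):
                    if isinstance(item, Module):
                        for sub, p in item.params():
                            yield f"{name}.{i}.{sub}", p

    def zero_grad(self) -> None:
        for _, p in self.params():
            p.zero_grad()


def softmax(x: np.ndarray, axis: int = -1) -> np.ndarray:
    z = x - x.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def log_softmax(x: np.ndarray, axis: int = -1) -> np.ndarray:
    z = x - x.max(axis=axis, keepdims=True)
    return z - np.log(np.exp(z).sum(axis=axis, keepdims=True))


def cross_entropy(
    logits: np.ndarray, targets: np.ndarray, mask: np.ndarray
) -> Tuple[float, np.ndarray]:
    """Masked token-level cross-entropy.

    Returns ``(mean loss over mask, dloss/dlogits)``.  ``logits`` is
    ``(B, T, V)``, ``targets`` and ``mask`` are ``(B, T)``; padding
    positions (mask 0) contribute neither loss nor gradient.
    """
    n = float(mask.sum())
    if n == 0:
        raise ValueError("cross_entropy: mask selects no tokens")
    logp = log_softmax(logits)
    b_idx, t_idx = np.nonzero(mask)
    loss = -logp[b_idx, t_idx, targets[b_idx, t_idx]].sum() / n
    grad = softmax(logits)
    grad[b_idx, t_idx, targets[b_idx, t_idx]] -= 1.0
    grad *= (mask / n)[..., None]
    return float(loss), grad


class Linear(Module):
    def __init__(self, rng: np.random.Generator, d_in: int, d_out: int):
        bound = math.sqrt(6.0 / (d_in + d_out))
        self.W = Param(rng.uniform(-bound, bound, size=(d_in, d_out)))
        self.b = Param(np.zeros(d_out))
        self._x: Optional[np.ndarray] = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.W.value + self.b.value

    def backward(self, g: np.ndarray) -> np.ndarray:
        x2 = self._x.reshape(-1, self._x.shape[-1])
        g2 = g.reshape(-1, g.shape[-1])
        self.W.grad += x2.T @ g2
        self.b.grad += g2.sum(axis=0)
        return g @ self.W.value.T


class LayerNorm(Module):
    def __init__(self, d: int, eps: float = 1e-5):
        self.gamma = Param(np.ones(d))
        self.beta = Param(np.zeros(d))
        self.eps = eps

    def forward(self, x: np.ndarray) -> np.ndarray:
        mu = x.mean(axis=-1, keepdims=True)
        var = x.var(axis=-1, keepdims=True)
        self._inv = 1.0 / np.sqrt(var + self.eps)
        self._xhat = (x - mu) * self._inv
        return self.gamma.value * self._xhat + self.beta.value

    def backward(self, g: np.ndarray) -> np.ndarray:
        xhat, inv = self._xhat, self._inv
        self.gamma.grad += (g * xhat).sum(axis=tuple(range(g.ndim - 1)))
        self.beta.grad += g.sum(axis=tuple(range(g.ndim - 1)))
        gx = g * self.gamma.value
        return inv * (
            gx
            - gx.mean(axis=-1, keepdims=True)
            - xhat * (gx * xhat).mean(axis=-1, keepdims=True)
        )


class Dropout(Module):
    """Inverted dropout; identity when ``train=False`` or rate 0."""

    def __init__(self, rate: float, rng: np.random.Generator):
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate
        self.rng = rng
        self._mask: Optional[np.ndarray] = None

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if not train or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep) / keep
        return x * self._mask

    def backward(self, g: np.ndarray) -> np.ndarray:
        return g if self._mask is None else g * self._mask


def sinusoidal_positions(max_len: int, d: int) -> np.ndarray:
    pos = np.arange(max_len)[:, None]
    i = np.arange(d // 2)[None, :]
    angles = pos / np.power(10000.0, 2 * i / d)
    pe = np.zeros((max_len, d))
    pe[:, 0::2] = np.sin(angles)
    pe[:, 1::2] = np.cos(angles)
    return pe


class Embedding(Module):
    """Token embedding scaled by sqrt(d) plus sinusoidal positions."""

    def __init__(self, rng: np.random.Generator, vocab_size: int, d: int,
                 max_len: int, dropout: float):
        self.E = Param(rng.normal(0.0, d ** -0.5, size=(vocab_size, d)))
        self.pe = sinusoidal_positions(max_len, d)
        self.d = d
        self.drop = Dropout(dropout, rng)
        self._ids: Optional[np.ndarray] = None

    def forward(self, ids: np.ndarray, train: bool) -> np.ndarray:
        self._ids = ids
        x = self.E.value[ids] * math.sqrt(self.d) + self.pe[: ids.shape[1]]
        return self.drop.forward(x, train)

    def backward(self, g: np.ndarray) -> None:
        g = self.drop.backward(g) * math.sqrt(self.d)
        np.add.at(self.E.grad, self._ids, g)


class MultiHeadAttention(Module):
    """Scaled dot-product attention with ``heads`` parallel heads."""

    def __init__(self, rng: np.random.Generator, d: int, heads: int, dropout: float):
        if d % heads:
            raise ValueError("embedding dimension must be divisible by heads")
        self.d, self.heads, self.dh = d, heads, d // heads
        self.wq = Linear(rng, d, d)
        self.wk = Linear(rng, d, d)
        self.wv = Linear(rng, d, d)
        self.wo = Linear(rng, d, d)
        self.drop = Dropout(dropout, rng)

    def _split(self, x: np.ndarray) -> np.ndarray:
        B, T, _ = x.shape
        return x.reshape(B, T, self.heads, self.dh).transpose(0, 2, 1, 3)

    def _merge(self, x: np.ndarray) -> np.ndarray:
        B, H, T, dh = x.shape
        return x.transpose(0, 2, 1, 3).reshape(B, T, H * dh)

    def forward(
        self,
        xq: np.ndarray,
        xkv: np.ndarray,
        mask: Optional[np.ndarray],
        train: bool,
    ) -> np.ndarray:
        q = self._split(self.wq.forward(xq))
        k = self._split(self.wk.forward(xkv))
        v = self._split(self.wv.forward(xkv))
        scores = q @ k.swapaxes(-1, -2) / math.sqrt(self.dh)
        if mask is not None:
            scores = scores + mask
        att = softmax(scores)
        att_d = self.drop.forward(att, train)
        out = att_d @ v
        self._cache = (q, k, v, att)
        return self.wo.forward(self._merge(out))

    def backward(self, g: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
        q, k, v, att = self._cache
        g = self._split(self.wo.backward(g))
        # out = drop(att) @ v
        att_d = att if self.drop._mask is None else att * self.drop._mask
        dv = att_d.swapaxes(-1, -2) @ g
        datt = self.drop.backward(g @ v.swapaxes(-1, -2))
        ds = att * (datt - (datt * att).sum(axis=-1, keepdims=True))
        ds /= math.sqrt(self.dh)
        dq = ds @ k
        dk = ds.swapaxes(-1, -2) @ q
        dxq = self.wq.backward(self._merge(dq))
        dxkv = self.wk.backward(self._merge(dk)) + self.wv.backward(self._merge(dv))
        return dxq, dxkv


class FeedForward(Module):
    """Position-wise two-layer MLP with ReLU."""

    def __init__(self, rng: np.random.Generator, d: int, d_ff: int, dropout: float):
        self.lin1 = Linear(rng, d, d_ff)
        self.lin2 = Linear(rng, d_ff, d)
        self.drop = Dropout(dropout, rng)

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        h = self.lin1.forward(x)
        self._relu_mask = h > 0
        h = h * self._relu_mask
        h = self.drop.forward(h, train)
        return self.lin2.forward(h)

    def backward(self, g: np.ndarray) -> np.ndarray:
        g = self.lin2.backward(g)
        g = self.drop.backward(g)
        g = g * self._relu_mask
        return self.lin1.backward(g)
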