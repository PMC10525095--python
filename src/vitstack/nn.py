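"""Minimal NumPy neural-network layers with explicit backpropagation.

Just enough machinery for a small pre-norm transformer encoder trained with
Adam and binary cross-entropy on CPU: linear layers, layer normalisation,
GELU, softmax multi-head self-attention, dropout, and the optimizer.  Every
layer caches what its backward pass needs during ``forward`` and returns the
input gradient from ``backward``; gradients accumulate into
``Parameter.grad``.  All computation is float64 — the models are tiny and
exact, checkable gradients matter more than speed here.
"""

from __future__ import annotations

import math
from typing import Iterable

import numpy as np

__all__ = [
    "Parameter", "Module", "Linear", "LayerNorm", "GELU", "Dropout",
    "MultiHeadSelfAttention", "Adam", "bce_with_logits", "sigmoid",
]


class Parameter:
    """A trainable array with an accumulated gradient."""

    __slots__ = ("value", "grad", "name")

    def __init__(self, value: np.ndarray, name: str = ""):
        self.value = np.asarray(value, dtype=np.float64)
        self.grad = np.zeros_like(self.value)
        self.name = name


class Module:
    def parameters(self) -> list[Parameter]:
        params: list[Parameter] = []
        for attr in vars(self).values():
            if isinstance(attr, Parameter):
                params.append(attr)
            elif isinstance(attr, Module):
                params.extend(attr.parameters())
            elif isinstance(attr, (list, tuple)):
                for item in attr:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
                    elif isinstance(item, Parameter):
                        params.append(item)
        return params

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad[...] = 0.0

    def n_parameters(self) -> int:
        return sum(p.value.size for p in self.parameters())


def trunc_normal(rng: np.random.Generator, shape, std: float = 0.02) -> np.ndarray:
    """Normal init truncated to two standard deviations (resampling)."""
    out = rng.normal(0.0, std, size=shape)
    bad = np.abs(out) > 2 * std
    while bad.any():
        out[bad] = rng.normal(0.0, std, size=int(bad.sum()))
        bad = np.abs(out) > 2 * std
    return out


class Linear(Module):
    def __init__(self, rng: np.random.Generator, n_in: int, n_out: int,
                 std: float = 0.02):
        self.W = Parameter(trunc_normal(rng, (n_in, n_out), std))
        self.b = Parameter(np.zeros(n_out))
        self._x: np.ndarray | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.W.value + self.b.value

    def backward(self, g: np.ndarray) -> np.ndarray:
        x = self._x
        self.W.grad += np.tensordot(x, g, axes=(range(x.ndim - 1),
                                                range(g.ndim - 1)))
        self.b.grad += g.reshape(-1, g.shape[-1]).sum(axis=0)
        return g @ self.W.value.T


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-5):
        self.gamma = Parameter(np.ones(dim))
        self.beta = Parameter(np.zeros(dim))
        self.eps = eps
        self._cache = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        mu = x.mean(axis=-1, keepdims=True)
        var = x.var(axis=-1, keepdims=True)
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu) * inv
        self._cache = (xhat, inv)
        return xhat * self.gamma.value + self.beta.value

    def backward(self, g: np.ndarray) -> np.ndarray:
        xhat, inv = self._cache
        n = xhat.shape[-1]
        self.gamma.grad += (g * xhat).reshape(-1, n).sum(axis=0)
        self.beta.grad += g.reshape(-1, n).sum(axis=0)
        gx = g * self.gamma.value
        return inv * (gx - gx.mean(axis=-1, keepdims=True)
                      - xhat * (gx * xhat).mean(axis=-1, keepdims=True))


class GELU(Module):
    """Exact (erf-based) Gaussian error linear unit."""

    def __init__(self):
        self._x = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        from scipy.special import erf
        return 0.5 * x * (1.0 + erf(x / math.sqrt(2.0)))

    def backward(self, g: np.ndarray) -> np.ndarray:
        from scipy.special import erf
        x = self._x
        cdf = 0.5 * (1.0 + erf(x / math.sqrt(2.0)))
        pdf = np.exp(-0.5 * x * x) / math.sqrt(2.0 * math.pi)
        return g * (cdf + x * pdf)


class Dropout(Module):
    """Inverted dropout; identity at rate 0 or in eval mode."""

    def __init__(self, rate: float):
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate
        self._mask = None

    def forward(self, x: np.ndarray, *, train: bool = False,
                rng: np.random.Generator | None = None) -> np.ndarray:
        if not train or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (rng.random(x.shape) < keep) / keep
        return x * self._mask

    def backward(self, g: np.ndarray) -> np.ndarray:
        return g if self._mask is None else g * self._mask


def _softmax(a: np.ndarray) -> np.ndarray:
    a = a - a.max(axis=-1, keepdims=True)
    e = np.exp(a)
    return e / e.sum(axis=-1, keepdims=True)


class MultiHeadSelfAttention(Module):
    """Standard k-head scaled dot-product self-attention over (B, T, D)."""

    def __init__(self, rng: np.random.Generator, dim: int, n_heads: int):
        if dim % n_heads != 0:
            raise ValueError(f"embedding size {dim} not divisible by {n_heads} heads")
        self.dim = dim
        self.n_heads = n_heads
        self.head_dim = dim // n_heads
        self.qkv = Linear(rng, dim, 3 * dim)
        self.proj = Linear(rng, dim, dim)
        self._cache = None

    def _split(self, x: np.ndarray) -> np.ndarray:
        b, t, _ = x.shape
        return x.reshape(b, t, self.n_heads, self.head_dim).transpose(0, 2, 1, 3)

    def _merge(self, x: np.ndarray) -> np.ndarray:
        b, h, t, d = x.shape
        return x.transpose(0, 2, 1, 3).reshape(b, t, h * d)

    def forward(self, x: np.ndarray) -> np.ndarray:
        qkv = self.qkv.forward(x)
        q, k, v = np.split(qkv, 3, axis=-1)
        q, k, v = self._split(q), self._split(k), self._split(v)
        scale = 1.0 / math.sqrt(self.head_dim)
        attn = _softmax(np.einsum("bhtd,bhsd->bhts", q, k) * scale)
        out = np.einsum("bhts,bhsd->bhtd", attn, v)
        self._cache = (q, k, v, attn, scale)
        return self.proj.forward(self._merge(out))

    def backward(self, g: np.ndarray) -> np.ndarray:
        q, k, v, attn, scale = self._cache
        g_out = self._split(self.proj.backward(g))
        g_attn = np.einsum("bhtd,bhsd->bhts", g_out, v)
        g_v = np.einsum("bhts,bhtd->bhsd", attn, g_out)
        # softmax backward along the key axis
        g_scores = attn * (g_attn - (g_attn * attn).sum(axis=-1, keepdims=True))
        g_scores *= scale
        g_q = np.einsum("bhts,bhsd->bhtd", g_scores, k)
        g_k = np.einsum("bhts,bhtd->bhsd", g_scores, q)
        g_qkv = np.concatenate([self._merge(g_q), self._merge(g_k),
                                self._merge(g_v)], axis=-1)
        return self.qkv.backward(g_qkv)


def sigmoid(x: np.ndarray) -> np.ndarray:
    return 0.5 * (1.0 + np.tanh(0.5 * np.asarray(x, dtype=np.float64)))


def bce_with_logits(logits: np.ndarray, targets: np.ndarray
                    ) -> tuple[float, np.ndarray]:
    """Mean binary cross-entropy from logits; returns (loss, dloss/dlogits)."""
    logits = np.asarray(logits, dtype=np.float64)
    targets = np.asarray(targets, dtype=np.float64)
    # log(1 + e^-|x|) formulation is stable for both signs
    loss = np.mean(np.maximum(logits, 0.0) - logits * targets
                   + np.log1p(np.exp(-np.abs(logits))))
    grad = (sigmoid(logits) - targets) / logits.size
    return float(loss), grad


class Adam:
    """Adam with non-decoupled L2 weight decay folded into the gradient."""

    def __init__(self, params: Iterable[Parameter], lr: float = 1e-4,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8,
                 weight_decay: float = 0.0):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in self.params]
        self.v = [np.zeros_like(p.value) for p in self.params]

    def step(self, lr_scale: float = 1.0) -> None:
        self.t += 1
        lr = self.lr * lr_scale
        for p, m, v in zip(self.params, self.m, self.v):
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.value
            m[...] = self.b1 * m + (1 - self.b1) * g
            v[...] = self.b2 * v + (1 - self.b2) * g * g
            mhat = m / (1 - self.b1 ** self.t)
            vhat = v / (1 - self.b2 ** self.t)
            p.value -= lr * mhat / (np.sqrt(vhat) + self.eps)
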