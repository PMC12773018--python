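"""Small neural building blocks on top of the autodiff engine."""

from __future__ import annotations

from typing import List, Optional, Sequence

import numpy as np

from .autodiff import Tensor, concatenate, constant

__all__ = [
    "Module",
    "Linear",
    "LayerNorm",
    "FeedForward",
    "MultiHeadAttention",
    "Conv1d",
    "Adam",
    "sinusoidal_positions",
    "masked_mean",
    "attention_bias",
]


class Module:
    """Base class; collects parameters from attributes recursively."""

    def parameters(self) -> List[Tensor]:
        out: List[Tensor] = []
        seen = set()
        for value in self.__dict__.values():
            for p in _collect(value):
                if id(p) not in seen:
                    seen.add(id(p))
                    out.append(p)
        return out

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.zero_grad()

    def state_arrays(self) -> List[np.ndarray]:
        return [p.data for p in self.parameters()]

    def load_state_arrays(self, arrays: Sequence[np.ndarray]) -> None:
        params = self.parameters()
        if len(arrays) != len(params):
            raise ValueError("state array count mismatch")
        for p, a in zip(params, arrays):
            if p.data.shape != a.shape:
                raise ValueError("state array shape mismatch")
            p.data = np.asarray(a, dtype=np.float64).copy()


def _collect(value):
    if isinstance(value, Tensor) and value.requires_grad:
        yield value
    elif isinstance(value, Module):
        yield from value.parameters()
    elif isinstance(value, (list, tuple)):
        for v in value:
            yield from _collect(v)


def _param(rng: np.random.Generator, *shape, scale: Optional[float] = None) -> Tensor:
    if scale is None:
        scale = 1.0 / np.sqrt(shape[0])
    return Tensor(rng.normal(0.0, scale, size=shape), requires_grad=True)


class Linear(Module):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator):
        self.W = _param(rng, d_in, d_out)
        self.b = Tensor(np.zeros(d_out), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.W + self.b


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-5):
        self.gamma = Tensor(np.ones(dim), requires_grad=True)
        self.beta = Tensor(np.zeros(dim), requires_grad=True)
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        centered = x - mu
        var = (centered * centered).mean(axis=-1, keepdims=True)
        inv = (var + self.eps) ** -0.5
        return centered * inv * self.gamma + self.beta


class FeedForward(Module):
    def __init__(self, dim: int, hidden: int, rng: np.random.Generator):
        self.fc1 = Linear(dim, hidden, rng)
        self.fc2 = Linear(hidden, dim, rng)

    def __call__(self, x: Tensor) -> Tensor:
        return self.fc2(self.fc1(x).relu())


def attention_bias(mask: np.ndarray) -> np.ndarray:
    """(B, Lk) 0/1 mask -> additive (B, 1, 1, Lk) bias with -1e9 at padding."""
    return (1.0 - np.asarray(mask, dtype=np.float64))[:, None, None, :] * -1e9


class MultiHeadAttention(Module):
    """Scaled dot-product attention; queries from one stream, keys/values
    from another (pass the same stream twice for self-attention)."""

    def __init__(self, dim: int, n_heads: int, rng: np.random.Generator):
        if dim % n_heads != 0:
            raise ValueError("dim must be divisible by n_heads")
        self.dim = dim
        self.n_heads = n_heads
        self.d_head = dim // n_heads
        self.Wq = Linear(dim, dim, rng)
        self.Wk = Linear(dim, dim, rng)
        self.Wv = Linear(dim, dim, rng)
        self.Wo = Linear(dim, dim, rng)

    def _split(self, x: Tensor, B: int, L: int) -> Tensor:
        return x.reshape(B, L, self.n_heads, self.d_head).transpose(1, 2)

    def __call__(
        self, xq: Tensor, xkv: Tensor, kv_mask: Optional[np.ndarray] = None
    ) -> Tensor:
        B, Lq, _ = xq.shape
        Lk = xkv.shape[1]
        q = self._split(self.Wq(xq), B, Lq)
        k = self._split(self.Wk(xkv), B, Lk)
        v = self._split(self.Wv(xkv), B, Lk)
        scores = (q @ k.transpose(2, 3)) * (1.0 / np.sqrt(self.d_head))
        if kv_mask is not None:
            scores = scores + constant(attention_bias(kv_mask))
        attn = scores.softmax(axis=-1)
        out = (attn @ v).transpose(1, 2).reshape(B, Lq, self.dim)
        return self.Wo(out)


class Conv1d(Module):
    """'Same'-padded 1-D convolution over (B, L, D_in) via shifted matmuls.

    Out-of-range positions contribute zeros, so appending padding rows never
    changes outputs at real positions.
    """

    def __init__(self, d_in: int, d_out: int, kernel: int, rng: np.random.Generator):
        if kernel % 2 != 1:
            raise ValueError("kernel size must be odd")
        self.kernel = kernel
        self.weights = [
            _param(rng, d_in, d_out, scale=1.0 / np.sqrt(d_in * kernel))
            for _ in range(kernel)
        ]
        self.b = Tensor(np.zeros(d_out), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        B, L, d_in = x.shape
        half = self.kernel // 2
        zeros = constant(np.zeros((B, half, d_in)))
        padded = concatenate([zeros, x, zeros], axis=1)
        out = None
        for j, Wj in enumerate(self.weights):
            term = padded[:, j : j + L, :] @ Wj
            out = term if out is None else out + term
        return out + self.b


def sinusoidal_positions(L: int, dim: int) -> np.ndarray:
    """Standard sinusoidal positional encoding matrix (L, dim)."""
    pos = np.arange(L)[:, None]
    i = np.arange(dim)[None, :]
    angle = pos / np.power(10000.0, (2 * (i // 2)) / dim)
    pe = np.zeros((L, dim))
    pe[:, 0::2] = np.sin(angle[:, 0::2])
    pe[:, 1::2] = np.cos(angle[:, 1::2])
    return pe


def masked_mean(x: Tensor, mask: np.ndarray) -> Tensor:
    """Mean over axis 1 of (B, L, D) counting only mask==1 positions."""
    m = constant(np.asarray(mask, dtype=np.float64)[:, :, None])
    total = (x * m).sum(axis=1)
    denom = constant(np.maximum(m.data.sum(axis=1), 1.0))
    return total / denom


class Adam:
    def __init__(
        self,
        params: Sequence[Tensor],
        lr: float = 1e-3,
        betas=(0.9, 0.999),
        eps: float = 1e-8,
        weight_decay: float = 0.0,
    ):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()
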