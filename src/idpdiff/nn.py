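"""Transformer building blocks on top of :mod:`idpdiff.autodiff`.

Layers hold their parameters in a flat ``dict`` keyed by qualified names so
that a whole model is a single parameter dictionary — easy to serialize,
hash, and feed to the optimizer.  Initialization is explicit: every layer
takes a seeded ``numpy.random.Generator``.
"""

from __future__ import annotations

from typing import Callable

import numpy as np

from .autodiff import Tensor


def _param(rng: np.random.Generator, shape, scale: float | None = None) -> Tensor:
    if scale is None:
        # Glorot-style scale for weight matrices
        fan_in = shape[0] if len(shape) > 1 else shape[0]
        scale = 1.0 / np.sqrt(fan_in)
    t = Tensor(rng.normal(0.0, scale, size=shape), requires_grad=True)
    return t


class Module:
    """Base: a named parameter dictionary plus a forward method."""

    def __init__(self):
        self.params: dict[str, Tensor] = {}

    def _register(self, name: str, tensor: Tensor) -> Tensor:
        self.params[name] = tensor
        return tensor

    def _adopt(self, prefix: str, child: "Module") -> "Module":
        for k, v in child.params.items():
            self.params[f"{prefix}.{k}"] = v
        return child

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.params.values())

    def state_arrays(self) -> dict[str, np.ndarray]:
        return {k: v.data.copy() for k, v in self.params.items()}

    def load_state_arrays(self, arrays: dict[str, np.ndarray]) -> None:
        missing = set(self.params) - set(arrays)
        if missing:
            raise ValueError(f"checkpoint missing parameters: {sorted(missing)[:5]}")
        for k, v in self.params.items():
            v.data = np.asarray(arrays[k], dtype=np.float64).reshape(v.data.shape)


class Linear(Module):
    def __init__(self, rng, d_in: int, d_out: int, zero_init: bool = False):
        super().__init__()
        scale = 0.0 if zero_init else None
        if zero_init:
            self.w = self._register("w", Tensor(np.zeros((d_in, d_out)), requires_grad=True))
        else:
            self.w = self._register("w", _param(rng, (d_in, d_out)))
        self.b = self._register("b", Tensor(np.zeros(d_out), requires_grad=True))

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.w + self.b


class LayerNorm(Module):
    """Layer normalization over the last axis; affine parameters optional."""

    def __init__(self, d: int, affine: bool = True, eps: float = 1e-5):
        super().__init__()
        self.eps = eps
        self.affine = affine
        if affine:
            self.g = self._register("g", Tensor(np.ones(d), requires_grad=True))
            self.b = self._register("b", Tensor(np.zeros(d), requires_grad=True))

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=-1, keepdims=True)
        y = xc / (var + self.eps).sqrt()
        if self.affine:
            y = y * self.g + self.b
        return y


def gelu(x: Tensor) -> Tensor:
    # tanh approximation
    c = np.sqrt(2.0 / np.pi)
    inner = (x + x * x * x * 0.044715) * c
    return x * 0.5 * (inner.tanh() + 1.0)


class SelfAttention(Module):
    """Multi-head self-attention with an optional additive logit bias.

    The bias carries pair information (embedded distances, relative
    positions) into the attention logits, shape-broadcastable to
    ``(batch, heads, L, L)``.
    """

    def __init__(self, rng, width: int, heads: int):
        super().__init__()
        if width % heads:
            raise ValueError("width must be divisible by heads")
        self.h = heads
        self.dk = width // heads
        self.wq = self._adopt("wq", Linear(rng, width, width))
        self.wk = self._adopt("wk", Linear(rng, width, width))
        self.wv = self._adopt("wv", Linear(rng, width, width))
        self.wo = self._adopt("wo", Linear(rng, width, width))

    def _split(self, x: Tensor, L: int) -> Tensor:
        # (B, L, w) -> (B, h, L, dk)
        B = x.shape[0]
        return x.reshape(B, L, self.h, self.dk).transpose(0, 2, 1, 3)

    def __call__(self, x: Tensor, bias: Tensor | None = None) -> Tensor:
        B, L, _ = x.shape
        q = self._split(self.wq(x), L)
        k = self._split(self.wk(x), L)
        v = self._split(self.wv(x), L)
        logits = (q @ k.swapaxes(-1, -2)) * (1.0 / np.sqrt(self.dk))
        if bias is not None:
            logits = logits + bias
        attn = logits.softmax(axis=-1)
        out = attn @ v  # (B, h, L, dk)
        out = out.transpose(0, 2, 1, 3).reshape(B, L, self.h * self.dk)
        return self.wo(out)


class FeedForward(Module):
    def __init__(self, rng, width: int, hidden_mult: int = 2):
        super().__init__()
        self.l1 = self._adopt("l1", Linear(rng, width, hidden_mult * width))
        self.l2 = self._adopt("l2", Linear(rng, hidden_mult * width, width))

    def __call__(self, x: Tensor) -> Tensor:
        return self.l2(gelu(self.l1(x)))


class TransformerBlock(Module):
    """Pre-LN transformer block with optional attention logit bias."""

    def __init__(self, rng, width: int, heads: int):
        super().__init__()
        self.ln1 = self._adopt("ln1", LayerNorm(width))
        self.attn = self._adopt("attn", SelfAttention(rng, width, heads))
        self.ln2 = self._adopt("ln2", LayerNorm(width))
        self.ff = self._adopt("ff", FeedForward(rng, width))

    def __call__(self, x: Tensor, bias: Tensor | None = None) -> Tensor:
        x = x + self.attn(self.ln1(x), bias)
        x = x + self.ff(self.ln2(x))
        return x


class AdaLNZeroBlock(Module):
    """Transformer block conditioned via adaLN-Zero.

    A conditioning vector per residue predicts scale/shift for the two
    normalizations and gates for the two residual branches.  The modulation
    projection is zero-initialized so every block starts as the identity.
    """

    def __init__(self, rng, width: int, heads: int):
        super().__init__()
        self.ln1 = self._adopt("ln1", LayerNorm(width, affine=False))
        self.attn = self._adopt("attn", SelfAttention(rng, width, heads))
        self.ln2 = self._adopt("ln2", LayerNorm(width, affine=False))
        self.ff = self._adopt("ff", FeedForward(rng, width))
        # 6 modulation channels: shift1, scale1, gate1, shift2, scale2, gate2
        self.mod = self._adopt("mod", Linear(rng, width, 6 * width, zero_init=True))

    def __call__(self, x: Tensor, cond: Tensor, bias: Tensor | None = None) -> Tensor:
        w = x.shape[-1]
        m = self.mod(gelu(cond))
        sh1, sc1, g1 = m[..., :w], m[..., w : 2 * w], m[..., 2 * w : 3 * w]
        sh2, sc2, g2 = m[..., 3 * w : 4 * w], m[..., 4 * w : 5 * w], m[..., 5 * w :]
        h = self.ln1(x) * (sc1 + 1.0) + sh1
        x = x + g1 * self.attn(h, bias)
        h = self.ln2(x) * (sc2 + 1.0) + sh2
        x = x + g2 * self.ff(h)
        return x


# ----------------------------------------------------------- fixed embeddings
def sinusoidal_embedding(t: np.ndarray, dim: int, max_period: float = 10_000.0) -> np.ndarray:
    """Standard sinusoidal timestep embedding, shape ``(len(t), dim)``."""
    t = np.asarray(t, dtype=np.float64).reshape(-1)
    half = dim // 2
    freqs = np.exp(-np.log(max_period) * np.arange(half) / half)
    args = t[:, None] * freqs[None, :]
    emb = np.concatenate([np.cos(args), np.sin(args)], axis=-1)
    if dim % 2:
        emb = np.concatenate([emb, np.zeros((len(t), 1))], axis=-1)
    return emb


def rbf_embed(d: np.ndarray, n_centers: int = 64, d_min: float = 0.0,
              d_max: float = 40.0) -> np.ndarray:
    """Gaussian radial-basis embedding of distances (Å).

    Centers are evenly spaced on ``[d_min, d_max]``; the kernel width equals
    the center spacing.
    """
    centers = np.linspace(d_min, d_max, n_centers)
    width = centers[1] - centers[0]
    return np.exp(-((d[..., None] - centers) ** 2) / (2.0 * width**2))


def relative_positions(L: int, clip: int = 32) -> np.ndarray:
    """Clipped signed offsets ``i - j`` mapped to indices ``0 … 2*clip``."""
    idx = np.arange(L)
    rel = np.clip(idx[:, None] - idx[None, :], -clip, clip) + clip
    return rel


# ------------------------------------------------------------------ optimizer
class Adam:
    def __init__(self, params: dict[str, Tensor], lr: float = 1e-3,
                 betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.v = {k: np.zeros_like(p.data) for k, p in params.items()}

    def step(self, lr: float | None = None) -> None:
        lr = self.lr if lr is None else lr
        self.t += 1
        for k, p in self.params.items():
            if p.grad is None:
                continue
            g = p.grad
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / (1 - self.b1**self.t)
            vhat = self.v[k] / (1 - self.b2**self.t)
            p.data -= lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params.values():
            p.grad = None


def warmup_cosine_schedule(base_lr: float, warmup_steps: int,
                           total_steps: int) -> Callable[[int], float]:
    """Linear warmup followed by cosine decay to zero."""

    def lr_at(step: int) -> float:
        if warmup_steps > 0 and step < warmup_steps:
            return base_lr * (step + 1) / warmup_steps
        frac = (step - warmup_steps) / max(1, total_steps - warmup_steps)
        frac = min(max(frac, 0.0), 1.0)
        return base_lr * 0.5 * (1.0 + np.cos(np.pi * frac))

    return lr_at
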