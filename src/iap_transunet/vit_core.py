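"""Transformer encoder primitives: scaled dot-product attention, multi-head
self-attention, the two-layer ReLU MLP, sinusoidal positional encoding and
the stacked encoder.

Layers use the pre-norm arrangement (layer norm before each sublayer, then
a residual add), the standard choice for vision transformers; post-norm is
available by flag.  Per-head dimensions are d_k = d_v = dim / n_heads.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn import Dropout, LayerNorm, Linear, Module, Sequential, Tensor

__all__ = [
    "EncoderConfig", "scaled_dot_attention", "sinusoidal_pe",
    "MultiHeadSelfAttention", "TransformerMlp", "TransformerEncoder",
]


@dataclass(frozen=True)
class EncoderConfig:
    dim: int
    n_layers: int = 12
    n_heads: int = 12
    mlp_dim: int | None = None          # default 4 * dim
    dropout: float = 0.1
    pre_norm: bool = True

    def __post_init__(self):
        if min(self.dim, self.n_layers + 1, self.n_heads) < 1:
            raise ValueError("dim, n_layers, n_heads must be positive")
        if self.dim % self.n_heads:
            raise ValueError(
                f"dim ({self.dim}) must be divisible by n_heads ({self.n_heads})")

    @property
    def resolved_mlp_dim(self) -> int:
        return self.mlp_dim if self.mlp_dim is not None else 4 * self.dim


def scaled_dot_attention(q: Tensor, k: Tensor, v: Tensor) -> Tensor:
    """softmax(Q K^T / sqrt(d_k)) V over the last two axes.

    Accepts (..., n_q, d_k), (..., n_kv, d_k), (..., n_kv, d_v); the softmax
    runs over keys, so each attention row is a convex combination of values.
    """
    if q.shape[-1] != k.shape[-1]:
        raise ValueError(f"query/key dim mismatch: {q.shape[-1]} vs {k.shape[-1]}")
    if k.shape[-2] != v.shape[-2]:
        raise ValueError(f"key/value token count mismatch: "
                         f"{k.shape[-2]} vs {v.shape[-2]}")
    d_k = q.shape[-1]
    kt_axes = list(range(k.ndim))
    kt_axes[-1], kt_axes[-2] = kt_axes[-2], kt_axes[-1]
    scores = (q @ k.transpose(*kt_axes)) * (1.0 / np.sqrt(d_k))
    return scores.softmax(axis=-1) @ v


def sinusoidal_pe(n_pos: int, d: int) -> np.ndarray:
    """(n_pos, d) sinusoidal positional table.

    PE[pos, 2i] = sin(pos / 10000^(2i/d)), PE[pos, 2i+1] = cos(...); each
    even/odd column pair shares one frequency, entries lie in [-1, 1].
    """
    if d % 2:
        raise ValueError(f"positional-encoding dim must be even, got {d}")
    pos = np.arange(n_pos, dtype=np.float64)[:, None]
    freq = np.power(10000.0, -np.arange(0, d, 2, dtype=np.float64) / d)[None, :]
    pe = np.empty((n_pos, d), dtype=np.float32)
    pe[:, 0::2] = np.sin(pos * freq)
    pe[:, 1::2] = np.cos(pos * freq)
    return pe


class MultiHeadSelfAttention(Module):
    """h parallel attention heads, concatenated and projected by W^O."""

    def __init__(self, dim: int, n_heads: int, *, dropout: float = 0.0,
                 rng: np.random.Generator | None = None):
        super().__init__()
        if dim % n_heads:
            raise ValueError(f"dim ({dim}) not divisible by n_heads ({n_heads})")
        self.dim, self.n_heads = dim, n_heads
        self.d_head = dim // n_heads
        self.wq = Linear(dim, dim, rng=rng)
        self.wk = Linear(dim, dim, rng=rng)
        self.wv = Linear(dim, dim, rng=rng)
        self.wo = Linear(dim, dim, rng=rng)
        self.drop = Dropout(dropout, rng=rng)

    def _split(self, t: Tensor) -> Tensor:
        B, N, _ = t.shape
        return t.reshape(B, N, self.n_heads, self.d_head).transpose(0, 2, 1, 3)

    def forward(self, x: Tensor) -> Tensor:
        B, N, D = x.shape
        q, k, v = self._split(self.wq(x)), self._split(self.wk(x)), self._split(self.wv(x))
        heads = scaled_dot_attention(q, k, v)            # (B, h, N, d_head)
        merged = heads.transpose(0, 2, 1, 3).reshape(B, N, D)
        return self.drop(self.wo(merged))


class TransformerMlp(Module):
    """MLP(X) = max(0, X W1 + b1) W2 + b2."""

    def __init__(self, dim: int, hidden: int, *, dropout: float = 0.0,
                 rng: np.random.Generator | None = None):
        super().__init__()
        self.fc1 = Linear(dim, hidden, rng=rng)
        self.fc2 = Linear(hidden, dim, rng=rng)
        self.drop = Dropout(dropout, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        return self.drop(self.fc2(self.fc1(x).relu()))


class _EncoderLayer(Module):
    def __init__(self, cfg: EncoderConfig, rng: np.random.Generator | None):
        super().__init__()
        self.norm1 = LayerNorm(cfg.dim)
        self.attn = MultiHeadSelfAttention(cfg.dim, cfg.n_heads,
                                           dropout=cfg.dropout, rng=rng)
        self.norm2 = LayerNorm(cfg.dim)
        self.mlp = TransformerMlp(cfg.dim, cfg.resolved_mlp_dim,
                                  dropout=cfg.dropout, rng=rng)
        self.pre_norm = cfg.pre_norm

    def forward(self, x: Tensor) -> Tensor:
        if self.pre_norm:
            x = x + self.attn(self.norm1(x))
            return x + self.mlp(self.norm2(x))
        x = self.norm1(x + self.attn(x))
        return self.norm2(x + self.mlp(x))


class TransformerEncoder(Module):
    """Stack of encoder layers; expects positionally-encoded token input."""

    def __init__(self, cfg: EncoderConfig, *, rng: np.random.Generator | None = None):
        super().__init__()
        self.cfg = cfg
        self.layers = Sequential(*[_EncoderLayer(cfg, rng)
                                   for _ in range(cfg.n_layers)])

    def forward(self, x: Tensor) -> Tensor:
        return self.layers(x)
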