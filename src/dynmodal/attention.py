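"""Local Window Transformer (LWT) short-range expert and generic attention.

Self-attention is restricted to a symmetric band: position i attends to j
iff |i - j| <= floor(w/2); disallowed pairs receive an additive -1e9 before
the softmax, so each attention row is a distribution over the allowed
positions only. Blocks are pre-norm: LayerNorm -> windowed MHSA -> residual,
LayerNorm -> FFN (Linear -> GELU -> Linear) -> residual. Stacking l blocks
grows the receptive field to about l*w. The per-layer cost is linear in
sequence length at fixed window size.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .errors import ValidationError
from .nn import Tensor

__all__ = [
    "LWTConfig",
    "band_mask",
    "MultiHeadAttention",
    "windowed_mhsa",
    "TransformerBlock",
    "LWTBlock",
    "add_positional",
    "PositionalTable",
]


@dataclass
class LWTConfig:
    d_model: int
    heads: int = 8
    head_dim: int = 64
    ff_dim: int = 2048
    window: int = 5
    layers: int = 2

    def __post_init__(self) -> None:
        if min(self.d_model, self.heads, self.head_dim, self.ff_dim, self.window, self.layers) < 1:
            raise ValidationError("all LWT dimensions must be >= 1")


def band_mask(N: int, w: int) -> np.ndarray:
    """Additive mask: 0 where |i-j| <= floor(w/2), -1e9 elsewhere."""
    if N < 1 or w < 1:
        raise ValidationError("N and w must be >= 1")
    i = np.arange(N)
    allowed = np.abs(i[:, None] - i[None, :]) <= w // 2
    return np.where(allowed, 0.0, -1e9)


class MultiHeadAttention(nn.Module):
    """Scaled dot-product attention, optionally masked and cross-modal.

    Set ``record=True`` to keep the last row-stochastic weight arrays
    (numpy, shape (..., heads, Nq, Nk)) on ``last_weights``.
    """

    def __init__(self, d_q: int, d_kv: int, heads: int, head_dim: int, d_out: int,
                 rng: np.random.Generator):
        super().__init__()
        self.heads = heads
        self.head_dim = head_dim
        inner = heads * head_dim
        self.wq = nn.Linear(d_q, inner, rng)
        self.wk = nn.Linear(d_kv, inner, rng)
        self.wv = nn.Linear(d_kv, inner, rng)
        self.wo = nn.Linear(inner, d_out, rng)
        self.record = False
        self.last_weights: np.ndarray | None = None

    def _split_heads(self, x: Tensor, n: int) -> Tensor:
        # (..., N, heads*hd) -> (..., heads, N, hd)
        x = x.reshape(x.shape[:-1] + (self.heads, self.head_dim))
        return x.swapaxes(-2, -3)

    def forward(self, q_in: Tensor, kv_in: Tensor, mask: np.ndarray | None = None) -> Tensor:
        if not np.isfinite(q_in.data).all() or not np.isfinite(kv_in.data).all():
            raise ValidationError("non-finite input to attention")
        nq, nk = q_in.shape[-2], kv_in.shape[-2]
        q = self._split_heads(self.wq(q_in), nq)
        k = self._split_heads(self.wk(kv_in), nk)
        v = self._split_heads(self.wv(kv_in), nk)
        scores = (q @ k.swapaxes(-1, -2)) * (1.0 / np.sqrt(self.head_dim))
        if mask is not None:
            scores = scores + Tensor(mask)
        weights = nn.softmax(scores, axis=-1)
        if self.record:
            self.last_weights = weights.data.copy()
        ctx = weights @ v                          # (..., heads, Nq, hd)
        ctx = ctx.swapaxes(-2, -3)
        ctx = ctx.reshape(ctx.shape[:-2] + (self.heads * self.head_dim,))
        return self.wo(ctx)

    def banded(self, x: Tensor, w: int) -> Tensor:
        """Self-attention restricted to |i-j| <= floor(w/2), computed per
        diagonal offset so the elementary-op count is O(N * w), linear in
        sequence length at fixed window size. Equal (to rounding) to the
        dense masked form."""
        if not np.isfinite(x.data).all():
            raise ValidationError("non-finite input to attention")
        n = x.shape[-2]
        r = min(w // 2, n - 1)
        q = self._split_heads(self.wq(x), n)       # (..., h, N, hd)
        k = self._split_heads(self.wk(x), n)
        v = self._split_heads(self.wv(x), n)
        lead = q.shape[:-2]
        scale = 1.0 / np.sqrt(self.head_dim)
        offsets = list(range(-r, r + 1))
        score_cols = []
        for off in offsets:
            i0 = max(0, -off)
            j0 = max(0, off)
            length = n - abs(off)
            s = (q[..., i0 : i0 + length, :] * k[..., j0 : j0 + length, :]).sum(axis=-1) * scale
            parts = []
            if i0 > 0:
                parts.append(Tensor(np.full(lead + (i0,), -1e9)))
            parts.append(s)
            tail = n - i0 - length
            if tail > 0:
                parts.append(Tensor(np.full(lead + (tail,), -1e9)))
            col = parts[0] if len(parts) == 1 else nn.concatenate(parts, axis=-1)
            score_cols.append(col)
        scores = nn.stack(score_cols, axis=-1)     # (..., h, N, n_off)
        weights = nn.softmax(scores, axis=-1)
        if self.record:
            dense = np.zeros(lead + (n, n))
            for idx, off in enumerate(offsets):
                i = np.arange(max(0, -off), n - max(0, off))
                dense[..., i, i + off] = weights.data[..., i, idx]
            self.last_weights = dense
        ctx = None
        for idx, off in enumerate(offsets):
            i0 = max(0, -off)
            j0 = max(0, off)
            length = n - abs(off)
            w_col = weights[..., i0 : i0 + length, idx : idx + 1]
            seg = w_col * v[..., j0 : j0 + length, :]
            parts = []
            if i0 > 0:
                parts.append(Tensor(np.zeros(lead + (i0, self.head_dim))))
            parts.append(seg)
            tail = n - i0 - length
            if tail > 0:
                parts.append(Tensor(np.zeros(lead + (tail, self.head_dim))))
            padded = parts[0] if len(parts) == 1 else nn.concatenate(parts, axis=-2)
            ctx = padded if ctx is None else ctx + padded
        ctx = ctx.swapaxes(-2, -3)
        ctx = ctx.reshape(ctx.shape[:-2] + (self.heads * self.head_dim,))
        return self.wo(ctx)


class WindowedSelfAttention(MultiHeadAttention):
    def __init__(self, cfg: LWTConfig, rng: np.random.Generator):
        super().__init__(cfg.d_model, cfg.d_model, cfg.heads, cfg.head_dim, cfg.d_model, rng)
        self.window = cfg.window

    def forward(self, x: Tensor, window: int | None = None) -> Tensor:  # type: ignore[override]
        w = self.window if window is None else window
        return self.banded(x, w)

    def dense_masked(self, x: Tensor, window: int | None = None) -> Tensor:
        """Reference path: dense attention with an additive band mask."""
        w = self.window if window is None else window
        return MultiHeadAttention.forward(self, x, x, mask=band_mask(x.shape[-2], w))

    def dense(self, x: Tensor) -> Tensor:
        """Unmasked full attention with the same weights (reference)."""
        return MultiHeadAttention.forward(self, x, x, mask=None)


def windowed_mhsa(x, attn: WindowedSelfAttention) -> Tensor:
    """Banded multi-head self-attention with the module's weights."""
    if not isinstance(x, Tensor):
        x = Tensor(x)
    return attn(x)


class TransformerBlock(nn.Module):
    """Pre-norm encoder block; pass a band mask for windowed attention."""

    def __init__(self, d_model: int, heads: int, head_dim: int, ff_dim: int,
                 rng: np.random.Generator, window: int | None = None):
        super().__init__()
        self.window = window
        self.norm1 = nn.LayerNorm(d_model)
        self.attn = MultiHeadAttention(d_model, d_model, heads, head_dim, d_model, rng)
        self.norm2 = nn.LayerNorm(d_model)
        self.ff1 = nn.Linear(d_model, ff_dim, rng)
        self.ff2 = nn.Linear(ff_dim, d_model, rng)

    def forward(self, x: Tensor) -> Tensor:
        if not isinstance(x, Tensor):
            x = Tensor(x)
        if not np.isfinite(x.data).all():
            raise ValidationError("non-finite input to TransformerBlock")
        xn = self.norm1(x)
        if self.window is not None:
            x = x + self.attn.banded(xn, self.window)
        else:
            x = x + self.attn(xn, xn, mask=None)
        h = self.ff2(nn.gelu(self.ff1(self.norm2(x))))
        return x + h


class LWTBlock(TransformerBlock):
    def __init__(self, cfg: LWTConfig, rng: np.random.Generator):
        super().__init__(cfg.d_model, cfg.heads, cfg.head_dim, cfg.ff_dim, rng,
                         window=cfg.window)


class PositionalTable(nn.Module):
    """Learnable additive positional encodings."""

    def __init__(self, max_len: int, d_model: int, rng: np.random.Generator):
        super().__init__()
        self.table = nn.Parameter(0.02 * rng.standard_normal((max_len, d_model)))

    def forward(self, x: Tensor) -> Tensor:
        return add_positional(x, self.table)


def add_positional(x, table) -> Tensor:
    if not isinstance(x, Tensor):
        x = Tensor(x)
    if not isinstance(table, Tensor):
        table = Tensor(table)
    n = x.shape[-2]
    if n > table.shape[0]:
        raise ValidationError(
            f"sequence length {n} exceeds positional table capacity {table.shape[0]}"
        )
    return x + table[:n]
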