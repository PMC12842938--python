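"""Per-modality multi-scale temporal encoder with long-short routing (MTEM).

Each univariate channel of a modality is patched at two resolutions. Long
(low-resolution) patches are linearly embedded and run through state-space
blocks; short (high-resolution) patches get learnable positional encodings
and local-window transformer blocks. A two-way router — softmax over a
linear map of the channel's global average — produces weights (p_long,
p_short) that scale the two token sequences before they are concatenated
along the token axis:

    z = concat(p_long * z_long, p_short * z_short)

giving N_long + N_short tokens per channel. Channel token matrices are then
averaged into one token matrix per modality, keeping the token count
independent of the channel dimension.
"""

from __future__ import annotations

import numpy as np

from . import nn
from .attention import LWTBlock, LWTConfig, PositionalTable
from .config import RunConfig
from .errors import ValidationError
from .nn import Tensor
from .patching import PatchSpec, patch_batch, patch_count
from .ssm import MambaBlock, MambaConfig

__all__ = ["global_context", "route_long_short", "fuse_long_short", "MTEMEncoder"]


def global_context(series, linear: nn.Linear) -> Tensor:
    """Time-mean of a series followed by a linear map to the context dim.

    Accepts a length-L vector, an L x d matrix, or batches thereof; the
    time axis is -1 for vectors and -2 for matrices.
    """
    if not isinstance(series, Tensor):
        series = Tensor(np.asarray(series, dtype=np.float64))
    if series.data.size == 0:
        raise ValidationError("empty series")
    if series.ndim == 1:
        pooled = series.mean(axis=-1).reshape(1)
    elif linear.weight.shape[0] == 1:
        # batch of univariate series: (B, L) -> (B, 1)
        pooled = series.mean(axis=-1, keepdims=True)
    else:
        pooled = series.mean(axis=-2)
    return linear(pooled)


def route_long_short(z_b, linear: nn.Linear) -> Tensor:
    """Two-way softmax gate over [long, short] logits; rows sum to 1."""
    if not isinstance(z_b, Tensor):
        z_b = Tensor(np.asarray(z_b, dtype=np.float64))
    if not np.isfinite(z_b.data).all():
        raise ValidationError("non-finite router input")
    return nn.softmax(linear(z_b), axis=-1)


def fuse_long_short(z_long, z_short, p) -> Tensor:
    """Scale each scale's tokens by its routing weight and concatenate rows."""
    if not isinstance(z_long, Tensor):
        z_long = Tensor(z_long)
    if not isinstance(z_short, Tensor):
        z_short = Tensor(z_short)
    if not isinstance(p, Tensor):
        p = Tensor(np.asarray(p, dtype=np.float64))
    if z_long.shape[-1] != z_short.shape[-1]:
        raise ValidationError("long and short token dims differ")
    p_long = p[..., 0:1].reshape(p.shape[:-1] + (1, 1))
    p_short = p[..., 1:2].reshape(p.shape[:-1] + (1, 1))
    return nn.concatenate([p_long * z_long, p_short * z_short], axis=-2)


class MTEMEncoder(nn.Module):
    """One modality's patch -> experts -> routed fusion pipeline."""

    def __init__(self, config: RunConfig, rng: np.random.Generator):
        super().__init__()
        d = config.d_model
        self.spec_long = PatchSpec(config.patch_long_len, config.patch_long_stride, "long")
        self.spec_short = PatchSpec(config.patch_short_len, config.patch_short_stride, "short")
        self.embed_long = nn.Linear(config.patch_long_len, d, rng)
        self.embed_short = nn.Linear(config.patch_short_len, d, rng)
        mcfg = MambaConfig(d, config.mamba_hidden_dim, config.mamba_state_dim,
                           config.mamba_conv_kernel)
        self.mamba_blocks = [MambaBlock(mcfg, rng) for _ in range(config.mamba_layers)]
        if config.mamba_freeze_state_matrix:
            for b in self.mamba_blocks:
                b.freeze_state_matrix()
        lcfg = LWTConfig(d, config.lwt_heads, config.lwt_head_dim, config.lwt_ff_dim,
                         config.lwt_window, config.lwt_layers)
        self.positional = PositionalTable(config.lwt_max_len, d, rng)
        self.lwt_blocks = [LWTBlock(lcfg, rng) for _ in range(config.lwt_layers)]
        self.ctx_linear = nn.Linear(1, d, rng)
        self.route_linear = nn.Linear(d, 2, rng)

    def token_count(self, T: int) -> int:
        return patch_count(T, self.spec_long) + patch_count(T, self.spec_short)

    def forward(self, x: np.ndarray):
        """x: (B, T, D_m) raw modality batch.

        Returns (tokens, p): tokens is a Tensor (B, N_long + N_short,
        d_model), p the routing weights as a (B, D_m, 2) array.
        """
        x = np.asarray(x, dtype=np.float64)
        if x.ndim != 3:
            raise ValidationError("expected a (B, T, D) batch")
        B, T, D = x.shape
        long_np = patch_batch(x, self.spec_long)    # (B, D, NL, PL)
        short_np = patch_batch(x, self.spec_short)  # (B, D, NS, PS)
        nl, ns = long_np.shape[2], short_np.shape[2]

        z_long = self.embed_long(Tensor(long_np.reshape(B * D, nl, -1)))
        for block in self.mamba_blocks:
            z_long = block(z_long)

        z_short = self.positional(self.embed_short(Tensor(short_np.reshape(B * D, ns, -1))))
        for block in self.lwt_blocks:
            z_short = block(z_short)

        # router on the raw channel's global average
        channels = x.transpose(0, 2, 1).reshape(B * D, T)
        z_b = global_context(Tensor(channels), self.ctx_linear)          # (B*D, d)
        p = route_long_short(z_b, self.route_linear)                     # (B*D, 2)

        fused = fuse_long_short(z_long, z_short, p)  # (B*D, NL+NS, d)
        fused = fused.reshape(B, D, nl + ns, -1).mean(axis=1)
        return fused, p.data.reshape(B, D, 2)
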