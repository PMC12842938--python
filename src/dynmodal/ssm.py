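"""Selective state-space (Mamba-style) long-range expert.

The block runs an input-dependent diagonal linear recurrence per hidden
channel,

    h_t = Abar_t * h_{t-1} + (Bbar_t x_t),     y_t = <C_t, h_t>,

where the discrete transition Abar_t = exp(Delta_t * A) and input term
Bbar_t = Delta_t * B_t follow from a softplus-positive learned timescale
Delta (zero-order-hold on A, Euler on B). A is diagonal per hidden channel,
parameterized A = -exp(a_log) so the recurrence is a contraction, with a_log
initialized to log(1..state_dim).

``scan_oracle`` is the normative sequential recurrence on plain arrays; any
faster scan must match it. ``selective_scan`` is the differentiable
implementation used by the block — a sequential scan over the (short) patch
axis, linear in sequence length.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .errors import ValidationError
from .nn import Tensor

__all__ = ["MambaConfig", "ScanInputs", "scan_oracle", "selective_scan", "discretize", "MambaBlock"]


@dataclass
class MambaConfig:
    d_model: int
    hidden_dim: int = 1024
    state_dim: int = 16
    conv_kernel: int = 4

    def __post_init__(self) -> None:
        if min(self.d_model, self.hidden_dim, self.state_dim, self.conv_kernel) < 1:
            raise ValidationError("all Mamba dimensions must be >= 1")


@dataclass
class ScanInputs:
    """Per-step recurrence inputs: Abar (N,H,S), input term Bbar*x (N,H,S),
    readout C (N,S); the initial state is zero."""

    abar: np.ndarray
    bx: np.ndarray
    c: np.ndarray

    def __post_init__(self) -> None:
        self.abar = np.asarray(self.abar, dtype=np.float64)
        self.bx = np.asarray(self.bx, dtype=np.float64)
        self.c = np.asarray(self.c, dtype=np.float64)
        if not (self.abar.shape == self.bx.shape and self.abar.ndim == 3):
            raise ValidationError("abar and bx must share shape (N, H, S)")
        if self.c.ndim != 2 or self.c.shape[0] != self.abar.shape[0] or self.c.shape[1] != self.abar.shape[2]:
            raise ValidationError("c must have shape (N, S) matching abar")


def scan_oracle(inputs: ScanInputs) -> np.ndarray:
    """Literal sequential recurrence; the normative definition of the scan."""
    n, h, s = inputs.abar.shape
    state = np.zeros((h, s))
    out = np.empty((n, h))
    for t in range(n):
        state = inputs.abar[t] * state + inputs.bx[t]
        out[t] = state @ inputs.c[t]
    return out


def selective_scan(abar, bx=None, c=None):
    """Differentiable scan; equals :func:`scan_oracle` on any input.

    Accepts either a :class:`ScanInputs` (returns a numpy array) or three
    tensors with shapes (..., N, H, S), (..., N, H, S), (..., N, S)
    (returns a Tensor of shape (..., N, H)).
    """
    if isinstance(abar, ScanInputs):
        inputs = abar
        y = selective_scan(Tensor(inputs.abar), Tensor(inputs.bx), Tensor(inputs.c))
        return y.data
    if bx is None or c is None:
        raise ValidationError("selective_scan needs abar, bx and c")
    if abar.shape != bx.shape or abar.shape[-3] != c.shape[-2] or abar.shape[-1] != c.shape[-1]:
        raise ValidationError("inconsistent scan input shapes")
    n = abar.shape[-3]
    state = None
    ys = []
    for t in range(n):
        a_t = abar[..., t, :, :]
        b_t = bx[..., t, :, :]
        state = b_t if state is None else a_t * state + b_t
        c_t = c[..., t, :]
        shape = c_t.shape[:-1] + (1, c_t.shape[-1])
        ys.append((state * c_t.reshape(shape)).sum(axis=-1))
    return nn.stack(ys, axis=-2)


def discretize(A, delta, B):
    """Zero-order-hold/Euler discretization: Abar = exp(delta*A), Bbar = delta*B.

    A: (H, S) diagonal state matrix per hidden channel (typically negative);
    delta: (..., N, H) positive timescales; B: (..., N, S).
    Returns (abar, bx_factor) with shapes (..., N, H, S) each, where
    bx_factor[..., h, s] = delta[..., h] * B[..., s] (multiply by x_t to get
    the input term).
    """
    delta_data = delta.data if isinstance(delta, Tensor) else np.asarray(delta)
    if not (delta_data > 0).all():
        raise ValidationError("delta must be positive elementwise")
    A = A if isinstance(A, Tensor) else Tensor(A)
    delta = delta if isinstance(delta, Tensor) else Tensor(delta)
    B = B if isinstance(B, Tensor) else Tensor(B)
    d_exp = delta.reshape(delta.shape + (1,))      # (..., N, H, 1)
    b_exp = B.reshape(B.shape[:-1] + (1, B.shape[-1]))  # (..., N, 1, S)
    abar = (d_exp * A).exp()
    bbar = d_exp * b_exp
    return abar, bbar


class MambaBlock(nn.Module):
    """Normalize -> up-project -> causal conv -> SiLU -> selective scan ->
    SiLU gate -> down-project -> residual."""

    def __init__(self, cfg: MambaConfig, rng: np.random.Generator):
        super().__init__()
        self.cfg = cfg
        d, h, s = cfg.d_model, cfg.hidden_dim, cfg.state_dim
        self.norm = nn.LayerNorm(d)
        self.in_proj = nn.Linear(d, h, rng)
        self.conv = nn.CausalDepthwiseConv1d(h, cfg.conv_kernel, rng)
        self.dt_proj = nn.Linear(h, h, rng)
        self.b_proj = nn.Linear(h, s, rng)
        self.c_proj = nn.Linear(h, s, rng)
        self.gate_proj = nn.Linear(d, h, rng)
        self.out_proj = nn.Linear(h, d, rng)
        # A = -exp(a_log), a_log = log(1..S) per hidden channel
        self.a_log = nn.Parameter(np.tile(np.log(np.arange(1, s + 1, dtype=np.float64)), (h, 1)))

    def freeze_state_matrix(self) -> None:
        self.a_log.requires_grad = False

    def forward(self, x: Tensor) -> Tensor:
        if not isinstance(x, Tensor):
            x = Tensor(x)
        if not np.isfinite(x.data).all():
            raise ValidationError("non-finite input to MambaBlock")
        xn = self.norm(x)
        xp = self.in_proj(xn)                  # (..., N, H)
        xc = nn.silu(self.conv(xp))
        delta = self.dt_proj(xc).softplus()    # (..., N, H) > 0
        b = self.b_proj(xc)                    # (..., N, S)
        c = self.c_proj(xc)                    # (..., N, S)
        A = -(self.a_log.exp())                # (H, S), strictly negative
        abar, bfac = discretize(A, delta, b)
        bx = bfac * xc.reshape(xc.shape + (1,))
        y = selective_scan(abar, bx, c)        # (..., N, H)
        y = y * nn.silu(self.gate_proj(xn))
        return self.out_proj(y) + x
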