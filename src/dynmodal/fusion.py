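"""Two-level dynamic multimodal fusion with conditional computation.

Modality level: a lightweight audio probe feeds a gating MLP that scores
four processing pathways of increasing cost — E1 audio-only (nominal 0.6
GFLOPs), E2 audio + compressed video (1.0), E3 audio + full video with
bidirectional cross-attention (1.6), E4 deep audio-visual fusion (2.3).
Exactly one expert executes per sample. At inference the selection either
takes the plain argmax or follows a confidence-thresholded policy: above
confidence 0.75 take the argmax (but escalate one tier when confidence is
at most 0.9, unless the argmax is the audio-only path); otherwise fall back
to path 2 when the audio-only score exceeds 0.4 and to path 4 when it does
not.

Fusion level: a stack of fusion cells each selects one of four operations
O1-O4 mirroring the pathway strategies, from audio-internal aggregation to
a deep co-attention stack; a single global gating head emits all per-unit
decisions at once. Costs are tracked both as the published nominal GFLOPs
per expert and as analytic elementary-operation counts measured by the
tensor library's counter.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn
from .attention import MultiHeadAttention, TransformerBlock
from .errors import ConfigError, ValidationError
from .nn import Tensor, count_flops

__all__ = [
    "PathDecision",
    "FusionDecision",
    "CostModel",
    "NOMINAL_EXPERT_COST",
    "LightAudioEncoder",
    "PathGate",
    "select_path",
    "compress_video",
    "ExpertBank",
    "FusionCell",
    "FusionGate",
    "expected_cost",
]

NOMINAL_EXPERT_COST = {1: 0.6, 2: 1.0, 3: 1.6, 4: 2.3}  # GFLOPs


@dataclass
class PathDecision:
    scores: np.ndarray          # post-softmax, sums to 1
    confidence: float
    selected: int               # 1..4
    hard: np.ndarray            # one-hot with the 1 at `selected`

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=np.float64)
        self.hard = np.asarray(self.hard, dtype=np.float64)
        if abs(self.scores.sum() - 1.0) > 1e-6:
            raise ValidationError("path scores must sum to 1")
        if self.hard.sum() != 1.0 or self.hard[self.selected - 1] != 1.0:
            raise ValidationError("hard decision must be one-hot at `selected`")


@dataclass
class FusionDecision:
    probs: np.ndarray           # (n_units, 4)
    hard: np.ndarray            # (n_units, 4) one-hot rows

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=np.float64)
        self.hard = np.asarray(self.hard, dtype=np.float64)
        if np.abs(self.probs.sum(axis=-1) - 1.0).max() > 1e-6:
            raise ValidationError("fusion probabilities must sum to 1 per unit")
        if not ((self.hard.sum(axis=-1) == 1.0).all() and ((self.hard == 0) | (self.hard == 1)).all()):
            raise ValidationError("fusion hard decisions must be one-hot per unit")

    @property
    def selected(self) -> np.ndarray:
        return self.hard.argmax(axis=-1) + 1


@dataclass
class CostModel:
    """Per-choice costs used by the resource-aware loss.

    ``expert_cost`` defaults to the published nominal GFLOPs; ``op_cost``
    defaults to analytic counts (filled in by the model at build time).
    """

    expert_cost: dict = field(default_factory=lambda: dict(NOMINAL_EXPERT_COST))
    op_cost: dict = field(default_factory=lambda: {1: 0.0, 2: 0.0, 3: 0.0, 4: 0.0})

    def __post_init__(self) -> None:
        e = self.expert_cost
        if not (e[1] < e[2] < e[3] < e[4]):
            raise ConfigError("expert costs must be strictly increasing E1<E2<E3<E4")

    def expert_vector(self) -> np.ndarray:
        return np.array([self.expert_cost[k] for k in (1, 2, 3, 4)])

    def op_vector(self) -> np.ndarray:
        return np.array([self.op_cost[k] for k in (1, 2, 3, 4)])


# -- path gating --------------------------------------------------------------


class LightAudioEncoder(nn.Module):
    """Cheap audio probe: depthwise conv over tokens, mean pool, linear to 512."""

    OUT_DIM = 512

    def __init__(self, d_model: int, rng: np.random.Generator):
        super().__init__()
        self.conv = nn.CausalDepthwiseConv1d(d_model, 3, rng)
        self.proj = nn.Linear(d_model, self.OUT_DIM, rng)

    def forward(self, tokens: Tensor) -> Tensor:
        if not isinstance(tokens, Tensor):
            tokens = Tensor(tokens)
        if tokens.shape[-2] < 1 or tokens.data.size == 0:
            raise ValidationError("empty input to LightAudioEncoder")
        pooled = self.conv(tokens).mean(axis=-2)
        return self.proj(pooled)


class PathGate(nn.Module):
    """512 -> 256 -> ReLU -> Dropout(0.2) -> 4 logits."""

    def __init__(self, rng: np.random.Generator):
        super().__init__()
        self.fc1 = nn.Linear(LightAudioEncoder.OUT_DIM, 256, rng)
        self.drop = nn.Dropout(0.2)
        self.fc2 = nn.Linear(256, 4, rng)

    def forward(self, f_a: Tensor, rng: np.random.Generator | None = None) -> Tensor:
        """Returns the pre-softmax logits; apply softmax for scores."""
        if not isinstance(f_a, Tensor):
            f_a = Tensor(f_a)
        if not np.isfinite(f_a.data).all():
            raise ValidationError("non-finite input to PathGate")
        h = self.drop(self.fc1(f_a).relu(), rng=rng)
        return self.fc2(h)


def path_gate_scores(gate: PathGate, f_a, rng=None) -> Tensor:
    return nn.softmax(gate(f_a, rng=rng), axis=-1)


def select_path(scores) -> int:
    """Confidence-thresholded path selection (total on the 4-simplex).

    if max > 0.75: p = argmax; return 1 if p == 1 else (p if max > 0.9
    else min(p+1, 4)); otherwise return 2 if the audio-only score > 0.4
    else 4.
    """
    scores = np.asarray(scores, dtype=np.float64)
    conf = float(scores.max())
    if conf > 0.75:
        p = int(scores.argmax()) + 1  # lowest index wins ties
        if p == 1:
            return 1
        if conf > 0.9:
            return p
        return min(p + 1, 4)
    if scores[0] > 0.4:
        return 2
    return 4


def make_path_decision(scores: np.ndarray, policy: str = "thresholded") -> PathDecision:
    scores = np.asarray(scores, dtype=np.float64)
    if policy == "thresholded":
        sel = select_path(scores)
    elif policy == "argmax":
        sel = int(scores.argmax()) + 1
    else:
        raise ConfigError(f"unknown path policy: {policy}")
    hard = np.zeros(4)
    hard[sel - 1] = 1.0
    return PathDecision(scores=scores, confidence=float(scores.max()), selected=sel, hard=hard)


# -- compressed video ---------------------------------------------------------


def compressed_dim(d: int) -> int:
    return min(d, max(8, d // 4))


def compress_video(tokens, seed: int) -> Tensor:
    """Fixed seeded Gaussian random projection of the feature dimension.

    Projects d -> min(d, max(8, d//4)) with entries N(0, 1/r), so squared
    norms are preserved in expectation (Johnson-Lindenstrauss scaling).
    Token count is unchanged; the projection is a constant, not trained.
    """
    if not isinstance(tokens, Tensor):
        tokens = Tensor(np.asarray(tokens, dtype=np.float64))
    d = tokens.shape[-1]
    r = compressed_dim(d)
    proj = np.random.default_rng(seed).standard_normal((d, r)) / np.sqrt(r)
    return tokens @ Tensor(proj)


# -- experts ------------------------------------------------------------------


def _mean_tokens(x: Tensor) -> Tensor:
    return x.mean(axis=-2)


def _as_row(u: Tensor) -> Tensor:
    """(..., d) -> (..., 1, d) for broadcasting over tokens."""
    return u.reshape(u.shape[:-1] + (1,) + u.shape[-1:])


class ExpertBank(nn.Module):
    """The four modality-level pathways, shared-skeleton with growing depth."""

    def __init__(self, d_model: int, rng: np.random.Generator, compress_seed: int):
        super().__init__()
        d = d_model
        heads = 2
        hd = max(4, d // heads)
        ff = 2 * d
        self.compress_seed = compress_seed
        # E1: audio-only self-attention encoder
        self.e1_block = TransformerBlock(d, heads, hd, ff, rng)
        # E2: compressed video -> d, token concat, encoder
        self.e2_vproj = nn.Linear(compressed_dim(d), d, rng)
        self.e2_block = TransformerBlock(d, heads, hd, ff, rng)
        # E3: bidirectional cross-attention + joint encoder
        self.e3_av = MultiHeadAttention(d, d, 4, hd, d, rng)
        self.e3_va = MultiHeadAttention(d, d, 4, hd, d, rng)
        self.e3_block = TransformerBlock(d, heads, hd, ff, rng)
        # E4: two further cross-attention rounds on top of the E3 pattern
        self.e4_av = MultiHeadAttention(d, d, 4, hd, d, rng)
        self.e4_va = MultiHeadAttention(d, d, 4, hd, d, rng)
        self.e4_av2 = MultiHeadAttention(d, d, 4, hd, d, rng)
        self.e4_va2 = MultiHeadAttention(d, d, 4, hd, d, rng)
        self.e4_av3 = MultiHeadAttention(d, d, 4, hd, d, rng)
        self.e4_va3 = MultiHeadAttention(d, d, 4, hd, d, rng)
        self.e4_block = TransformerBlock(d, heads, hd, ff, rng)

    def run(self, k: int, x_a, x_v=None) -> Tensor:
        """Execute exactly the selected expert; E1 never reads the video."""
        if k not in (1, 2, 3, 4):
            raise ConfigError(f"expert index must be 1..4, got {k}")
        if not isinstance(x_a, Tensor):
            x_a = Tensor(np.asarray(x_a, dtype=np.float64))
        if k == 1:
            return self.e1_block(x_a)
        if x_v is None:
            raise ValidationError(f"expert E{k} requires video features")
        if not isinstance(x_v, Tensor):
            x_v = Tensor(np.asarray(x_v, dtype=np.float64))
        if k == 2:
            v = self.e2_vproj(compress_video(x_v, self.compress_seed))
            return self.e2_block(nn.concatenate([x_a, v], axis=-2))
        if k == 3:
            a = x_a + self.e3_av(x_a, x_v)
            v = x_v + self.e3_va(x_v, x_a)
            return self.e3_block(nn.concatenate([a, v], axis=-2))
        a = x_a + self.e4_av(x_a, x_v)
        v = x_v + self.e4_va(x_v, x_a)
        a = a + self.e4_av2(a, v)
        v = v + self.e4_va2(v, a)
        a = a + self.e4_av3(a, v)
        v = v + self.e4_va3(v, a)
        return self.e4_block(nn.concatenate([a, v], axis=-2))

    forward = run


def run_modality_expert(bank: ExpertBank, k: int, x_a, x_v=None) -> Tensor:
    return bank.run(k, x_a, x_v)


# -- fusion cells -------------------------------------------------------------


class _OpAudioInternal(nn.Module):
    """O1: audio-internal multi-level aggregation; never reads the video."""

    def __init__(self, d: int, rng):
        super().__init__()
        self.proj = nn.Linear(d, d, rng)
        self.mix = nn.Parameter(np.zeros(1))

    def forward(self, h: Tensor, x_a: Tensor, x_v=None) -> Tensor:
        u = nn.gelu(self.proj(_mean_tokens(x_a)))
        return h + self.mix.sigmoid() * _as_row(u)


class _OpLightweight(nn.Module):
    """O2: gated single-head cross-attention at reduced dimensionality."""

    def __init__(self, d: int, rng):
        super().__init__()
        dr = max(8, d // 4)
        self.attn = MultiHeadAttention(d, d, 1, dr, d, rng)
        self.gate = nn.Linear(d, d, rng)

    def forward(self, h: Tensor, x_a: Tensor, x_v: Tensor) -> Tensor:
        g = self.gate(_mean_tokens(x_a)).sigmoid()
        return h + _as_row(g) * self.attn(h, x_v)


class _OpStandard(nn.Module):
    """O3: bidirectional 4-head cross-attention with residuals."""

    def __init__(self, d: int, rng):
        super().__init__()
        hd = max(4, d // 4)
        self.attn_v = MultiHeadAttention(d, d, 4, hd, d, rng)
        self.attn_a = MultiHeadAttention(d, d, 4, hd, d, rng)

    def forward(self, h: Tensor, x_a: Tensor, x_v: Tensor) -> Tensor:
        h = h + self.attn_v(h, x_v)
        return h + self.attn_a(h, x_a)


class _OpDeep(nn.Module):
    """O4: 3-level co-attention stack, then a self-attention decoder block."""

    def __init__(self, d: int, rng):
        super().__init__()
        hd = max(4, d // 4)
        self.rounds = [
            (MultiHeadAttention(d, d, 4, hd, d, rng), MultiHeadAttention(d, d, 4, hd, d, rng))
            for _ in range(3)
        ]
        self.decoder = TransformerBlock(d, 4, hd, 2 * d, rng)

    def forward(self, h: Tensor, x_a: Tensor, x_v: Tensor) -> Tensor:
        for attn_v, attn_a in self.rounds:
            h = h + attn_v(h, x_v)
            h = h + attn_a(h, x_a)
        return self.decoder(h)


class FusionCell(nn.Module):
    """One fusion unit holding the four candidate operations."""

    def __init__(self, d_model: int, rng: np.random.Generator):
        super().__init__()
        self.ops = [
            _OpAudioInternal(d_model, rng),
            _OpLightweight(d_model, rng),
            _OpStandard(d_model, rng),
            _OpDeep(d_model, rng),
        ]

    def forward(self, h: Tensor, x_a: Tensor, x_v, g) -> Tensor:
        """h_j = g_k * O_k with one-hot (or straight-through) g; only the
        selected operation executes."""
        g_data = g.data if isinstance(g, Tensor) else np.asarray(g, dtype=np.float64)
        if not (np.isin(g_data, (0.0, 1.0)).all() and g_data.sum() == 1.0):
            raise ValidationError("fusion decision must be one-hot in hard mode")
        k = int(g_data.argmax())
        if k > 0 and x_v is None:
            raise ValidationError("selected fusion operation requires video features")
        out = self.ops[k](h, x_a, x_v)
        if isinstance(g, Tensor) and g.requires_grad:
            out = out * g[k]
        return out


class FusionGate(nn.Module):
    """Global gating head emitting all per-unit operation logits at once."""

    def __init__(self, d_model: int, n_units: int, rng: np.random.Generator):
        super().__init__()
        self.n_units = n_units
        self.fc1 = nn.Linear(2 * d_model, 64, rng)
        self.fc2 = nn.Linear(64, n_units * 4, rng)

    def forward(self, x_a: Tensor, x_v: Tensor) -> Tensor:
        pooled = nn.concatenate([_mean_tokens(x_a), _mean_tokens(x_v)], axis=-1)
        logits = self.fc2(self.fc1(pooled).relu())
        return logits.reshape(logits.shape[:-1] + (self.n_units, 4))


# -- cost ---------------------------------------------------------------------


def expected_cost(path_probs, fusion_probs, cost_model: CostModel):
    """Expected cost sum_i p_i C(E_i) + sum_j sum_k pi_jk C(O_k).

    Accepts numpy arrays (returns float) or Tensors (returns a Tensor so the
    penalty is differentiable w.r.t. the gate probabilities). Leading batch
    axes are summed, so pass per-sample vectors for a per-sample cost.
    """
    p_data = path_probs.data if isinstance(path_probs, Tensor) else np.asarray(path_probs)
    f_data = fusion_probs.data if isinstance(fusion_probs, Tensor) else np.asarray(fusion_probs)
    if np.abs(p_data.sum(axis=-1) - 1.0).max() > 1e-6:
        raise ValidationError("path probabilities must sum to 1")
    if np.abs(f_data.sum(axis=-1) - 1.0).max() > 1e-6:
        raise ValidationError("fusion probabilities must sum to 1 per unit")
    ev = cost_model.expert_vector()
    ov = cost_model.op_vector()
    if isinstance(path_probs, Tensor) or isinstance(fusion_probs, Tensor):
        p = path_probs if isinstance(path_probs, Tensor) else Tensor(path_probs)
        f = fusion_probs if isinstance(fusion_probs, Tensor) else Tensor(fusion_probs)
        return (p * Tensor(ev)).sum() + (f * Tensor(ov)).sum()
    return float((p_data @ ev).sum() + (f_data @ ov).sum())


def measure_flops(fn, *args, **kwargs) -> int:
    """Elementary-operation count of a forward call (analytic, not timed)."""
    with count_flops() as counter:
        fn(*args, **kwargs)
    return counter.total
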