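"""End-to-end dynamic multimodal classifier.

Pipeline per batch: each modality runs through its multi-scale temporal
encoder (patching, state-space + local-window experts, long-short routing)
producing a token matrix per sample; a lightweight audio probe scores the
four processing pathways; exactly one modality-level expert executes per
sample; the result passes through a stack of fusion cells, each executing
one selected operation; the final tokens are mean-pooled and mapped to two
class probabilities.

Modes: ``hard`` (inference) takes deterministic decisions — argmax or the
confidence-thresholded policy; ``soft`` (training) samples straight-through
Gumbel-Softmax decisions so gate gradients flow while still executing a
single branch per sample. For efficiency samples sharing a pathway are
executed as one sub-batch (grouping changes nothing numerically: gathers
and concatenations are exact). When the video modality is absent (None)
the forward clamps the path to the audio-only expert and every cell to the
audio-internal operation.
"""

from __future__ import annotations

import numpy as np

from . import nn
from .config import RunConfig
from .errors import ConfigError
from .fusion import (
    NOMINAL_EXPERT_COST,
    CostModel,
    ExpertBank,
    FusionCell,
    FusionDecision,
    FusionGate,
    LightAudioEncoder,
    PathDecision,
    PathGate,
    make_path_decision,
    measure_flops,
)
from .nn import Tensor
from .router import MTEMEncoder
from .training_utils import gumbel_softmax_sample

__all__ = ["DynamicMultimodalClassifier"]


class DynamicMultimodalClassifier(nn.Module):
    def __init__(self, config: RunConfig):
        super().__init__()
        self.config = config
        rng = np.random.default_rng(config.seed)
        d = config.d_model
        self.mtem_audio = MTEMEncoder(config, rng)
        self.mtem_video = MTEMEncoder(config, rng)
        self.light_audio = LightAudioEncoder(d, rng)
        self.path_gate = PathGate(rng)
        self.experts = ExpertBank(d, rng, compress_seed=config.seed + 13)
        self.fusion_cells = [FusionCell(d, rng) for _ in range(config.n_fusion_units)]
        self.fusion_gate = FusionGate(d, config.n_fusion_units, rng)
        self.classifier = nn.Linear(d, 2, rng)
        self.cost_model = self.build_cost_model()

    # -- cost accounting ------------------------------------------------------

    def analytic_costs(self, n_audio_tokens: int = 16, n_video_tokens: int = 16) -> dict:
        """Elementary-op counts per expert and per fusion op at reference shapes."""
        d = self.config.d_model
        rng = np.random.default_rng(0)
        xa = Tensor(rng.standard_normal((n_audio_tokens, d)))
        xv = Tensor(rng.standard_normal((n_video_tokens, d)))
        with nn.no_grad():
            expert = {k: measure_flops(self.experts.run, k, xa, xv) for k in (1, 2, 3, 4)}
            h = Tensor(rng.standard_normal((n_audio_tokens, d)))
            cell = self.fusion_cells[0]
            op = {}
            for k in (1, 2, 3, 4):
                g = np.zeros(4)
                g[k - 1] = 1.0
                op[k] = measure_flops(cell, h, xa, xv, g)
        return {"expert": expert, "op": op}

    def build_cost_model(self) -> CostModel:
        counts = self.analytic_costs()
        op_cost = {k: v / 1e9 for k, v in counts["op"].items()}
        if self.config.use_nominal_costs:
            expert_cost = dict(NOMINAL_EXPERT_COST)
        else:
            expert_cost = {k: v / 1e9 for k, v in counts["expert"].items()}
        return CostModel(expert_cost=expert_cost, op_cost=op_cost)

    # -- forward --------------------------------------------------------------

    def forward(
        self,
        audio: np.ndarray,
        video: np.ndarray | None,
        mode: str = "hard",
        tau: float = 1.0,
        rng: np.random.Generator | None = None,
        forced_path: int | None = None,
        forced_ops=None,
    ) -> dict:
        """audio: (B, T_a, D_a); video: (B, T_v, D_v) or None (fully missing).

        Returns class probabilities, logits, per-sample path and fusion
        decisions, and the differentiable gate probabilities the
        resource-aware loss consumes.
        """
        if mode not in ("hard", "soft"):
            raise ConfigError("mode must be 'hard' or 'soft'")
        if mode == "soft" and rng is None:
            raise ConfigError("soft mode needs an rng for Gumbel sampling")
        audio = np.asarray(audio, dtype=np.float64)
        B = audio.shape[0]
        n_units = self.config.n_fusion_units

        tokens_a, route_a = self.mtem_audio(audio)
        video_missing = video is None
        if video_missing:
            tokens_v, route_v = None, None
        else:
            tokens_v, route_v = self.mtem_video(np.asarray(video, dtype=np.float64))

        # ---- modality-level decisions (path gate reads the audio probe only)
        f_light = self.light_audio(tokens_a)                     # (B, 512)
        path_logits = self.path_gate(f_light, rng=rng)           # (B, 4)
        path_probs = nn.softmax(path_logits, axis=-1)
        scores_all = path_probs.data

        g_path = None  # straight-through (B, 4) in soft mode
        if video_missing:
            sel = np.ones(B, dtype=int)
        elif forced_path is not None:
            if forced_path not in (1, 2, 3, 4):
                raise ConfigError("forced_path must be 1..4")
            sel = np.full(B, forced_path, dtype=int)
        elif mode == "hard":
            sel = np.array(
                [make_path_decision(scores_all[b], self.config.path_policy).selected
                 for b in range(B)],
                dtype=int,
            )
        else:
            g_path = gumbel_softmax_sample(path_logits, tau, rng, hard=True)
            sel = g_path.data.argmax(axis=-1).astype(int) + 1

        path_decisions = [
            PathDecision(
                scores=scores_all[b],
                confidence=float(scores_all[b].max()),
                selected=int(sel[b]),
                hard=(g_path.data[b].copy() if g_path is not None else np.eye(4)[sel[b] - 1]),
            )
            for b in range(B)
        ]

        # ---- fusion-level decisions
        if video_missing:
            f_probs_all = np.tile(np.eye(4)[0], (B, n_units, 1))
            f_probs_t = Tensor(f_probs_all)
            op_sel = np.ones((B, n_units), dtype=int)
            g_fusion = None
        elif forced_ops is not None:
            ops = list(forced_ops)
            if len(ops) != n_units:
                raise ConfigError("forced_ops must give one op per fusion unit")
            f_probs_all = np.tile(np.stack([np.eye(4)[k - 1] for k in ops]), (B, 1, 1))
            f_probs_t = Tensor(f_probs_all)
            op_sel = np.tile(np.asarray(ops, dtype=int), (B, 1))
            g_fusion = None
        else:
            flogits = self.fusion_gate(tokens_a, tokens_v)       # (B, n_units, 4)
            f_probs_t = nn.softmax(flogits, axis=-1)
            if mode == "hard":
                op_sel = f_probs_t.data.argmax(axis=-1).astype(int) + 1
                g_fusion = None
            else:
                g_fusion = gumbel_softmax_sample(flogits, tau, rng, hard=True)
                op_sel = g_fusion.data.argmax(axis=-1).astype(int) + 1

        fusion_decisions = [
            FusionDecision(
                probs=f_probs_t.data[b],
                hard=(g_fusion.data[b].copy() if g_fusion is not None
                      else np.eye(4)[op_sel[b] - 1]),
            )
            for b in range(B)
        ]

        # ---- grouped execution: one sub-batch per selected pathway
        logits_parts = []
        order_parts = []
        for k in (1, 2, 3, 4):
            idx = np.flatnonzero(sel == k)
            if idx.size == 0:
                continue
            xa_k = tokens_a[idx]
            xv_k = None if (video_missing or k == 1) else tokens_v[idx]
            h = self.experts.run(k, xa_k, xv_k)
            if g_path is not None:
                w = g_path[idx, sel[idx] - 1]
                h = h * w.reshape((idx.size, 1, 1))

            xv_cells = None if video_missing else (tokens_v[idx] if k == 1 else xv_k)
            h = self._run_cells(h, xa_k, xv_cells, op_sel[idx], g_fusion, idx)
            pooled = h.mean(axis=-2)
            logits_parts.append(self.classifier(pooled))
            order_parts.append(idx)

        perm = np.concatenate(order_parts)
        inv = np.empty(B, dtype=int)
        inv[perm] = np.arange(B)
        logits = nn.concatenate(logits_parts, axis=0)[inv]
        probs = nn.softmax(logits, axis=-1)
        return {
            "probs": probs,
            "logits": logits,
            "path_decisions": path_decisions,
            "fusion_decisions": fusion_decisions,
            "path_probs": path_probs,                            # Tensor (B, 4)
            "fusion_probs": f_probs_t,                           # Tensor (B, n_units, 4)
            "route_audio": route_a,
            "route_video": route_v,
            "tokens_audio": tokens_a,
            "tokens_video": tokens_v,
        }

    def _run_cells(self, h, xa, xv, op_sel_group, g_fusion, idx):
        """Run the fusion-cell stack on one path group, sub-grouping per unit
        by the selected operation."""
        nb = op_sel_group.shape[0]
        for j, cell in enumerate(self.fusion_cells):
            sel_j = op_sel_group[:, j]
            parts, orders = [], []
            for k in (1, 2, 3, 4):
                sub = np.flatnonzero(sel_j == k)
                if sub.size == 0:
                    continue
                h_sub = h[sub]
                xa_sub = xa[sub]
                xv_sub = None if xv is None else xv[sub]
                out = cell.ops[k - 1](h_sub, xa_sub, xv_sub)
                if g_fusion is not None:
                    w = g_fusion[idx[sub], j, k - 1]
                    out = out * w.reshape((sub.size, 1, 1))
                parts.append(out)
                orders.append(sub)
            perm = np.concatenate(orders)
            inv = np.empty(nb, dtype=int)
            inv[perm] = np.arange(nb)
            h = nn.concatenate(parts, axis=0)[inv] if len(parts) > 1 else parts[0]
        return h

    def predict(self, audio, video, batch_size: int = 32) -> np.ndarray:
        """Hard-mode class predictions for a list/array of samples."""
        self.eval()
        preds = []
        n = len(audio)
        with nn.no_grad():
            for start in range(0, n, batch_size):
                a = np.stack(audio[start : start + batch_size])
                v = None if video is None else np.stack(video[start : start + batch_size])
                out = self.forward(a, v, mode="hard")
                preds.append(out["probs"].data.argmax(axis=-1))
        return np.concatenate(preds)
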