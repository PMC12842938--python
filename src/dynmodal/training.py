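"""Losses, temperature annealing and the optimization loop.

The objective is task loss plus a resource penalty,

    L = L_task + lambda * (sum_i p_i C(E_i) + sum_j sum_k pi_jk C(O_k)),

with p/pi the gate probabilities before argmax and C the per-choice costs.
Discrete decisions are relaxed during training with straight-through
Gumbel-Softmax samples whose temperature anneals geometrically from
tau_start to tau_end; validation and early stopping use hard (deployable)
decisions. The task loss is cross-entropy or focal loss
(-alpha_y (1-p_y)^gamma log p_y, gamma=2, alpha = inverse class frequency).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import nn
from .config import RunConfig
from .data import MultimodalSample, make_split
from .errors import ConfigError, ValidationError
from .fusion import CostModel, expected_cost
from .model import DynamicMultimodalClassifier
from .nn import Adam, Tensor
from .training_utils import gumbel_softmax_sample

__all__ = [
    "LossBreakdown",
    "TemperatureSchedule",
    "gumbel_softmax_sample",
    "resource_aware_loss",
    "focal_loss",
    "cross_entropy_loss",
    "classify_head",
    "anneal_temperature",
    "train_model",
    "save_checkpoint",
    "load_checkpoint",
]


@dataclass
class LossBreakdown:
    task_loss: float
    cost_penalty: float
    total: float
    lam: float

    def __post_init__(self) -> None:
        if self.cost_penalty < 0:
            raise ValidationError("cost penalty must be >= 0")
        if abs(self.total - (self.task_loss + self.lam * self.cost_penalty)) > 1e-9:
            raise ValidationError("total must equal task_loss + lambda * cost_penalty")


@dataclass
class TemperatureSchedule:
    tau_start: float = 5.0
    tau_end: float = 0.1
    epochs: int = 120
    mode: str = "exponential"

    def __post_init__(self) -> None:
        if not (0 < self.tau_end <= self.tau_start):
            raise ConfigError("need 0 < tau_end <= tau_start")
        if self.epochs < 1:
            raise ConfigError("epochs must be >= 1")


def anneal_temperature(epoch: int, schedule: TemperatureSchedule) -> float:
    """Geometric interpolation tau(e) = tau_start * (tau_end/tau_start)^(e/(E-1))."""
    if not 0 <= epoch < schedule.epochs:
        raise ConfigError("epoch outside schedule")
    if schedule.epochs == 1:
        return schedule.tau_end
    frac = epoch / (schedule.epochs - 1)
    return float(schedule.tau_start * (schedule.tau_end / schedule.tau_start) ** frac)


# -- losses -------------------------------------------------------------------


def cross_entropy_loss(logits: Tensor, labels: np.ndarray) -> Tensor:
    labels = np.asarray(labels, dtype=int)
    logp = nn.log_softmax(logits, axis=-1)
    picked = logp[np.arange(len(labels)), labels]
    return -picked.mean()


def focal_loss(probs, labels, gamma: float = 2.0, alpha=None) -> Tensor:
    """Mean of -alpha_y (1 - p_y)^gamma log p_y; gamma=0, alpha=1 is CE."""
    if gamma < 0:
        raise ConfigError("gamma must be >= 0")
    if not isinstance(probs, Tensor):
        probs = Tensor(np.asarray(probs, dtype=np.float64))
    labels = np.asarray(labels, dtype=int)
    n = len(labels)
    p_y = probs[np.arange(n), labels]
    # clamp to avoid log(0); forward-only guard on the data
    p_clamped = p_y + Tensor(np.maximum(1e-12 - p_y.data, 0.0))
    if alpha is None:
        a = np.ones(n)
    else:
        a = np.asarray(alpha, dtype=np.float64)[labels]
    modulator = (1.0 - p_clamped) ** gamma if gamma > 0 else Tensor(np.ones(n))
    return -(Tensor(a) * modulator * p_clamped.log()).mean()


def resource_aware_loss(task_loss, path_probs, fusion_probs, cost_model: CostModel,
                        lam: float):
    """Total = task + lambda * expected cost. Returns (total, LossBreakdown)."""
    if lam < 0:
        raise ConfigError("lambda must be >= 0")
    cost = expected_cost(path_probs, fusion_probs, cost_model)
    if isinstance(task_loss, Tensor) or isinstance(cost, Tensor):
        task_t = task_loss if isinstance(task_loss, Tensor) else Tensor(task_loss)
        cost_t = cost if isinstance(cost, Tensor) else Tensor(cost)
        total = task_t + lam * cost_t
        breakdown = LossBreakdown(
            task_loss=float(task_t.data), cost_penalty=float(cost_t.data),
            total=float(task_t.data) + lam * float(cost_t.data), lam=lam,
        )
        return total, breakdown
    total = task_loss + lam * cost
    return total, LossBreakdown(task_loss=float(task_loss), cost_penalty=float(cost),
                                total=float(total), lam=lam)


def classify_head(h_pooled, linear: nn.Linear) -> Tensor:
    """Fully connected layer + softmax over two classes."""
    if not isinstance(h_pooled, Tensor):
        h_pooled = Tensor(np.asarray(h_pooled, dtype=np.float64))
    return nn.softmax(linear(h_pooled), axis=-1)


# -- training loop ------------------------------------------------------------


def _batch_cost(out, cost_model: CostModel) -> Tensor:
    """Mean differentiable expected cost over a forward batch."""
    path_probs = out["path_probs"]
    b = path_probs.shape[0]
    total = expected_cost(path_probs, out["fusion_probs"], cost_model)
    return total * (1.0 / b)


def _stack(samples, ids):
    by_id = {s.sample_id: s for s in samples}
    sel = [by_id[i] for i in ids]
    audio = np.stack([s.audio for s in sel])
    video = np.stack([s.video for s in sel])
    labels = np.array([s.label for s in sel], dtype=int)
    return audio, video, labels


def _eval_loss(model, audio, video, labels, cost_model, lam, loss_name, gamma, alpha):
    model.eval()
    out = model.forward(audio, video, mode="hard")
    if loss_name == "focal":
        task = focal_loss(out["probs"], labels, gamma=gamma, alpha=alpha)
    else:
        task = cross_entropy_loss(out["logits"], labels)
    cost = _batch_cost(out, cost_model)
    breakdown = LossBreakdown(float(task.data), float(cost.data),
                              float(task.data) + lam * float(cost.data), lam)
    preds = out["probs"].data.argmax(axis=-1)
    acc = float((preds == labels).mean())
    return breakdown, acc, out


def train_model(samples, config: RunConfig, split=None, progress=None):
    """Train on a list of samples; returns (model, history, split).

    history is a list of per-epoch dicts (loss breakdown, temperature,
    validation loss/accuracy). The model returned carries the best
    validation-loss weights.
    """
    samples = list(samples)
    if split is None:
        split = make_split(samples, config.split_ratios, config.seed)
    if not split.train or not split.val:
        raise ValidationError("train and val splits must be non-empty")

    rng = np.random.default_rng(config.seed)
    model = DynamicMultimodalClassifier(config)
    cost_model = model.cost_model
    opt = Adam(model.parameters(), lr=config.lr)
    schedule = TemperatureSchedule(config.tau_start, config.tau_end, config.max_epochs)

    labels_train = np.array([s.label for s in samples if s.sample_id in set(split.train)])
    if config.loss == "focal":
        freq = np.bincount(labels_train, minlength=2) / max(len(labels_train), 1)
        alpha = np.where(freq > 0, 1.0 / np.maximum(freq, 1e-12), 0.0)
        alpha = alpha / alpha.sum() * 2.0
    else:
        alpha = None

    a_val, v_val, y_val = _stack(samples, split.val)
    train_ids = list(split.train)

    history = []
    best_val = np.inf
    best_state = model.state_dict()
    best_epoch = -1
    bad_epochs = 0

    for epoch in range(config.max_epochs):
        tau = anneal_temperature(epoch, schedule)
        order = [train_ids[i] for i in rng.permutation(len(train_ids))]
        model.train()
        task_sum = cost_sum = 0.0
        n_batches = 0
        for start in range(0, len(order), config.batch_size):
            ids = order[start : start + config.batch_size]
            audio, video, labels = _stack(samples, ids)
            out = model.forward(audio, video, mode="soft", tau=tau, rng=rng)
            if config.loss == "focal":
                task = focal_loss(out["probs"], labels, gamma=config.focal_gamma, alpha=alpha)
            else:
                task = cross_entropy_loss(out["logits"], labels)
            cost = _batch_cost(out, cost_model)
            total = task + config.cost_lambda * cost
            opt.zero_grad()
            total.backward()
            opt.step()
            task_sum += float(task.data)
            cost_sum += float(cost.data)
            n_batches += 1

        val_breakdown, val_acc, _ = _eval_loss(
            model, a_val, v_val, y_val, cost_model, config.cost_lambda,
            config.loss, config.focal_gamma, alpha,
        )
        epoch_record = {
            "epoch": epoch,
            "task_loss": task_sum / n_batches,
            "cost_penalty": cost_sum / n_batches,
            "total": task_sum / n_batches + config.cost_lambda * cost_sum / n_batches,
            "tau": tau,
            "val_loss": val_breakdown.total,
            "val_task_loss": val_breakdown.task_loss,
            "val_accuracy": val_acc,
        }
        history.append(epoch_record)
        if progress is not None:
            progress(epoch_record)

        if val_breakdown.total < best_val - 1e-12:
            best_val = val_breakdown.total
            best_state = model.state_dict()
            best_epoch = epoch
            bad_epochs = 0
        else:
            bad_epochs += 1
            # stop once val loss has failed to improve `patience` epochs running
            if bad_epochs >= max(config.patience, 1):
                break

    model.load_state_dict(best_state)
    model.eval()
    for rec in history:
        rec["best_epoch"] = best_epoch
    return model, history, split


# -- checkpoints --------------------------------------------------------------


def save_checkpoint(model: DynamicMultimodalClassifier, path, history=None) -> None:
    """Weights as .npz plus a JSON sidecar with the config (and history)."""
    path = Path(path)
    np.savez(path, **model.state_dict())
    sidecar = {"config": model.config.to_dict(), "history": history or []}
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=1))


def load_checkpoint(path) -> tuple:
    path = Path(path)
    if not path.exists() and path.with_suffix(path.suffix + ".npz").exists():
        path = path.with_suffix(path.suffix + ".npz")
    sidecar = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    config = RunConfig.from_dict(sidecar["config"])
    model = DynamicMultimodalClassifier(config)
    with np.load(path) as data:
        model.load_state_dict({k: data[k] for k in data.files})
    model.eval()
    return model, sidecar.get("history", [])
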