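"""Evaluation: the six classification metrics, significance comparison,
robustness sweeps, path-distribution and attention reporting.

Precision/recall/F1 are reported for the positive class (label 1); UA is
the unweighted (macro) average of per-class recalls and WF1 the
support-weighted average of per-class F1 scores. Significance comparison
uses a pooled-variance two-sided t-test with Cohen's d (pooled SD) and a
Bonferroni-adjusted p-value.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import f1_score, precision_score, recall_score

from .errors import ValidationError
from .fusion import expected_cost
from .simulate import apply_temporal_disturbance
from .attention import MultiHeadAttention

__all__ = [
    "MetricsReport",
    "SignificanceReport",
    "compute_metrics",
    "significance_compare",
    "robustness_sweep",
    "path_distribution",
    "attention_maps",
]


@dataclass
class MetricsReport:
    accuracy: float
    precision: float
    recall: float
    f1: float
    ua: float
    wf1: float
    n_samples: int
    support: dict
    undefined_precision: bool = False

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy, "precision": self.precision,
            "recall": self.recall, "f1": self.f1, "ua": self.ua, "wf1": self.wf1,
            "n_samples": self.n_samples,
            "support": {str(k): v for k, v in self.support.items()},
            "undefined_precision": self.undefined_precision,
        }


@dataclass
class SignificanceReport:
    mean_diff: float
    cohens_d: float
    p_raw: float
    p_adjusted: float
    n_comparisons: int

    def to_dict(self) -> dict:
        return {
            "mean_diff": self.mean_diff, "cohens_d": self.cohens_d,
            "p_raw": self.p_raw, "p_adjusted": self.p_adjusted,
            "n_comparisons": self.n_comparisons,
        }


def compute_metrics(y_true, y_pred) -> MetricsReport:
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if y_true.size == 0 or y_true.shape != y_pred.shape:
        raise ValidationError("need equal-length non-empty label vectors")
    if not (np.isin(y_true, (0, 1)).all() and np.isin(y_pred, (0, 1)).all()):
        raise ValidationError("labels must be 0/1")
    acc = float((y_true == y_pred).mean())
    labels = [0, 1]
    precision = float(precision_score(y_true, y_pred, labels=labels, pos_label=1,
                                      zero_division=0))
    recall = float(recall_score(y_true, y_pred, labels=labels, pos_label=1,
                                zero_division=0))
    f1 = float(f1_score(y_true, y_pred, labels=labels, pos_label=1, zero_division=0))
    ua = float(recall_score(y_true, y_pred, labels=labels, average="macro",
                            zero_division=0))
    wf1 = float(f1_score(y_true, y_pred, labels=labels, average="weighted",
                         zero_division=0))
    support = {0: int((y_true == 0).sum()), 1: int((y_true == 1).sum())}
    undefined = bool((y_pred == 1).sum() == 0)
    return MetricsReport(acc, precision, recall, f1, ua, wf1,
                         int(y_true.size), support, undefined)


def significance_compare(acc_a, acc_b, n_comparisons: int = 1) -> SignificanceReport:
    """Pooled two-sided t-test of two accuracy samples, Cohen's d, Bonferroni."""
    a = np.asarray(acc_a, dtype=np.float64)
    b = np.asarray(acc_b, dtype=np.float64)
    if a.size < 2 or b.size < 2:
        raise ValidationError("each sample needs length >= 2")
    mean_diff = float(a.mean() - b.mean())
    na, nb = a.size, b.size
    pooled_var = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    if pooled_var <= 0:
        raise ValidationError("zero pooled variance: Cohen's d undefined")
    t_res = stats.ttest_ind(a, b, equal_var=True)
    d = mean_diff / float(np.sqrt(pooled_var))
    p_raw = float(t_res.pvalue)
    return SignificanceReport(
        mean_diff=mean_diff, cohens_d=d, p_raw=p_raw,
        p_adjusted=min(1.0, p_raw * n_comparisons), n_comparisons=int(n_comparisons),
    )


def _evaluate(model, samples) -> MetricsReport:
    audio = [s.audio for s in samples]
    video = [s.video for s in samples]
    y_true = np.array([s.label for s in samples], dtype=int)
    y_pred = model.predict(audio, video)
    return compute_metrics(y_true, y_pred)


def robustness_sweep(model, samples, specs) -> pd.DataFrame:
    """Evaluate under each perturbation; report metrics + degradation % of
    accuracy and F1 relative to the unperturbed baseline."""
    baseline = _evaluate(model, samples)
    rows = [{"perturbation": "baseline", "sigma": 0.0, "rate": 0.0, "target": "none",
             **baseline.to_dict(),
             "accuracy_degradation_pct": 0.0, "f1_degradation_pct": 0.0}]
    for spec in specs:
        perturbed = [apply_temporal_disturbance(s, spec) for s in samples]
        rep = _evaluate(model, perturbed)
        rows.append({
            "perturbation": spec.kind, "sigma": spec.sigma, "rate": spec.rate,
            "target": spec.target, **rep.to_dict(),
            "accuracy_degradation_pct":
                100.0 * (baseline.accuracy - rep.accuracy) / baseline.accuracy
                if baseline.accuracy > 0 else np.nan,
            "f1_degradation_pct":
                100.0 * (baseline.f1 - rep.f1) / baseline.f1
                if baseline.f1 > 0 else np.nan,
        })
    return pd.DataFrame(rows)


def path_distribution(model, samples, batch_size: int = 32) -> dict:
    """Per-path usage fractions and mean costs over a dataset (hard mode)."""
    if not samples:
        raise ValidationError("empty dataset")
    model.eval()
    counts = np.zeros(4)
    nominal_costs = []
    analytic = model.analytic_costs()
    analytic_costs = []
    for start in range(0, len(samples), batch_size):
        chunk = samples[start : start + batch_size]
        audio = np.stack([s.audio for s in chunk])
        video = np.stack([s.video for s in chunk])
        out = model.forward(audio, video, mode="hard")
        for pd_, fd in zip(out["path_decisions"], out["fusion_decisions"]):
            counts[pd_.selected - 1] += 1
            nominal_costs.append(expected_cost(pd_.hard, fd.hard, model.cost_model))
            analytic_costs.append(
                analytic["expert"][pd_.selected]
                + sum(analytic["op"][k] for k in fd.selected)
            )
    fractions = counts / counts.sum()
    return {
        "fractions": {f"path_{k}": float(fractions[k - 1]) for k in (1, 2, 3, 4)},
        "mean_nominal_cost": float(np.mean(nominal_costs)),
        "mean_analytic_ops": float(np.mean(analytic_costs)),
        "n_samples": int(counts.sum()),
    }


def attention_maps(model, sample) -> dict:
    """Row-stochastic attention weights per attention module for one sample.

    Returns {module_name: array (..., heads, Nq, Nk)}; rows sum to 1 over
    allowed positions.
    """
    model.eval()
    modules = []

    def collect(name, value):
        if isinstance(value, MultiHeadAttention):
            modules.append((name, value))
        if hasattr(value, "forward") and hasattr(value, "__dict__"):
            for attr, child in vars(value).items():
                collect(f"{name}.{attr}" if name else attr, child)
        elif isinstance(value, (list, tuple)):
            for i, item in enumerate(value):
                collect(f"{name}.{i}", item)

    collect("", model)
    for _, m in modules:
        m.record = True
        m.last_weights = None
    try:
        model.forward(sample.audio[None], sample.video[None], mode="hard")
    finally:
        maps = {name: m.last_weights for name, m in modules if m.last_weights is not None}
        for _, m in modules:
            m.record = False
    return maps
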