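"""Synthetic two-modality behavioral feature sequences, plus perturbations.

The generator emulates the shape of frame-level audio descriptors (e.g. 25
low-level descriptors) and facial features (e.g. 136 landmark coordinates
plus action-unit/gaze/pose channels) without emulating their actual
statistics. The label signal is placed at two temporal scales so that the
long-range and short-range experts have genuinely different structure to
detect:

* long-term trend — a linear ramp plus a slow sinusoid (period ~ T) on a
  seeded quarter of the channels, present only in positive samples;
* short-term fluctuation — a high-frequency sinusoid (period 4-8 steps),
  amplitude-modulated in bursts for positives and unmodulated for negatives.

Only the informative modality carries class-dependent structure; the other
modality receives the negative-class signal regardless of label. I.i.d.
Gaussian noise of standard deviation ``noise_sd`` (feature z-score units) is
added everywhere. Perturbations mirror the robustness protocols: Gaussian
noise injection, temporal disturbances (truncation, resampling, shuffling,
missing values) and whole-modality masking with zero/mean imputation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .data import MultimodalSample
from .errors import ConfigError, ValidationError

__all__ = [
    "GeneratorConfig",
    "PerturbationSpec",
    "generate_dataset",
    "inject_gaussian_noise",
    "apply_temporal_disturbance",
    "mask_modality",
    "impute_missing",
]

_KINDS = ("gaussian_noise", "truncation", "resampling", "shuffling", "missing_values", "modality_mask")
_TARGETS = ("audio", "video", "both")


@dataclass
class GeneratorConfig:
    n_samples: int = 200
    T_a: int = 128
    D_a: int = 25
    T_v: int = 128
    D_v: int = 136
    trend_strength: float = 1.0
    fluctuation_strength: float = 1.0
    informative_modality: str = "both"  # audio | video | both
    noise_sd: float = 0.5
    baseline_offset_sd: float = 0.0
    positive_fraction: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_samples, self.T_a, self.D_a, self.T_v, self.D_v) < 1:
            raise ConfigError("all sizes must be >= 1")
        if self.trend_strength < 0 or self.fluctuation_strength < 0 or self.noise_sd < 0:
            raise ConfigError("strengths and noise_sd must be >= 0")
        if self.baseline_offset_sd < 0:
            raise ConfigError("baseline_offset_sd must be >= 0")
        if not 0.0 < self.positive_fraction < 1.0:
            raise ConfigError("positive_fraction must lie in (0, 1)")
        if self.informative_modality not in _TARGETS:
            raise ConfigError("informative_modality must be audio, video or both")


@dataclass
class PerturbationSpec:
    kind: str
    sigma: float = 0.0
    rate: float = 0.0
    target: str = "both"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ConfigError(f"unknown perturbation kind: {self.kind}")
        if self.target not in _TARGETS:
            raise ConfigError("target must be audio, video or both")
        if self.sigma < 0:
            raise ConfigError("sigma must be >= 0")
        if not 0.0 <= self.rate <= 1.0:
            raise ConfigError("rate must lie in [0, 1]")


# -- generation ---------------------------------------------------------------


def _signal_matrix(rng, T, D, positive, trend_strength, fluct_strength,
                   trend_channels, fluct_channels, noise_sd, informative):
    """Build one modality matrix. `informative`=False forces negative-style signal."""
    x = noise_sd * rng.standard_normal((T, D))
    t = np.arange(T) / max(T, 1)
    pos = positive and informative

    if trend_strength > 0:
        phase = rng.uniform(0, 2 * np.pi)
        if pos:
            # ramp dominates; the slow sinusoid (period ~ T) stays small enough
            # that the least-squares slope still separates the classes
            trend = trend_strength * t + 0.15 * trend_strength * np.sin(2 * np.pi * t + phase)
            x[:, trend_channels] += trend[:, None]
    if fluct_strength > 0:
        period = rng.integers(4, 9)
        carrier = np.sin(2 * np.pi * np.arange(T) / period + rng.uniform(0, 2 * np.pi))
        if pos:
            # class-dependent bursts: ~3 bursts covering about half the steps
            envelope = np.zeros(T)
            n_bursts = 3
            width = max(T // (2 * n_bursts), 1)
            for _ in range(n_bursts):
                start = int(rng.integers(0, max(T - width, 1)))
                envelope[start : start + width] = 1.0
            x[:, fluct_channels] += (2.0 * fluct_strength * envelope * carrier)[:, None]
        else:
            # negatives keep a weak, flat-envelope carrier: the class signal
            # is the burst modulation, detectable from local variance
            x[:, fluct_channels] += (0.3 * fluct_strength * carrier)[:, None]
    return x


def generate_dataset(cfg: GeneratorConfig) -> list:
    """Deterministic labeled dataset of two-modality feature sequences."""
    rng = np.random.default_rng(cfg.seed)
    chan_rng = np.random.default_rng(cfg.seed + 1)

    def pick(D):
        k = math.ceil(D / 4)
        return np.sort(chan_rng.choice(D, size=k, replace=False))

    trend_a, fluct_a = pick(cfg.D_a), pick(cfg.D_a)
    trend_v, fluct_v = pick(cfg.D_v), pick(cfg.D_v)

    samples = []
    for i in range(cfg.n_samples):
        positive = bool(rng.random() < cfg.positive_fraction)
        # label-independent per-sample baseline shift (session/calibration
        # offset); with it switched on, absolute level carries no class
        # information and only temporal structure discriminates
        offset = rng.normal(0.0, cfg.baseline_offset_sd) if cfg.baseline_offset_sd else 0.0
        audio = offset + _signal_matrix(
            rng, cfg.T_a, cfg.D_a, positive, cfg.trend_strength, cfg.fluctuation_strength,
            trend_a, fluct_a, cfg.noise_sd,
            informative=cfg.informative_modality in ("audio", "both"),
        )
        video = offset + _signal_matrix(
            rng, cfg.T_v, cfg.D_v, positive, cfg.trend_strength, cfg.fluctuation_strength,
            trend_v, fluct_v, cfg.noise_sd,
            informative=cfg.informative_modality in ("video", "both"),
        )
        samples.append(
            MultimodalSample(
                sample_id=f"s{i:05d}",
                audio=audio,
                video=video,
                label=int(positive),
                meta={"source": "synthetic", "seed": cfg.seed,
                      "informative_modality": cfg.informative_modality},
            )
        )
    return samples


# -- perturbations ------------------------------------------------------------


def _targets(target: str):
    if target == "both":
        return ("audio", "video")
    return (target,)


def inject_gaussian_noise(sample: MultimodalSample, sigma: float, target: str = "both",
                          seed: int = 0) -> MultimodalSample:
    """Add i.i.d. N(0, sigma^2) noise to the targeted modality matrices."""
    if sigma < 0:
        raise ConfigError("sigma must be >= 0")
    if target not in _TARGETS:
        raise ConfigError("target must be audio, video or both")
    out = sample.copy()
    rng = np.random.default_rng(seed)
    for mod in _targets(target):
        mat = getattr(out, mod)
        if sigma > 0:
            setattr(out, mod, mat + sigma * rng.standard_normal(mat.shape))
    return out


def _disturb_matrix(mat: np.ndarray, kind: str, rate: float, rng) -> np.ndarray:
    T = mat.shape[0]
    if kind == "truncation":
        keep = max(int(math.ceil((1.0 - rate) * T)), 1)
        return mat[:keep].copy()
    if kind == "resampling":
        m = max(int(math.ceil((1.0 - rate) * T)), 1)
        if m == T:
            return mat.copy()
        src = np.arange(T, dtype=float)
        down_pos = np.linspace(0, T - 1, m)
        up_pos = src
        down = np.empty((m, mat.shape[1]))
        up = np.empty_like(mat)
        for j in range(mat.shape[1]):
            down[:, j] = np.interp(down_pos, src, mat[:, j])
            up[:, j] = np.interp(up_pos, down_pos, down[:, j])
        return up
    if kind == "shuffling":
        k = int(round(rate * T))
        out = mat.copy()
        if k >= 2:
            idx = np.sort(rng.choice(T, size=k, replace=False))
            out[idx] = out[idx[rng.permutation(k)]]
        return out
    if kind == "missing_values":
        k = int(round(rate * T))
        out = mat.copy()
        if k > 0:
            idx = rng.choice(T, size=k, replace=False)
            out[idx] = 0.0
        return out
    raise ConfigError(f"unknown disturbance kind: {kind}")


def apply_temporal_disturbance(sample: MultimodalSample, spec: PerturbationSpec) -> MultimodalSample:
    """Apply truncation / resampling / shuffling / missing-values to a sample."""
    if spec.kind == "gaussian_noise":
        return inject_gaussian_noise(sample, spec.sigma, spec.target, spec.seed)
    if spec.kind == "modality_mask":
        tgt = "video" if spec.target == "both" else spec.target
        return mask_modality(sample, tgt, spec.rate, spec.seed)
    out = sample.copy()
    rng = np.random.default_rng(spec.seed)
    for mod in _targets(spec.target):
        setattr(out, mod, _disturb_matrix(getattr(out, mod), spec.kind, spec.rate, rng))
    return out


def mask_modality(sample: MultimodalSample, target: str, rate: float, seed: int = 0) -> MultimodalSample:
    """Mark a seeded fraction of the target modality's time steps missing.

    Flagged rows are zeroed and their indices recorded in
    ``meta['missing_mask_<modality>']``; rate=1 flags every row.
    """
    if target not in ("audio", "video"):
        raise ConfigError("mask target must be audio or video")
    if not 0.0 <= rate <= 1.0:
        raise ConfigError("rate must lie in [0, 1]")
    out = sample.copy()
    mat = getattr(out, target)
    T = mat.shape[0]
    k = int(round(rate * T))
    rng = np.random.default_rng(seed)
    idx = np.sort(rng.choice(T, size=k, replace=False)) if k > 0 else np.array([], dtype=int)
    mat = mat.copy()
    mat[idx] = 0.0
    setattr(out, target, mat)
    if k > 0:
        out.meta[f"missing_mask_{target}"] = [int(i) for i in idx]
    return out


def impute_missing(sample: MultimodalSample, strategy: str = "zero") -> MultimodalSample:
    """Fill flagged rows (zero or per-feature mean of observed rows); clears the mask."""
    if strategy not in ("zero", "mean"):
        raise ConfigError("strategy must be 'zero' or 'mean'")
    out = sample.copy()
    for mod in ("audio", "video"):
        key = f"missing_mask_{mod}"
        if key not in out.meta:
            continue
        idx = np.asarray(out.meta.pop(key), dtype=int)
        mat = getattr(out, mod).copy()
        if strategy == "zero":
            mat[idx] = 0.0
        else:
            observed = np.setdiff1d(np.arange(mat.shape[0]), idx)
            if observed.size == 0:
                raise ValidationError(
                    f"sample {out.sample_id}: cannot mean-impute {mod} with no observed rows"
                )
            mat[idx] = mat[observed].mean(axis=0)
        setattr(out, mod, mat)
    return out
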