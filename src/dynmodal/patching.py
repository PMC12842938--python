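"""Multi-scale patching of univariate series.

A series of length L is sliced into N = floor((L - P)/Str) + 1 overlapping
windows of length P at stride Str; trailing steps not covered by a full
window are dropped. The patch-to-stride (PTS) resolution R = P/Str
quantifies overlap: the long-range scale uses a lower resolution (global
pattern modeling), the short-range scale a higher one (fine-grained
fluctuations); config validation enforces R_long < R_short.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigError, ValidationError

__all__ = [
    "PatchSpec",
    "PatchedSeries",
    "split_modalities",
    "make_patches",
    "pts_resolution",
    "patch_count",
    "patch_batch",
]


@dataclass(frozen=True)
class PatchSpec:
    P: int
    Str: int
    scale: str = "long"  # long | short

    def __post_init__(self) -> None:
        if self.Str < 1 or self.P < self.Str:
            raise ConfigError("need 1 <= Str <= P")
        if self.scale not in ("long", "short"):
            raise ConfigError("scale must be 'long' or 'short'")


@dataclass
class PatchedSeries:
    patches: np.ndarray  # N x P
    spec: PatchSpec
    source_length: int


def split_modalities(x: np.ndarray) -> list:
    """Columns of an L x M matrix as M univariate series, order preserved."""
    x = np.asarray(x)
    if x.ndim != 2 or x.size == 0:
        raise ValidationError("expected a non-empty L x M matrix")
    return [x[:, i].copy() for i in range(x.shape[1])]


def patch_count(L: int, spec: PatchSpec) -> int:
    if spec.P > L:
        raise ValidationError(
            f"series length {L} shorter than patch length {spec.P}; need L >= {spec.P}"
        )
    return (L - spec.P) // spec.Str + 1


def make_patches(series: np.ndarray, spec: PatchSpec) -> PatchedSeries:
    """Slice a length-L series into N x P verbatim windows."""
    series = np.asarray(series)
    if series.ndim != 1:
        raise ValidationError("expected a 1-D series")
    L = series.shape[0]
    n = patch_count(L, spec)
    idx = np.arange(n)[:, None] * spec.Str + np.arange(spec.P)[None, :]
    return PatchedSeries(patches=series[idx], spec=spec, source_length=L)


def pts_resolution(spec: PatchSpec) -> float:
    """PTS resolution R = P / Str."""
    return spec.P / spec.Str


def patch_batch(x: np.ndarray, spec: PatchSpec) -> np.ndarray:
    """Patch every channel of a batch at once.

    x: (B, T, D) -> (B, D, N, P), sharing windows across channels.
    """
    x = np.asarray(x)
    B, T, D = x.shape
    n = patch_count(T, spec)
    idx = np.arange(n)[:, None] * spec.Str + np.arange(spec.P)[None, :]
    # (B, N, P, D) -> (B, D, N, P)
    return x[:, idx, :].transpose(0, 3, 1, 2)
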