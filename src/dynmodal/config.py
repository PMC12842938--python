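"""Run configuration: model hyperparameters, training settings, validation.

Defaults follow the published training recipe where one exists (Adam with
learning rate 1e-4, batch size 16, early stopping with patience 15 within at
most 120 epochs, seed 42; state-space block with hidden_dim 1024, state_dim
16, conv kernel 4; windowed transformer with 8 heads of dimension 64 and a
2048-wide feed-forward). Quantities the recipe leaves open (window size,
number of layers, lambda, temperature schedule, token dimension) carry
package-chosen defaults documented in docs/methods.md.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .errors import ConfigError

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    # token / patching geometry
    d_model: int = 64
    patch_long_len: int = 16
    patch_long_stride: int = 16
    patch_short_len: int = 4
    patch_short_stride: int = 1

    # long-range (state-space) expert
    mamba_hidden_dim: int = 1024
    mamba_state_dim: int = 16
    mamba_conv_kernel: int = 4
    mamba_layers: int = 1
    mamba_freeze_state_matrix: bool = False

    # short-range (local-window attention) expert
    lwt_heads: int = 8
    lwt_head_dim: int = 64
    lwt_ff_dim: int = 2048
    lwt_window: int = 5
    lwt_layers: int = 2
    lwt_max_len: int = 1024

    # dynamic fusion
    n_fusion_units: int = 4
    path_policy: str = "thresholded"  # or "argmax"
    use_nominal_costs: bool = True

    # loss / schedule
    cost_lambda: float = 0.01
    tau_start: float = 5.0
    tau_end: float = 0.1
    loss: str = "cross_entropy"  # or "focal"
    focal_gamma: float = 2.0

    # optimization
    lr: float = 1e-4
    batch_size: int = 16
    patience: int = 15
    max_epochs: int = 120
    seed: int = 42
    split_ratios: tuple = (0.7, 0.1, 0.2)

    def __post_init__(self) -> None:
        self.validate()

    # -- validation -----------------------------------------------------------

    def validate(self) -> None:
        positive_fields = [
            "d_model", "patch_long_len", "patch_long_stride", "patch_short_len",
            "patch_short_stride", "mamba_hidden_dim", "mamba_state_dim",
            "mamba_conv_kernel", "mamba_layers", "lwt_heads", "lwt_head_dim",
            "lwt_ff_dim", "lwt_window", "lwt_layers", "lwt_max_len",
            "n_fusion_units", "batch_size", "max_epochs",
        ]
        for name in positive_fields:
            if getattr(self, name) < 1:
                raise ConfigError(f"{name} must be >= 1")
        if self.cost_lambda < 0:
            raise ConfigError("cost_lambda must be >= 0")
        if not (0 < self.tau_end <= self.tau_start):
            raise ConfigError("temperature schedule needs 0 < tau_end <= tau_start")
        if self.patch_long_stride > self.patch_long_len:
            raise ConfigError("long patch stride must not exceed patch length")
        if self.patch_short_stride > self.patch_short_len:
            raise ConfigError("short patch stride must not exceed patch length")
        r_long = self.patch_long_len / self.patch_long_stride
        r_short = self.patch_short_len / self.patch_short_stride
        if not r_long < r_short:
            raise ConfigError(
                f"long-range patch resolution must be lower than short-range "
                f"(got R_long={r_long:g}, R_short={r_short:g})"
            )
        if self.loss not in ("cross_entropy", "focal"):
            raise ConfigError("loss must be 'cross_entropy' or 'focal'")
        if self.path_policy not in ("thresholded", "argmax"):
            raise ConfigError("path_policy must be 'thresholded' or 'argmax'")
        ratios = tuple(self.split_ratios)
        if len(ratios) != 3 or any(r < 0 for r in ratios):
            raise ConfigError("split_ratios must be three non-negative fractions")
        if abs(sum(ratios) - 1.0) > 1e-9:
            raise ConfigError("split_ratios must sum to 1")
        self.split_ratios = ratios

    # -- (de)serialization ----------------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["split_ratios"] = list(self.split_ratios)
        return d

    @classmethod
    def from_dict(cls, d: dict, **overrides) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        merged = {**d, **{k: v for k, v in overrides.items() if v is not None}}
        if "split_ratios" in merged:
            merged["split_ratios"] = tuple(merged["split_ratios"])
        return cls(**merged)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path, **overrides) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(d, **overrides)
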