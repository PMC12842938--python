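"""Data model and feature-container I/O.

A dataset is a list of :class:`MultimodalSample` — one labeled pair of
per-modality feature matrices (audio ``T_a x D_a``, video ``T_v x D_v``,
rows are time steps). On disk a dataset is an HDF5 container (one group per
sample with datasets ``audio``/``video`` and a ``label`` attribute) next to a
JSON-lines manifest, or a CSV directory fallback (one file per modality per
sample). Class 1 is the positive class throughout the package.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np

from .errors import ConfigError, ValidationError

__all__ = [
    "MultimodalSample",
    "DatasetSplit",
    "read_feature_container",
    "write_feature_container",
    "make_split",
]


@dataclass
class MultimodalSample:
    sample_id: str
    audio: np.ndarray  # T_a x D_a
    video: np.ndarray  # T_v x D_v
    label: int         # 1 = positive (depressed), 0 = control
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.audio = np.asarray(self.audio, dtype=np.float64)
        self.video = np.asarray(self.video, dtype=np.float64)
        self.label = int(self.label)
        self.validate()

    def validate(self) -> None:
        for name, mat in (("audio", self.audio), ("video", self.video)):
            if mat.ndim != 2 or mat.shape[0] < 1 or mat.shape[1] < 1:
                raise ValidationError(
                    f"sample {self.sample_id}: {name} must be a T x D matrix with T,D >= 1"
                )
            if not np.isfinite(mat).all():
                raise ValidationError(f"sample {self.sample_id}: {name} contains NaN/Inf")
        if self.label not in (0, 1):
            raise ValidationError(f"sample {self.sample_id}: label must be 0 or 1")

    def copy(self) -> "MultimodalSample":
        return MultimodalSample(
            sample_id=self.sample_id,
            audio=self.audio.copy(),
            video=self.video.copy(),
            label=self.label,
            meta=json.loads(json.dumps(self.meta)),
        )


@dataclass
class DatasetSplit:
    train: list
    val: list
    test: list
    ratios: tuple
    seed: int

    def __post_init__(self) -> None:
        groups = [set(self.train), set(self.val), set(self.test)]
        total = sum(len(g) for g in groups)
        if len(set().union(*groups)) != total:
            raise ValidationError("splits must be disjoint")


# -- container I/O ------------------------------------------------------------


def _manifest_path(path: Path) -> Path:
    return path.with_name(path.name + ".manifest.jsonl")


def _sample_record(s: MultimodalSample) -> dict:
    return {
        "sample_id": s.sample_id,
        "T_a": int(s.audio.shape[0]),
        "D_a": int(s.audio.shape[1]),
        "T_v": int(s.video.shape[0]),
        "D_v": int(s.video.shape[1]),
        "label": int(s.label),
        "meta": s.meta,
    }


def write_feature_container(samples, path, fmt: str = "hdf5") -> dict:
    """Write samples + manifest; returns the manifest summary."""
    samples = list(samples)
    if not samples:
        raise ValidationError("refusing to write an empty dataset")
    for s in samples:
        s.validate()
    path = Path(path)
    hist = {1: sum(s.label == 1 for s in samples), 0: sum(s.label == 0 for s in samples)}
    summary = {
        "_summary": True,
        "n_samples": len(samples),
        "label_histogram": {str(k): v for k, v in hist.items()},
        "format": fmt,
    }
    if fmt == "hdf5":
        with h5py.File(path, "w") as f:
            for i, s in enumerate(samples):
                g = f.create_group(f"{i:06d}_{s.sample_id}")
                g.create_dataset("audio", data=s.audio)
                g.create_dataset("video", data=s.video)
                g.attrs["label"] = s.label
                g.attrs["sample_id"] = s.sample_id
                g.attrs["meta"] = json.dumps(s.meta)
        manifest = _manifest_path(path)
    elif fmt == "csv":
        path.mkdir(parents=True, exist_ok=True)
        for s in samples:
            np.savetxt(path / f"{s.sample_id}_audio.csv", s.audio, delimiter=",", fmt="%.10g")
            np.savetxt(path / f"{s.sample_id}_video.csv", s.video, delimiter=",", fmt="%.10g")
        manifest = path / "manifest.jsonl"
    else:
        raise ConfigError(f"unknown container format: {fmt}")
    with open(manifest, "w") as fh:
        fh.write(json.dumps(summary) + "\n")
        for s in samples:
            fh.write(json.dumps(_sample_record(s)) + "\n")
    return summary


def read_feature_container(path) -> list:
    """Read samples back in manifest order, validating shapes and labels."""
    path = Path(path)
    if path.is_dir():
        manifest = path / "manifest.jsonl"
        fmt = "csv"
    else:
        manifest = _manifest_path(path)
        fmt = "hdf5"
        if not path.exists():
            raise FileNotFoundError(f"container not found: {path}")
    if not manifest.exists():
        raise FileNotFoundError(f"manifest not found: {manifest}")
    records = [json.loads(line) for line in manifest.read_text().splitlines() if line.strip()]
    records = [r for r in records if not r.get("_summary")]

    samples = []
    if fmt == "hdf5":
        with h5py.File(path, "r") as f:
            by_id = {}
            for key in f:
                g = f[key]
                by_id[str(g.attrs["sample_id"])] = (
                    np.asarray(g["audio"]),
                    np.asarray(g["video"]),
                    int(g.attrs["label"]),
                    json.loads(g.attrs.get("meta", "{}")),
                )
            for rec in records:
                sid = rec["sample_id"]
                if sid not in by_id:
                    raise ValidationError(f"sample {sid} listed in manifest but missing from container")
                audio, video, label, meta = by_id[sid]
                _check_record(sid, rec, audio, video, label)
                samples.append(MultimodalSample(sid, audio, video, label, meta))
    else:
        for rec in records:
            sid = rec["sample_id"]
            a_path = path / f"{sid}_audio.csv"
            v_path = path / f"{sid}_video.csv"
            if not a_path.exists() or not v_path.exists():
                raise FileNotFoundError(f"CSV files for sample {sid} not found")
            audio = np.loadtxt(a_path, delimiter=",", ndmin=2)
            video = np.loadtxt(v_path, delimiter=",", ndmin=2)
            _check_record(sid, rec, audio, video, rec["label"])
            samples.append(MultimodalSample(sid, audio, video, rec["label"], rec.get("meta", {})))
    return samples


def _check_record(sid, rec, audio, video, label) -> None:
    if audio.shape != (rec["T_a"], rec["D_a"]):
        raise ValidationError(
            f"sample {sid}: audio shape {audio.shape} does not match manifest "
            f"({rec['T_a']}, {rec['D_a']})"
        )
    if video.shape != (rec["T_v"], rec["D_v"]):
        raise ValidationError(
            f"sample {sid}: video shape {video.shape} does not match manifest "
            f"({rec['T_v']}, {rec['D_v']})"
        )
    if int(label) != int(rec["label"]):
        raise ValidationError(f"sample {sid}: label mismatch vs manifest")


# -- splitting ----------------------------------------------------------------


def _largest_remainder(n: int, ratios) -> list:
    """Apportion n into len(ratios) integer counts by largest remainder."""
    exact = [n * r for r in ratios]
    counts = [int(np.floor(e)) for e in exact]
    remainder = n - sum(counts)
    order = sorted(range(len(ratios)), key=lambda i: exact[i] - counts[i], reverse=True)
    for i in order[:remainder]:
        counts[i] += 1
    return counts


def make_split(samples, ratios, seed: int) -> DatasetSplit:
    """Deterministic subject-level split with largest-remainder apportionment."""
    ratios = tuple(ratios)
    if len(ratios) != 3 or any(r < 0 for r in ratios):
        raise ConfigError("ratios must be three non-negative fractions")
    if abs(sum(ratios) - 1.0) > 1e-9:
        raise ConfigError("ratios must sum to 1")
    ids = [s.sample_id if isinstance(s, MultimodalSample) else str(s) for s in samples]
    if len(set(ids)) != len(ids):
        raise ValidationError("duplicate sample_ids")
    counts = _largest_remainder(len(ids), ratios)
    for r, c in zip(ratios, counts):
        if r > 0 and c == 0:
            raise ConfigError("not enough samples to populate every nonzero split")
    rng = np.random.default_rng(seed)
    perm = [ids[i] for i in rng.permutation(len(ids))]
    train = perm[: counts[0]]
    val = perm[counts[0] : counts[0] + counts[1]]
    test = perm[counts[0] + counts[1] :]
    return DatasetSplit(train=train, val=val, test=test, ratios=ratios, seed=seed)
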