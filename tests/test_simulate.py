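"""Synthetic generator signal structure and perturbation contracts."""

import numpy as np
import pytest

from dynmodal.errors import ConfigError, ValidationError
from dynmodal.simulate import (
    GeneratorConfig,
    PerturbationSpec,
    apply_temporal_disturbance,
    generate_dataset,
    impute_missing,
    inject_gaussian_noise,
    mask_modality,
)


def _slopes(samples, modality):
    out = []
    for s in samples:
        mat = getattr(s, modality)
        t = np.arange(mat.shape[0])
        out.append([np.polyfit(t, mat[:, c], 1)[0] for c in range(mat.shape[1])])
    return np.asarray(out)


def test_generator_determinism():
    cfg = GeneratorConfig(n_samples=10, T_a=32, D_a=3, T_v=32, D_v=3, seed=5)
    a = generate_dataset(cfg)
    b = generate_dataset(cfg)
    for x, y in zip(a, b):
        np.testing.assert_array_equal(x.audio, y.audio)
        np.testing.assert_array_equal(x.video, y.video)
        assert x.label == y.label


def test_trend_signal_in_informative_modality_only():
    cfg = GeneratorConfig(
        n_samples=200, T_a=64, D_a=4, T_v=64, D_v=4, trend_strength=1.0,
        fluctuation_strength=0.0, informative_modality="audio", noise_sd=0.0,
        positive_fraction=0.5, seed=11,
    )
    samples = generate_dataset(cfg)
    labels = np.array([s.label for s in samples])
    audio_slopes = _slopes(samples, "audio").mean(axis=1)
    video_slopes = _slopes(samples, "video").mean(axis=1)
    # audio slope separates the classes; video slopes are identical (zero noise)
    assert audio_slopes[labels == 1].mean() > audio_slopes[labels == 0].mean() + 1e-3
    assert np.allclose(video_slopes[labels == 1].mean(), video_slopes[labels == 0].mean(),
                       atol=1e-9)


def test_slope_oracle_separates_at_low_noise():
    """A trend-slope threshold classifier exceeds 95% accuracy at small noise."""
    cfg = GeneratorConfig(
        n_samples=200, T_a=64, D_a=4, T_v=64, D_v=4, trend_strength=1.0,
        fluctuation_strength=1.0, informative_modality="audio", noise_sd=0.1,
        positive_fraction=0.5, seed=11,
    )
    samples = generate_dataset(cfg)
    labels = np.array([s.label for s in samples])
    slopes = _slopes(samples, "audio")
    # pick the most separating channel, threshold at the midpoint
    best_acc = 0.0
    for c in range(slopes.shape[1]):
        thr = 0.5 * (slopes[labels == 1, c].mean() + slopes[labels == 0, c].mean())
        acc = ((slopes[:, c] > thr).astype(int) == labels).mean()
        best_acc = max(best_acc, acc)
    assert best_acc > 0.95


def test_no_signal_means_identical_distributions():
    cfg = GeneratorConfig(
        n_samples=50, T_a=32, D_a=3, T_v=32, D_v=3, trend_strength=0.0,
        fluctuation_strength=0.0, noise_sd=1.0, positive_fraction=0.3, seed=2,
    )
    samples = generate_dataset(cfg)
    pos = np.concatenate([s.audio.ravel() for s in samples if s.label == 1])
    neg = np.concatenate([s.audio.ravel() for s in samples if s.label == 0])
    # same N(0, 1) distribution in both classes
    assert abs(pos.mean() - neg.mean()) < 0.05
    assert abs(pos.std() - neg.std()) < 0.05


def test_positive_fraction_is_expected_rate():
    cfg = GeneratorConfig(n_samples=2000, T_a=4, D_a=1, T_v=4, D_v=1,
                          positive_fraction=0.3, seed=9)
    labels = np.array([s.label for s in generate_dataset(cfg)])
    assert abs(labels.mean() - 0.3) < 0.03


def test_config_validation():
    with pytest.raises(ConfigError):
        GeneratorConfig(positive_fraction=0.0)
    with pytest.raises(ConfigError):
        GeneratorConfig(noise_sd=-1.0)
    with pytest.raises(ConfigError):
        PerturbationSpec(kind="explosion")


# -- perturbations ------------------------------------------------------------


@pytest.fixture
def sample():
    cfg = GeneratorConfig(n_samples=1, T_a=100, D_a=3, T_v=100, D_v=2, seed=3)
    return generate_dataset(cfg)[0]


def test_noise_identity_and_targeting(sample):
    out = inject_gaussian_noise(sample, sigma=0.0, target="both", seed=1)
    np.testing.assert_array_equal(out.audio, sample.audio)
    np.testing.assert_array_equal(out.video, sample.video)
    out = inject_gaussian_noise(sample, sigma=1.0, target="audio", seed=1)
    np.testing.assert_array_equal(out.video, sample.video)
    assert not np.array_equal(out.audio, sample.audio)
    with pytest.raises(ConfigError):
        inject_gaussian_noise(sample, sigma=-0.1)


def test_noise_moment():
    rng = np.random.default_rng(0)
    from dynmodal.data import MultimodalSample

    big = MultimodalSample("big", rng.standard_normal((2000, 10)),
                           rng.standard_normal((4, 2)), 0)
    out = inject_gaussian_noise(big, sigma=0.5, target="audio", seed=5)
    diff = (out.audio - big.audio).ravel()
    assert diff.size >= 10_000
    assert abs(diff.var() - 0.25) / 0.25 < 0.05


@pytest.mark.parametrize("kind,rate,check", [
    ("truncation", 0.0, "identity"),
    ("resampling", 0.0, "identity"),
    ("shuffling", 0.0, "identity"),
    ("missing_values", 0.0, "identity"),
])
def test_disturbance_rate_zero_identity(sample, kind, rate, check):
    spec = PerturbationSpec(kind=kind, rate=rate, target="both", seed=1)
    out = apply_temporal_disturbance(sample, spec)
    np.testing.assert_array_equal(out.audio, sample.audio)
    np.testing.assert_array_equal(out.video, sample.video)


def test_truncation_keeps_prefix(sample):
    spec = PerturbationSpec(kind="truncation", rate=0.5, target="audio", seed=0)
    out = apply_temporal_disturbance(sample, spec)
    assert out.audio.shape[0] == 50
    np.testing.assert_array_equal(out.audio, sample.audio[:50])
    np.testing.assert_array_equal(out.video, sample.video)


def test_shuffle_full_rate_is_permutation(sample):
    spec = PerturbationSpec(kind="shuffling", rate=1.0, target="audio", seed=4)
    out = apply_temporal_disturbance(sample, spec)
    got = {tuple(r) for r in out.audio}
    want = {tuple(r) for r in sample.audio}
    assert got == want
    assert not np.array_equal(out.audio, sample.audio)


def test_missing_values_row_count(sample):
    spec = PerturbationSpec(kind="missing_values", rate=0.3, target="audio", seed=4)
    out = apply_temporal_disturbance(sample, spec)
    zero_rows = int((np.abs(out.audio).sum(axis=1) == 0).sum())
    assert zero_rows == 30


def test_resampling_preserves_shape_loses_detail(sample):
    spec = PerturbationSpec(kind="resampling", rate=0.5, target="audio", seed=0)
    out = apply_temporal_disturbance(sample, spec)
    assert out.audio.shape == sample.audio.shape
    assert not np.array_equal(out.audio, sample.audio)
    # endpoints survive linear down-up interpolation
    np.testing.assert_allclose(out.audio[0], sample.audio[0])
    np.testing.assert_allclose(out.audio[-1], sample.audio[-1])


def test_perturbations_never_touch_label_or_id(sample):
    for spec in [PerturbationSpec(kind="truncation", rate=0.4),
                 PerturbationSpec(kind="gaussian_noise", sigma=1.0)]:
        out = apply_temporal_disturbance(sample, spec)
        assert out.sample_id == sample.sample_id and out.label == sample.label


# -- masking / imputation -----------------------------------------------------


def test_mask_counts(sample):
    out = mask_modality(sample, "video", rate=0.3, seed=2)
    assert len(out.meta["missing_mask_video"]) == 30
    out = mask_modality(sample, "video", rate=1.0, seed=2)
    assert len(out.meta["missing_mask_video"]) == sample.video.shape[0]
    out = mask_modality(sample, "video", rate=0.0, seed=2)
    assert "missing_mask_video" not in out.meta
    np.testing.assert_array_equal(out.video, sample.video)


def test_impute_mean_arithmetic():
    from dynmodal.data import MultimodalSample

    s = MultimodalSample("m", np.array([[1.0, 3.0], [3.0, 5.0], [9.0, 9.0]]),
                         np.ones((2, 2)), 0)
    masked = mask_modality(s, "audio", rate=0.0, seed=0)
    masked.meta["missing_mask_audio"] = [2]
    masked.audio[2] = 0.0
    out = impute_missing(masked, "mean")
    np.testing.assert_allclose(out.audio[2], [2.0, 4.0])
    assert "missing_mask_audio" not in out.meta


def test_impute_zero_and_identity(sample):
    untouched = impute_missing(sample, "zero")
    np.testing.assert_array_equal(untouched.audio, sample.audio)
    masked = mask_modality(sample, "audio", rate=0.2, seed=1)
    out = impute_missing(masked, "zero")
    idx = masked.meta["missing_mask_audio"]
    assert np.abs(out.audio[idx]).sum() == 0.0


def test_impute_mean_all_missing_errors(sample):
    masked = mask_modality(sample, "audio", rate=1.0, seed=1)
    with pytest.raises(ValidationError):
        impute_missing(masked, "mean")
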