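"""Gumbel-Softmax calibration, losses, annealing and the training loop."""

import numpy as np
import pytest

from dynmodal import nn
from dynmodal.errors import ConfigError, ValidationError
from dynmodal.fusion import CostModel
from dynmodal.nn import Tensor
from dynmodal.training import (
    LossBreakdown,
    TemperatureSchedule,
    anneal_temperature,
    classify_head,
    cross_entropy_loss,
    focal_loss,
    gumbel_softmax_sample,
    resource_aware_loss,
    save_checkpoint,
    load_checkpoint,
    train_model,
)
from tests.conftest import small_config


# -- Gumbel-Softmax -----------------------------------------------------------


def test_gumbel_soft_sums_to_one():
    rng = np.random.default_rng(0)
    for tau in (0.1, 1.0, 10.0):
        g = gumbel_softmax_sample(np.array([1.0, -2.0, 0.3]), tau, rng)
        assert abs(float(g.data.sum()) - 1.0) < 1e-6


def test_gumbel_hard_calibration():
    """Hard samples follow categorical(softmax(logits)) — Gumbel-max trick."""
    logits = np.log(np.array([0.7, 0.2, 0.1]))
    rng = np.random.default_rng(42)
    counts = np.zeros(3)
    n = 10_000
    for _ in range(n):
        g = gumbel_softmax_sample(logits, 3.0, rng, hard=True)
        counts[int(g.data.argmax())] += 1
    np.testing.assert_allclose(counts / n, [0.7, 0.2, 0.1], atol=0.02)


def test_gumbel_low_temperature_sharpens_to_argmax():
    logits = np.array([0.5, 1.5, -0.3])
    noise_rng = np.random.default_rng(7)
    noise = noise_rng.gumbel(size=3)
    winner = int(np.argmax(logits + noise))
    # replay identical noise at decreasing tau
    for tau, tol in ((1.0, None), (0.01, 1e-3)):
        rng = np.random.default_rng(7)
        soft = gumbel_softmax_sample(logits, tau, rng, hard=False)
        if tol is not None:
            onehot = np.eye(3)[winner]
            np.testing.assert_allclose(soft.data, onehot, atol=tol)


def test_gumbel_single_category_and_bad_tau():
    rng = np.random.default_rng(1)
    g = gumbel_softmax_sample(np.array([3.0]), 1.0, rng)
    np.testing.assert_allclose(g.data, [1.0])
    with pytest.raises(ConfigError):
        gumbel_softmax_sample(np.array([1.0, 2.0]), 0.0, rng)


def test_gumbel_straight_through_gradient():
    logits = Tensor(np.array([0.2, -0.1, 0.4]), requires_grad=True)
    g = gumbel_softmax_sample(logits, 1.0, np.random.default_rng(3), hard=True)
    assert set(np.unique(g.data)) <= {0.0, 1.0}
    (g * Tensor(np.array([1.0, 2.0, 3.0]))).sum().backward()
    assert logits.grad is not None and np.abs(logits.grad).sum() > 0


# -- losses -------------------------------------------------------------------


def test_resource_aware_loss_identities():
    cm = CostModel(op_cost={1: 0.05, 2: 0.06, 3: 0.07, 4: 0.08})
    p = np.array([1.0, 0.0, 0.0, 0.0])
    pis = np.tile(np.eye(4)[0], (4, 1))
    total, br = resource_aware_loss(0.3, p, pis, cm, lam=0.0)
    assert total == 0.3 and br.cost_penalty > 0
    total1, br1 = resource_aware_loss(0.3, p, pis, cm, lam=1.0)
    np.testing.assert_allclose(total1, 0.3 + 0.6 + 4 * 0.05, atol=1e-12)
    total2, _ = resource_aware_loss(0.3, p, pis, cm, lam=2.0)
    np.testing.assert_allclose(total2 - 0.3, 2 * (total1 - 0.3), atol=1e-12)
    with pytest.raises(ConfigError):
        resource_aware_loss(0.3, p, pis, cm, lam=-0.1)


def test_loss_breakdown_invariant():
    with pytest.raises(ValidationError):
        LossBreakdown(task_loss=1.0, cost_penalty=1.0, total=5.0, lam=0.1)


def test_focal_reduces_to_cross_entropy_at_gamma_zero():
    rng = np.random.default_rng(0)
    logits = Tensor(rng.standard_normal((6, 2)))
    labels = np.array([0, 1, 1, 0, 1, 0])
    probs = nn.softmax(logits, axis=-1)
    ce = cross_entropy_loss(logits, labels)
    fl = focal_loss(probs, labels, gamma=0.0, alpha=None)
    np.testing.assert_allclose(float(fl.data), float(ce.data), atol=1e-12)


def test_focal_values():
    probs = np.array([[0.5, 0.5]])
    val = float(focal_loss(probs, np.array([1]), gamma=2.0).data)
    np.testing.assert_allclose(val, -0.25 * np.log(0.5), atol=1e-12)  # ~0.1733
    sure = float(focal_loss(np.array([[0.0, 1.0]]), np.array([1]), gamma=2.0).data)
    assert abs(sure) < 1e-12  # p_y = 1 contributes nothing
    # p_y = 0 is clamped, not infinite
    clamped = float(focal_loss(np.array([[1.0, 0.0]]), np.array([1]), gamma=2.0).data)
    assert np.isfinite(clamped)


def test_classify_head_contracts():
    lin = nn.Linear(4, 2, np.random.default_rng(0))
    lin.weight.data[:] = 0.0
    lin.bias.data[:] = 0.0
    p = classify_head(np.ones(4), lin)
    np.testing.assert_allclose(p.data, [0.5, 0.5], atol=1e-12)
    lin.bias.data[:] = 3.0  # equal shift leaves softmax unchanged
    np.testing.assert_allclose(classify_head(np.ones(4), lin).data, [0.5, 0.5],
                               atol=1e-12)


# -- temperature schedule -----------------------------------------------------


def test_anneal_endpoints_and_midpoint():
    sched = TemperatureSchedule(5.0, 0.1, epochs=3)
    assert anneal_temperature(0, sched) == 5.0
    np.testing.assert_allclose(anneal_temperature(1, sched), np.sqrt(0.5), atol=1e-12)
    np.testing.assert_allclose(anneal_temperature(2, sched), 0.1, atol=1e-12)
    taus = [anneal_temperature(e, TemperatureSchedule(5.0, 0.1, epochs=10))
            for e in range(10)]
    assert all(a >= b for a, b in zip(taus, taus[1:])) and min(taus) > 0
    with pytest.raises(ConfigError):
        anneal_temperature(3, sched)
    with pytest.raises(ConfigError):
        TemperatureSchedule(0.1, 5.0, epochs=3)


# -- training loop ------------------------------------------------------------


def test_training_deterministic_and_checkpoint_roundtrip(tiny_samples, tmp_path):
    cfg = small_config(max_epochs=2, patience=1, split_ratios=(0.6, 0.2, 0.2))
    m1, h1, _ = train_model(tiny_samples, cfg)
    m2, h2, _ = train_model(tiny_samples, cfg)
    assert h1 == h2
    for (n1, p1), (n2, p2) in zip(sorted(m1.named_parameters()),
                                  sorted(m2.named_parameters())):
        assert n1 == n2
        np.testing.assert_array_equal(p1.data, p2.data)

    path = tmp_path / "model.npz"
    save_checkpoint(m1, path, history=h1)
    m3, h3 = load_checkpoint(path)
    audio = np.stack([s.audio for s in tiny_samples[:4]])
    video = np.stack([s.video for s in tiny_samples[:4]])
    with nn.no_grad():
        out1 = m1.forward(audio, video, mode="hard")
        out3 = m3.forward(audio, video, mode="hard")
    np.testing.assert_array_equal(out1["probs"].data, out3["probs"].data)
    assert [r["epoch"] for r in h3] == [r["epoch"] for r in h1]


def test_patience_zero_stops_at_first_plateau(tiny_samples):
    cfg = small_config(max_epochs=10, patience=0, lr=0.0,
                       split_ratios=(0.6, 0.2, 0.2))
    # zero learning rate: the val loss can never improve after epoch 0
    _, history, _ = train_model(tiny_samples, cfg)
    assert len(history) == 2


def test_empty_split_rejected(tiny_samples):
    cfg = small_config(split_ratios=(1.0, 0.0, 0.0))
    with pytest.raises(ValidationError):
        train_model(tiny_samples, cfg)
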