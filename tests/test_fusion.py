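"""Path gating, thresholded selection, experts, fusion cells and costs."""

import itertools

import numpy as np
import pytest

from dynmodal import nn
from dynmodal.errors import ConfigError, ValidationError
from dynmodal.fusion import (
    CostModel,
    ExpertBank,
    FusionCell,
    LightAudioEncoder,
    PathGate,
    compress_video,
    expected_cost,
    measure_flops,
    path_gate_scores,
    select_path,
)
from dynmodal.nn import Tensor


# -- light audio encoder / gate ----------------------------------------------


def test_light_audio_encoder_outputs_512():
    enc = LightAudioEncoder(6, np.random.default_rng(0))
    out = enc(Tensor(np.random.default_rng(1).standard_normal((10, 6))))
    assert out.shape == (512,)
    with pytest.raises(ValidationError):
        enc(Tensor(np.zeros((0, 6))))


def test_light_audio_encoder_zero_input_zero_bias():
    enc = LightAudioEncoder(6, np.random.default_rng(0))
    enc.conv.bias.data[:] = 0.0
    enc.proj.bias.data[:] = 0.0
    out = enc(Tensor(np.zeros((7, 6))))
    np.testing.assert_allclose(out.data, 0.0, atol=1e-15)


def test_path_gate_simplex_and_determinism():
    gate = PathGate(np.random.default_rng(0))
    gate.eval()
    f = Tensor(np.random.default_rng(1).standard_normal(512))
    s1 = path_gate_scores(gate, f).data
    s2 = path_gate_scores(gate, f).data
    np.testing.assert_array_equal(s1, s2)  # dropout off in eval
    assert abs(s1.sum() - 1.0) < 1e-6 and (s1 > 0).all()


def test_path_gate_zero_weights_uniform():
    gate = PathGate(np.random.default_rng(0))
    for lin in (gate.fc1, gate.fc2):
        lin.weight.data[:] = 0.0
        lin.bias.data[:] = 0.0
    s = path_gate_scores(gate, Tensor(np.ones(512))).data
    np.testing.assert_allclose(s, 0.25, atol=1e-12)


# -- thresholded selection ----------------------------------------------------


@pytest.mark.parametrize("scores,expected", [
    ((0.05, 0.02, 0.92, 0.01), 3),   # confident: argmax above 0.9
    ((0.05, 0.80, 0.10, 0.05), 3),   # borderline: escalate p+1
    ((0.45, 0.30, 0.15, 0.10), 2),   # low confidence, strong audio score
    ((0.30, 0.30, 0.20, 0.20), 4),   # uncertain: full modality
    ((0.92, 0.04, 0.02, 0.02), 1),   # audio path returns immediately
    ((0.02, 0.02, 0.04, 0.92), 4),
    ((0.05, 0.05, 0.10, 0.80), 4),   # escalation clamps at 4
])
def test_select_path_branch_table(scores, expected):
    assert select_path(np.array(scores)) == expected


def _oracle_select(scores):
    conf = max(scores)
    if conf > 0.75:
        p = int(np.argmax(scores)) + 1
        if p == 1:
            return 1
        return p if conf > 0.9 else min(p + 1, 4)
    return 2 if scores[0] > 0.4 else 4


def test_select_path_exhaustive_simplex_grid():
    """Every 0.05-step simplex point agrees with a hand-coded branch oracle."""
    step = 0.05
    n = 20
    checked = 0
    for a in range(n + 1):
        for b in range(n + 1 - a):
            for c in range(n + 1 - a - b):
                d = n - a - b - c
                s = np.array([a, b, c, d], dtype=float) / n
                assert select_path(s) == _oracle_select(s)
                checked += 1
    assert checked == 1771


# -- compressed video ---------------------------------------------------------


def test_compress_video_contracts():
    x = np.random.default_rng(0).standard_normal((5, 32))
    out1 = compress_video(x, seed=3)
    out2 = compress_video(x, seed=3)
    np.testing.assert_array_equal(out1.data, out2.data)
    assert out1.shape == (5, 8)  # 32 -> max(8, 32//4)
    np.testing.assert_allclose(compress_video(np.zeros((4, 32)), 3).data, 0.0)


def test_compress_video_preserves_norm_in_expectation():
    rng = np.random.default_rng(1)
    x = rng.standard_normal((10_000, 32))
    out = compress_video(x, seed=9)
    ratio = (out.data ** 2).sum() / (x ** 2).sum()
    assert abs(ratio - 1.0) < 0.1


# -- experts ------------------------------------------------------------------


@pytest.fixture
def bank():
    return ExpertBank(12, np.random.default_rng(0), compress_seed=5)


def test_e1_never_reads_video(bank):
    rng = np.random.default_rng(1)
    xa = Tensor(rng.standard_normal((6, 12)))
    out_none = bank.run(1, xa, None)
    out_video = bank.run(1, xa, Tensor(rng.standard_normal((6, 12))))
    np.testing.assert_array_equal(out_none.data, out_video.data)


def test_expert_requires_video_for_k_ge_2(bank):
    xa = Tensor(np.zeros((4, 12)))
    for k in (2, 3, 4):
        with pytest.raises(ValidationError):
            bank.run(k, xa, None)
    with pytest.raises(ConfigError):
        bank.run(5, xa, None)


def test_expert_costs_strictly_increasing(bank):
    rng = np.random.default_rng(2)
    xa = Tensor(rng.standard_normal((8, 12)))
    xv = Tensor(rng.standard_normal((8, 12)))
    costs = [measure_flops(bank.run, k, xa, xv) for k in (1, 2, 3, 4)]
    assert costs[0] < costs[1] < costs[2] < costs[3]


# -- fusion cells -------------------------------------------------------------


@pytest.fixture
def cell():
    return FusionCell(12, np.random.default_rng(0))


def test_o1_invariant_to_video(cell):
    rng = np.random.default_rng(3)
    h = Tensor(rng.standard_normal((6, 12)))
    xa = Tensor(rng.standard_normal((6, 12)))
    g = np.array([1.0, 0.0, 0.0, 0.0])
    out1 = cell(h, xa, Tensor(rng.standard_normal((6, 12))), g)
    out2 = cell(h, xa, Tensor(100.0 + rng.standard_normal((6, 12))), g)
    np.testing.assert_array_equal(out1.data, out2.data)


def test_cell_executes_selected_op_only(cell):
    rng = np.random.default_rng(4)
    h = Tensor(rng.standard_normal((5, 12)))
    xa = Tensor(rng.standard_normal((5, 12)))
    xv = Tensor(rng.standard_normal((7, 12)))
    for k in range(4):
        g = np.eye(4)[k]
        direct = cell.ops[k](h, xa, xv)
        routed = cell(h, xa, xv, g)
        np.testing.assert_array_equal(direct.data, routed.data)
    with pytest.raises(ValidationError):
        cell(h, xa, xv, np.array([0.5, 0.5, 0.0, 0.0]))


def test_op_costs_strictly_increasing(cell):
    rng = np.random.default_rng(5)
    h = Tensor(rng.standard_normal((8, 12)))
    xa = Tensor(rng.standard_normal((8, 12)))
    xv = Tensor(rng.standard_normal((8, 12)))
    costs = [measure_flops(cell, h, xa, xv, np.eye(4)[k]) for k in range(4)]
    assert costs[0] < costs[1] < costs[2] < costs[3]


# -- expected cost ------------------------------------------------------------


def test_expected_cost_printed_values():
    cm = CostModel(op_cost={1: 0.01, 2: 0.02, 3: 0.03, 4: 0.04})
    p = np.array([1.0, 0.0, 0.0, 0.0])
    pis = np.tile(p, (4, 1))
    total = expected_cost(p, pis, cm)
    np.testing.assert_allclose(total, 0.6 + 4 * 0.01, atol=1e-12)
    uniform = np.full(4, 0.25)
    # uniform path mass over the nominal tiers averages to 1.375
    with_ops = expected_cost(uniform, pis, cm)
    np.testing.assert_allclose(with_ops - 4 * 0.01, 1.375, atol=1e-12)


def test_expected_cost_monotone_in_expensive_mass():
    cm = CostModel(op_cost={1: 0.0, 2: 0.0, 3: 0.0, 4: 0.0})
    pis = np.tile(np.eye(4)[0], (2, 1))
    base = expected_cost(np.array([1.0, 0, 0, 0]), pis, cm)
    shifted = expected_cost(np.array([0.7, 0, 0, 0.3]), pis, cm)
    assert shifted > base


def test_expected_cost_rejects_unnormalized():
    cm = CostModel()
    with pytest.raises(ValidationError):
        expected_cost(np.array([0.5, 0.2, 0.1, 0.1]), np.tile(np.eye(4)[0], (2, 1)), cm)


def test_cost_model_ordering_enforced():
    with pytest.raises(ConfigError):
        CostModel(expert_cost={1: 1.0, 2: 0.5, 3: 1.6, 4: 2.3})
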