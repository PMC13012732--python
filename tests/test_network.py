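"""SS2D wiring, LEFN, holistic blocks, the UNet, loss, and efficiency probes."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hicmamba.nn.autograd import Tensor
from hicmamba.network import (LEFN, SS2D, HiCMambaNet, HolisticBlock,
                              NetworkConfig, cross_merge, cross_scan,
                              count_macs, hicmamba_forward, l1_loss,
                              parameter_count)


# ---------------------------------------------------------------------------
# cross scan / merge

def test_cross_scan_2x2_hand_enumeration():
    fm = np.array([[[1.0, 2.0], [3.0, 4.0]]])  # a,b / c,d as one channel
    p1, p2, p3, p4 = cross_scan(fm)
    assert p1[:, 0].tolist() == [1, 2, 3, 4]
    assert p2[:, 0].tolist() == [4, 3, 2, 1]
    assert p3[:, 0].tolist() == [1, 3, 2, 4]
    assert p4[:, 0].tolist() == [4, 2, 3, 1]


def test_cross_scan_degenerate_single_pixel():
    fm = np.full((3, 1, 1), 5.0)
    for p in cross_scan(fm):
        assert p.shape == (1, 3)
        assert np.all(p == 5.0)


@given(st.integers(1, 5), st.integers(1, 6), st.integers(1, 6),
       st.integers(0, 2 ** 31 - 1))
@settings(derandomize=True, max_examples=30, deadline=None)
def test_each_path_is_a_permutation(c, h, w, seed):
    fm = np.random.default_rng(seed).standard_normal((c, h, w))
    ref = np.sort(fm.reshape(c, -1), axis=1)
    for p in cross_scan(fm):
        assert p.shape == (h * w, c)
        assert np.allclose(np.sort(p.T, axis=1), ref)


@given(st.integers(1, 4), st.integers(1, 5), st.integers(1, 5),
       st.integers(0, 2 ** 31 - 1))
@settings(derandomize=True, max_examples=30, deadline=None)
def test_cross_roundtrip_property(c, h, w, seed):
    fm = np.random.default_rng(seed).integers(-50, 50, (c, h, w)).astype(float)
    assert np.array_equal(cross_merge(cross_scan(fm), h, w), 4 * fm)


def test_cross_merge_roundtrip_is_4x_identity():
    rng = np.random.default_rng(1)
    fm = rng.integers(0, 100, (3, 4, 5)).astype(float)
    out = cross_merge(cross_scan(fm), 4, 5)
    assert np.array_equal(out, 4 * fm)  # bit-exact for integer-valued input


def test_cross_merge_additive_in_paths():
    rng = np.random.default_rng(2)
    fm = rng.standard_normal((2, 3, 3))
    paths = cross_scan(fm)
    paths[1] = np.zeros_like(paths[1])
    out = cross_merge(paths, 3, 3)
    assert np.allclose(out, 3 * fm)


# ---------------------------------------------------------------------------
# SS2D

def test_ss2d_preserves_shape():
    ss = SS2D(np.random.default_rng(0), channels=6, d_state=4)
    x = np.random.default_rng(1).standard_normal((2, 6, 8, 8)).astype(np.float32)
    assert ss(Tensor(x)).shape == (2, 6, 8, 8)


def test_ss2d_zero_input_zero_output_at_init():
    ss = SS2D(np.random.default_rng(0), channels=4, d_state=3)
    out = ss(Tensor(np.zeros((1, 4, 6, 6), dtype=np.float32))).data
    assert np.allclose(out, 0.0)


def test_ss2d_shared_lti_heads_commute_with_180_rotation():
    """With identical per-path parameters, the four-path union treats a
    180-degree-symmetric input symmetrically."""
    ss = SS2D(np.random.default_rng(3), channels=2, d_state=3)
    for name in ("W_in", "b_in", "W_B", "b_B", "W_C", "b_C", "W_dt", "b_dt",
                 "W_A", "b_A", "D", "W_out", "b_out"):
        p = getattr(ss, name)
        p.data = np.broadcast_to(p.data[:1], p.data.shape).copy()
    rng = np.random.default_rng(4)
    half = rng.standard_normal((1, 2, 3, 6)).astype(np.float32)
    fm = np.concatenate([half, half[:, :, ::-1, ::-1]], axis=2)  # rot180-symmetric
    out = ss(Tensor(fm)).data
    rot = out[:, :, ::-1, ::-1]
    assert np.allclose(out, rot, atol=1e-5)


def test_gated_variant_runs_and_preserves_shape():
    ss = SS2D(np.random.default_rng(5), channels=4, d_state=2, variant="gated")
    x = np.random.default_rng(6).standard_normal((1, 4, 4, 4)).astype(np.float32)
    assert ss(Tensor(x)).shape == (1, 4, 4, 4)


# ---------------------------------------------------------------------------
# LEFN and holistic block

def test_lefn_shape_and_zero_propagation():
    lefn = LEFN(np.random.default_rng(0), channels=5, expansion=2)
    x = np.zeros((2, 5, 7, 7), dtype=np.float32)
    out = lefn(Tensor(x)).data
    assert out.shape == x.shape
    assert np.allclose(out, 0.0)  # GELU(0) = 0 and zero biases at init


def test_lefn_receptive_field_is_3x3():
    lefn = LEFN(np.random.default_rng(1), channels=3)
    x = np.zeros((1, 3, 9, 9), dtype=np.float32)
    x[0, 0, 4, 4] = 1.0
    base = lefn(Tensor(np.zeros_like(x))).data
    out = lefn(Tensor(x)).data
    diff = np.abs(out - base).sum(axis=(0, 1))
    nz = np.argwhere(diff > 1e-8)
    assert nz[:, 0].min() >= 3 and nz[:, 0].max() <= 5
    assert nz[:, 1].min() >= 3 and nz[:, 1].max() <= 5


def test_holistic_block_is_identity_with_zeroed_branches():
    cfg = NetworkConfig(base_channels=4, d_state=2)
    blk = HolisticBlock(np.random.default_rng(2), 4, cfg)
    blk.ss2d.W_out.data[:] = 0
    blk.ss2d.b_out.data[:] = 0
    blk.lefn.conv3.weight.data[:] = 0
    blk.lefn.conv3.bias.data[:] = 0
    x = np.random.default_rng(3).standard_normal((2, 4, 4, 4)).astype(np.float32)
    assert np.array_equal(blk(Tensor(x)).data, x)


def test_holistic_block_gradient_includes_identity_path():
    cfg = NetworkConfig(base_channels=3, d_state=2)
    blk = HolisticBlock(np.random.default_rng(4), 3, cfg)
    x = Tensor(np.random.default_rng(5).standard_normal((1, 3, 4, 4))
               .astype(np.float32), requires_grad=True)
    blk(x).sum().backward()
    # each input pixel feeds its own output through the residual path
    assert np.abs(x.grad).min() > 0.1


# ---------------------------------------------------------------------------
# full network

@pytest.fixture(scope="module")
def tiny_net():
    return HiCMambaNet(NetworkConfig(base_channels=4, d_state=2, patch_size=8),
                       seed=0)


def test_forward_preserves_shape(tiny_net):
    out = hicmamba_forward(np.zeros((1, 8, 8), dtype=np.float32), tiny_net)
    assert out.shape == (1, 8, 8)


def test_encoder_feature_widths(tiny_net):
    x = Tensor(np.zeros((1, 1, 8, 8), dtype=np.float32))
    _, feats = tiny_net(x, return_features=True)
    assert feats["E1"].shape == (1, 4, 8, 8)
    assert feats["E2"].shape == (1, 8, 4, 4)   # 2C at H/2 x W/2
    assert feats["E3"].shape == (1, 16, 2, 2)  # 4C at H/4 x W/4


def test_indivisible_input_rejected(tiny_net):
    with pytest.raises(ValueError):
        tiny_net(Tensor(np.zeros((1, 1, 44, 41), dtype=np.float32)))


def test_forward_is_deterministic(tiny_net):
    x = np.random.default_rng(7).random((2, 1, 8, 8)).astype(np.float32)
    y1 = tiny_net(Tensor(x)).data
    y2 = tiny_net(Tensor(x)).data
    assert np.array_equal(y1, y2)


def test_parameter_count_independent_of_input_side(tiny_net):
    n = parameter_count(tiny_net)
    for side in (8, 12, 16):
        tiny_net(Tensor(np.zeros((1, 1, side, side), dtype=np.float32)))
    assert parameter_count(tiny_net) == n


# ---------------------------------------------------------------------------
# loss

def test_l1_loss_values():
    assert l1_loss([[1.0, 2], [3, 4]], [[1.0, 2], [3, 4]]) == 0.0
    assert l1_loss([[1.0, 2], [3, 4]], [[1.0, 1], [3, 3]]) == pytest.approx(0.5)


def test_l1_loss_symmetry_and_shape_check():
    rng = np.random.default_rng(1)
    a, b = rng.random((2, 5, 5))
    assert l1_loss(a, b) == pytest.approx(l1_loss(b, a))
    with pytest.raises(ValueError):
        l1_loss(a, b[:4])


# ---------------------------------------------------------------------------
# MACs counter

def test_input_projection_mac_count():
    _, layers = count_macs(NetworkConfig(), 40, per_layer=True)
    assert layers["in_conv"] * 1e9 == pytest.approx(40 * 40 * 9 * 1 * 32)


def test_macs_scale_linearly_with_pixel_count():
    cfg = NetworkConfig()
    ratio = count_macs(cfg, 320) / count_macs(cfg, 160)
    assert 3.8 <= ratio <= 4.2


def test_macs_counter_covers_both_ss2d_variants():
    minimal = count_macs(NetworkConfig(), 80)
    gated = count_macs(NetworkConfig(ss2d_variant="gated"), 80)
    assert gated > minimal > 0
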