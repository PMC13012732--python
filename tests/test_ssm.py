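"""S6 state-space machinery: discretization, scans, and their equivalences."""

import numpy as np
import pytest
from scipy.linalg import expm

from hicmamba.ssm import (S6Params, ScanWeights, convolutional_scan,
                          discretize, recurrent_scan, selective_scan,
                          ssm_kernel)


# ---------------------------------------------------------------------------
# zeroth-order-hold discretization

def test_scalar_zoh_closed_form():
    d = discretize(np.array(-1.0), np.array(2.0), 0.5)
    assert d.A_bar == pytest.approx(np.exp(-0.5), abs=1e-10)
    # (dA)^-1 (e^dA - 1) * d*B with dA = -0.5, d*B = 1
    assert d.B_bar == pytest.approx(np.expm1(-0.5) / (-0.5), abs=1e-5)
    assert d.B_bar == pytest.approx(0.78694, abs=1e-5)


def test_vanishing_timescale_gives_identity_transition():
    A = np.array([[-1.0, -2.0, -0.3]])
    d = discretize(A, np.ones_like(A), 1e-8)
    assert np.abs(d.A_bar - 1.0).max() < 1e-6


def test_diagonal_matches_matrix_exponential_oracle():
    rng = np.random.default_rng(2)
    for _ in range(20):
        s = rng.integers(2, 6)
        diag = -rng.uniform(0.1, 3.0, s)
        b = rng.standard_normal(s)
        delta = float(rng.uniform(0.05, 1.5))
        dd = discretize(diag, b, delta)
        # dense oracle: expm and linear solve on the full matrix
        A_full = np.diag(diag)
        A_bar = expm(delta * A_full)
        B_bar = np.linalg.solve(delta * A_full, A_bar - np.eye(s)) @ (delta * b)
        assert np.allclose(dd.A_bar, np.diag(A_bar), rtol=1e-10)
        assert np.allclose(dd.B_bar, B_bar, rtol=1e-9)


def test_first_order_fallback_is_euler():
    d = discretize(np.array(-2.0), np.array(3.0), 0.1, first_order=True)
    assert d.B_bar == pytest.approx(0.3)


def test_nonpositive_delta_rejected():
    with pytest.raises(ValueError):
        discretize(np.array(-1.0), np.array(1.0), 0.0)


# ---------------------------------------------------------------------------
# recurrent vs convolutional evaluation

def _params_for_discrete(a_bar, b_bar, c):
    """Continuous params whose ZOH discretization at delta=1 is (a_bar, b_bar)."""
    A = np.log(a_bar)
    B = b_bar / ((a_bar - 1.0) / A)
    return S6Params(A=np.array([[A]]), B=np.array([[B]]), C=np.array([[c]]),
                    delta=1.0)


def test_recurrent_hand_iteration():
    # discrete system A_bar=0.5, B_bar=1, C=1 on x=(1,1): h1=1, h2=1.5
    p = _params_for_discrete(0.5, 1.0, 1.0)
    y = recurrent_scan(np.array([1.0, 1.0]), p)
    assert np.allclose(y, [1.0, 1.5], atol=1e-12)


def test_single_step_is_c_bbar_x():
    p = S6Params(A=-0.7, B=1.3, C=2.0, delta=0.4)
    d = discretize(p.A, p.B, p.delta)
    y = recurrent_scan(np.array([3.0]), p)
    assert y[0] == pytest.approx(2.0 * float(np.asarray(d.B_bar).ravel()[0]) * 3.0)


def test_zero_input_gives_zero_output():
    p = S6Params(A=[[-1.0, -2.0]], B=[[1.0, 1.0]], C=[[1.0, 0.5]], delta=0.3)
    assert np.allclose(recurrent_scan(np.zeros(10), p), 0.0)


def test_kernel_leading_entry_is_c_bbar():
    p = S6Params(A=[[-1.0, -0.2]], B=[[0.7, 1.1]], C=[[2.0, -1.0]], delta=0.5)
    K = ssm_kernel(p, 4)
    d = discretize(p.A, p.B, p.delta)
    assert K[0, 0] == pytest.approx(float((p.C * d.B_bar).sum()))


def test_convolutional_matches_recurrent_hand_case():
    p = _params_for_discrete(0.5, 1.0, 1.0)
    y = convolutional_scan(np.array([1.0, 1.0]), p)
    assert np.allclose(y, [1.0, 1.5], atol=1e-10)


@pytest.mark.parametrize("T", [1, 2, 7, 64])
@pytest.mark.parametrize("d_state", [1, 4, 16])
def test_convolutional_equals_recurrent_on_random_lti(T, d_state):
    rng = np.random.default_rng(T * 100 + d_state)
    for _ in range(10):
        d = int(rng.integers(1, 4))
        p = S6Params(A=-rng.uniform(0.05, 2.0, (d, d_state)),
                     B=rng.standard_normal((d, d_state)),
                     C=rng.standard_normal((d, d_state)),
                     delta=rng.uniform(0.05, 1.0, d))
        x = rng.standard_normal((T, d))
        yr = recurrent_scan(x, p)
        yc = convolutional_scan(x, p)
        assert np.abs(yc - yr).max() <= 1e-5 * max(np.abs(yr).max(), 1e-12)


def test_convolutional_rejects_input_dependent_params():
    p = S6Params(A=-1.0, B=1.0, C=1.0, delta=0.1, input_dependent=True)
    with pytest.raises(ValueError):
        convolutional_scan(np.ones(4), p)


def test_empty_sequence_rejected():
    p = S6Params(A=-1.0, B=1.0, C=1.0, delta=0.1)
    with pytest.raises(ValueError):
        recurrent_scan(np.zeros(0), p)


# ---------------------------------------------------------------------------
# selective (input-dependent) scan

def test_constant_projections_reduce_to_lti_scan():
    d, s = 3, 4
    rng = np.random.default_rng(1)
    B_const = rng.standard_normal(s)
    C_const = rng.standard_normal(s)
    dt_const = 0.23
    A = -rng.uniform(0.2, 1.5, (d, s))
    w = ScanWeights(W_B=np.zeros((d, s)), W_C=np.zeros((d, s)),
                    W_delta=np.zeros((d, d)),
                    b_delta=np.full(d, np.log(np.expm1(dt_const))),
                    b_B=B_const, b_C=C_const,
                    input_dependent_a=False, A=A)
    x = rng.standard_normal((12, d))
    y_sel = selective_scan(x, w)
    p = S6Params(A=A, B=np.tile(B_const, (d, 1)), C=np.tile(C_const, (d, 1)),
                 delta=np.full(d, dt_const))
    y_rec = recurrent_scan(x, p)
    assert np.allclose(y_sel, y_rec, rtol=0, atol=1e-14)


def test_selective_scan_matches_naive_interpreter():
    """Independent step-by-step oracle: project, discretize, recur."""
    d, s, T = 3, 4, 16
    rng = np.random.default_rng(4)
    w = ScanWeights(W_B=rng.standard_normal((d, s)) * 0.4,
                    W_C=rng.standard_normal((d, s)) * 0.4,
                    W_delta=rng.standard_normal((d, d)) * 0.2,
                    b_delta=rng.standard_normal(d) * 0.1,
                    W_A=rng.standard_normal((d, s)) * 0.3,
                    b_A=rng.standard_normal(s) * 0.1,
                    D=rng.standard_normal(d))
    x = rng.standard_normal((T, d))
    y = selective_scan(x, w)

    h = np.zeros((d, s))
    expected = np.zeros((T, d))
    for t in range(T):
        xt = x[t]
        Bt = xt @ w.W_B + w.b_B
        Ct = xt @ w.W_C + w.b_C
        dt = np.log1p(np.exp(xt @ w.W_delta + w.b_delta))
        At = -np.exp(xt @ w.W_A + w.b_A)
        dA = dt[:, None] * At[None, :]
        Ab = np.exp(dA)
        Bb = (np.expm1(dA) / dA) * (dt[:, None] * Bt[None, :])
        h = Ab * h + Bb * xt[:, None]
        expected[t] = h @ Ct + w.D * xt
    assert np.abs(y - expected).max() <= 1e-6 * max(np.abs(expected).max(), 1.0)


def test_selective_scan_zero_input_is_zero():
    d, s = 2, 3
    w = ScanWeights(W_B=np.ones((d, s)), W_C=np.ones((d, s)),
                    W_delta=np.ones((d, d)), b_delta=np.zeros(d))
    assert np.allclose(selective_scan(np.zeros((8, d)), w), 0.0)


# ---------------------------------------------------------------------------
# invariants

def test_linearity_in_input_for_fixed_lti_params():
    rng = np.random.default_rng(6)
    p = S6Params(A=-rng.uniform(0.1, 1.0, (2, 3)),
                 B=rng.standard_normal((2, 3)), C=rng.standard_normal((2, 3)),
                 delta=[0.2, 0.7])
    x1, x2 = rng.standard_normal((2, 20, 2))
    lhs = recurrent_scan(2.0 * x1 - 3.0 * x2, p)
    rhs = 2.0 * recurrent_scan(x1, p) - 3.0 * recurrent_scan(x2, p)
    assert np.abs(lhs - rhs).max() < 1e-6


def test_stability_over_long_horizons():
    p = S6Params(A=[[-0.5, -0.01]], B=[[1.0, 1.0]], C=[[1.0, 1.0]], delta=0.5)
    x = np.ones(10_000)
    y = recurrent_scan(x, p)
    assert np.isfinite(y).all()
    assert np.abs(y).max() < 1e3


def test_outputs_continuous_in_delta():
    p1 = S6Params(A=-1.0, B=1.0, C=1.0, delta=0.3)
    p2 = S6Params(A=-1.0, B=1.0, C=1.0, delta=0.3 + 1e-6)
    x = np.random.default_rng(8).standard_normal(64)
    assert np.abs(recurrent_scan(x, p1) - recurrent_scan(x, p2)).max() < 1e-4


def test_unstable_a_rejected():
    with pytest.raises(ValueError):
        S6Params(A=0.5, B=1.0, C=1.0, delta=0.1)
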