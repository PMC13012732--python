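"""Selective state-space (S6) scan machinery.

A continuous linear state-space system

    h'(t) = A h(t) + B x(t),      y(t) = C h(t)

is discretized with the zeroth-order hold (ZOH) rule,

    A_bar = exp(dt * A),
    B_bar = (dt * A)^{-1} (exp(dt * A) - I) * dt * B,

and evaluated either as a left-to-right recurrence

    h_t = A_bar h_{t-1} + B_bar x_t,   y_t = C h_t,   h_0 = 0,

or, in the linear time-invariant (LTI) case, as a causal convolution with
the kernel K = (C B_bar, C A_bar B_bar, ..., C A_bar^{T-1} B_bar).

The *selective* variant makes the parameters functions of the input: at
each step B, C and the timescale dt (and, in the default mode, the decay
A itself) are produced by learned linear maps of x_t, the system is
re-discretized, and the recurrence is evaluated step by step.  Stability
is enforced by parameterization: A = -exp(.) is strictly negative, and
dt = softplus(.) is strictly positive.

Everything here operates on plain numpy arrays and is deliberately
sequential and simple; the trainable network uses a vectorized chunked
equivalent that is tested against these functions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import expm as _expm


def _phi(x: np.ndarray) -> np.ndarray:
    """(exp(x) - 1) / x with the removable singularity at 0 filled in."""
    x = np.asarray(x, dtype=float)
    out = np.ones_like(x)
    nz = np.abs(x) > 1e-12
    out[nz] = np.expm1(x[nz]) / x[nz]
    return out


@dataclass
class DiscretizedParams:
    """ZOH-discretized transition (A_bar) and input (B_bar) operators."""

    A_bar: np.ndarray
    B_bar: np.ndarray


@dataclass
class S6Params:
    """Continuous diagonal state-space parameters for ``d`` channels.

    A, B, C have shape (d, s) where s is the state size; A holds the
    (negative) diagonal of the state matrix per channel.  ``delta`` is the
    per-channel timescale, shape (d,).  Scalars / 1-D inputs are promoted.
    """

    A: np.ndarray
    B: np.ndarray
    C: np.ndarray
    delta: np.ndarray
    input_dependent: bool = False

    def __post_init__(self):
        self.A = np.atleast_2d(np.asarray(self.A, dtype=float))
        self.B = np.broadcast_to(np.atleast_2d(np.asarray(self.B, dtype=float)),
                                 self.A.shape).copy()
        self.C = np.broadcast_to(np.atleast_2d(np.asarray(self.C, dtype=float)),
                                 self.A.shape).copy()
        self.delta = np.broadcast_to(np.atleast_1d(np.asarray(self.delta, dtype=float)),
                                     (self.A.shape[0],)).copy()
        if np.any(self.delta <= 0):
            raise ValueError("timescale delta must be positive")
        if np.any(self.A.real > 0):
            raise ValueError("state matrix A must have non-positive real part")


def discretize(A: np.ndarray, B: np.ndarray, delta,
               first_order: bool = False) -> DiscretizedParams:
    """ZOH discretization of (A, B) at timescale ``delta``.

    For a diagonal A (given as a scalar or 1-/2-D array of diagonal
    entries) the exact elementwise closed form is used.  For a full square
    matrix A, the matrix exponential and a linear solve are used; a
    singular ``delta * A`` raises unless ``first_order`` requests the
    Euler fallback B_bar = delta * B.
    """
    delta = np.asarray(delta, dtype=float)
    if np.any(delta <= 0):
        raise ValueError("delta must be positive")
    A = np.asarray(A, dtype=float)
    B = np.asarray(B, dtype=float)
    if A.ndim == 2 and A.shape[0] == A.shape[1] and A.shape[0] > 1 and B.ndim <= 2 \
            and B.shape[0] == A.shape[0] and (B.ndim == 1 or B.shape[1] == 1):
        # full-matrix path
        dA = float(delta) * A
        A_bar = _expm(dA)
        if first_order:
            B_bar = float(delta) * B
        else:
            if abs(np.linalg.det(dA)) < 1e-300:
                raise np.linalg.LinAlgError(
                    "delta*A is singular; request first_order fallback")
            B_bar = np.linalg.solve(dA, (A_bar - np.eye(A.shape[0]))) @ (float(delta) * B)
        return DiscretizedParams(A_bar, B_bar)
    # diagonal / scalar path
    dA = delta * A if A.ndim < 2 else np.atleast_1d(delta)[:, None] * A
    A_bar = np.exp(dA)
    if first_order:
        B_bar = (delta * B if A.ndim < 2 else np.atleast_1d(delta)[:, None] * B)
    else:
        dB = delta * B if A.ndim < 2 else np.atleast_1d(delta)[:, None] * B
        B_bar = _phi(dA) * dB
    return DiscretizedParams(np.asarray(A_bar), np.asarray(B_bar))


def _promote_sequence(x: np.ndarray, d: int) -> tuple[np.ndarray, bool]:
    x = np.asarray(x, dtype=float)
    if x.ndim == 1:
        if d != 1:
            raise ValueError("1-D sequence requires single-channel parameters")
        return x[:, None], True
    return x, False


def recurrent_scan(x: np.ndarray, params: S6Params) -> np.ndarray:
    """Sequential LTI evaluation: h_t = A_bar h_{t-1} + B_bar x_t, y_t = C h_t."""
    d = params.A.shape[0]
    xs, squeeze = _promote_sequence(x, d)
    T = xs.shape[0]
    if T == 0:
        raise ValueError("empty sequence")
    disc = discretize(params.A, params.B, params.delta)
    A_bar, B_bar = disc.A_bar, disc.B_bar
    h = np.zeros_like(params.A)
    y = np.empty((T, d))
    for t in range(T):
        h = A_bar * h + B_bar * xs[t][:, None]
        y[t] = (params.C * h).sum(axis=1)
    return y[:, 0] if squeeze else y


def ssm_kernel(params: S6Params, T: int) -> np.ndarray:
    """Convolution kernel K_t = C A_bar^t B_bar, shape (T, d)."""
    disc = discretize(params.A, params.B, params.delta)
    powers = disc.A_bar[None, :, :] ** np.arange(T)[:, None, None]
    return (powers * (params.C * disc.B_bar)[None]).sum(axis=2)


def convolutional_scan(x: np.ndarray, params: S6Params) -> np.ndarray:
    """Parallel (causal convolution) evaluation of the LTI scan.

    Equals :func:`recurrent_scan` up to floating-point accumulation
    (relative tolerance ~1e-5 over T steps).
    """
    if params.input_dependent:
        raise ValueError("convolutional form requires time-invariant parameters")
    d = params.A.shape[0]
    xs, squeeze = _promote_sequence(x, d)
    T = xs.shape[0]
    if T == 0:
        raise ValueError("empty sequence")
    K = ssm_kernel(params, T)
    y = np.empty((T, d))
    for c in range(d):
        y[:, c] = np.convolve(xs[:, c], K[:, c])[:T]
    return y[:, 0] if squeeze else y


@dataclass
class ScanWeights:
    """Learned projections producing per-step S6 parameters from x_t.

    With ``input_dependent_a`` (default) the decay is A_t = -exp(x_t W_A + b_A),
    mirroring the selective-scan pseudocode in which A, B, C and dt are all
    linear functions of the input; otherwise a static ``A`` (d, s) is used,
    the standard Mamba parameterization.  dt_t = softplus(x_t W_delta + b_delta)
    is strictly positive by construction.
    """

    W_B: np.ndarray
    W_C: np.ndarray
    W_delta: np.ndarray
    b_delta: np.ndarray
    b_B: np.ndarray | None = None
    b_C: np.ndarray | None = None
    input_dependent_a: bool = True
    W_A: np.ndarray | None = None
    b_A: np.ndarray | None = None
    A: np.ndarray | None = None
    D: np.ndarray | None = None

    def __post_init__(self):
        self.W_B = np.asarray(self.W_B, dtype=float)
        self.W_C = np.asarray(self.W_C, dtype=float)
        self.W_delta = np.asarray(self.W_delta, dtype=float)
        self.b_delta = np.asarray(self.b_delta, dtype=float)
        s = self.W_B.shape[1]
        if self.b_B is None:
            self.b_B = np.zeros(s)
        if self.b_C is None:
            self.b_C = np.zeros(s)
        if self.input_dependent_a:
            if self.W_A is None:
                self.W_A = np.zeros_like(self.W_B)
            if self.b_A is None:
                self.b_A = np.zeros(s)
        elif self.A is None:
            raise ValueError("static mode requires A")


def _softplus(x: np.ndarray) -> np.ndarray:
    return np.logaddexp(0.0, x)


def selective_scan(x: np.ndarray, weights: ScanWeights) -> np.ndarray:
    """Input-dependent S6 scan: project, discretize and recur per step."""
    d = weights.W_B.shape[0]
    xs, squeeze = _promote_sequence(x, d)
    T = xs.shape[0]
    if T == 0:
        raise ValueError("empty sequence")
    s = weights.W_B.shape[1]
    h = np.zeros((d, s))
    y = np.empty((T, d))
    for t in range(T):
        xt = xs[t]
        Bt = xt @ weights.W_B + weights.b_B
        Ct = xt @ weights.W_C + weights.b_C
        dt = _softplus(xt @ weights.W_delta + weights.b_delta)
        if np.any(dt <= 0):
            raise ValueError("non-positive timescale produced")
        if weights.input_dependent_a:
            At = -np.exp(xt @ weights.W_A + weights.b_A)  # (s,), strictly negative
            dA = dt[:, None] * At[None, :]
        else:
            dA = dt[:, None] * weights.A
        A_bar = np.exp(dA)
        B_bar = _phi(dA) * (dt[:, None] * Bt[None, :])
        h = A_bar * h + B_bar * xt[:, None]
        y[t] = h @ Ct
        if weights.D is not None:
            y[t] += weights.D * xt
    return y[:, 0] if squeeze else y


__all__ = ["S6Params", "DiscretizedParams", "ScanWeights", "discretize",
           "recurrent_scan", "convolutional_scan", "selective_scan", "ssm_kernel"]
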