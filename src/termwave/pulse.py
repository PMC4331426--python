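"""Closed-form traveling-pulse profiles and the reverberation-time inversion.

In the moving frame z = x - c*t the model reduces, piece by piece in the
Heaviside output, to the linear system

    U'(z) = A U(z) - (alpha/c) * H * e1,    A = [[alpha, beta], [-delta, delta]] / c

with U = (u, q).  A traveling pulse crosses the synaptic threshold exactly
twice, at z = 0 (trailing edge) and z = w (leading edge); ahead of the
pulse (z >= w) the only bounded solution is U = 0, and behind (z <= 0) the
solution decays as z -> -inf because both eigenvalues of A have positive
real part.  Continuity of (u, q) at both edges fixes every coefficient.

Two families result.  When 4*delta*beta < (alpha-delta)^2 the eigenvalues

    lambda_pm = [alpha + delta +- sqrt((alpha+delta)^2 - 4*delta*(alpha+beta))] / (2c)

are real and the wake returns to rest monotonically.  Otherwise the
eigenvalues are complex and the wake carries damped oscillations of spatial
angular frequency r/(2c) and decay rate f = (alpha+delta)/(2c), where

    r = sqrt(4*beta*delta - (delta-alpha)^2),   g = 2*beta + alpha - delta.

The oscillatory tail's single positive lobe is the model's account of the
post-wave "reverberation" in the LFP; its temporal period 4*pi/r inverts
to an adaptation strength from an observed reverberation time.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .params import (
    CriticalDampingError,
    EigenRegime,
    RateParams,
    Regime,
    RegimeMismatchError,
    WaveShape,
    classify_eigenvalues,
)

__all__ = [
    "PulseSolutionReal",
    "PulseSolutionComplex",
    "ReverberationFit",
    "make_pulse",
    "eval_pulse_real",
    "eval_pulse_complex",
    "eval_pulse_uq",
    "profile_terms",
    "damped_period",
    "beta_from_reverberation",
    "beta0_large_alpha_limit",
]


def _frame_matrix(params: RateParams, c: float) -> np.ndarray:
    a, b, d = params.alpha, params.beta, params.delta
    return np.array([[a, b], [-d, d]]) / c


def profile_terms(params: RateParams, shape: WaveShape):
    """Exact complex-exponential representation of the pulse (u and q).

    Returns ``(mid_const, mid_terms, left_terms)`` where each term is a
    tuple ``(Cu, Cq, mu)`` of complex coefficients and rate such that

        mid  (0 < z < w):  U(z) = mid_const + sum Re(C * exp(mu*(z - w)))
        left (z <= 0):     U(z) = sum Re(C * exp(mu*z))

    and U(z) = 0 for z >= w.  This representation is shared by both
    eigenvalue regimes (the eigenvalues are simply real or conjugate) and
    only involves decaying exponentials, so downstream evaluation and the
    matching-condition integrals are free of catastrophic cancellation.
    """
    a, b = params.alpha, params.beta
    A = _frame_matrix(params, shape.c).astype(complex)
    up = a / (a + b) * np.ones(2)
    lam, V = np.linalg.eig(A)
    Vi = np.linalg.inv(V)
    coef_mid = Vi @ up
    # mid: U(z) = up - expm(A (z-w)) up
    mid_terms = [(-V[0, j] * coef_mid[j], -V[1, j] * coef_mid[j], lam[j]) for j in range(2)]
    # continuity at 0: U(0) = up - expm(-A w) up
    U0 = up - (V @ (np.exp(-lam * shape.w) * coef_mid)).real
    coef_left = Vi @ U0.astype(complex)
    left_terms = [(V[0, j] * coef_left[j], V[1, j] * coef_left[j], lam[j]) for j in range(2)]
    return a / (a + b), mid_terms, left_terms


def eval_pulse_uq(params: RateParams, shape: WaveShape, z) -> tuple[np.ndarray, np.ndarray]:
    """Evaluate (u(z), q(z)) from the exact piecewise-exponential terms.

    Regime-agnostic; serves as the reference construction the printed
    closed forms are checked against, and supplies the adaptation profile
    needed to initialize simulations with an analytic pulse.
    """
    mc, mt, lt = profile_terms(params, shape)
    z = np.asarray(z, dtype=float)
    u = np.zeros_like(z)
    q = np.zeros_like(z)
    mid = (z > 0) & (z < shape.w)
    left = z <= 0
    for Cu, Cq, mu in mt:
        e = np.exp(mu * (z[mid] - shape.w))
        u[mid] += (Cu * e).real
        q[mid] += (Cq * e).real
    u[mid] += mc
    q[mid] += mc
    for Cu, Cq, mu in lt:
        e = np.exp(mu * z[left])
        u[left] += (Cu * e).real
        q[left] += (Cq * e).real
    return u, q


# ---------------------------------------------------------------------------
# real-eigenvalue closed form
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PulseSolutionReal:
    """Closed-form pulse in the monotone-wake regime.

    ``lambda_plus`` and ``lambda_minus`` are the (real, nonnegative)
    spatial rates of the traveling frame, 1/um.
    """

    params: RateParams
    shape: WaveShape
    lambda_plus: float
    lambda_minus: float

    def __call__(self, z):
        return eval_pulse_real(self, z)


def _real_rates(params: RateParams, shape: WaveShape) -> tuple[float, float]:
    a, b, d, c = params.alpha, params.beta, params.delta, shape.c
    s = math.sqrt((a + d) ** 2 - 4.0 * d * (a + b))
    return (a + d + s) / (2.0 * c), (a + d - s) / (2.0 * c)


def eval_pulse_real(sol: PulseSolutionReal, z) -> np.ndarray:
    """Activity u(z) of the real-eigenvalue pulse (dimensionless).

    Three pieces: 0 ahead of the leading edge (z >= w); inside the
    suprathreshold interval a rise toward alpha/(alpha+beta); behind the
    trailing edge a biexponential wake decaying to rest.
    """
    p, sh = sol.params, sol.shape
    if classify_eigenvalues(p).regime is not Regime.REAL:
        raise RegimeMismatchError("params are in the COMPLEX regime; use eval_pulse_complex")
    a, b, d, c, w = p.alpha, p.beta, p.delta, sh.c, sh.w
    lp, lm = sol.lambda_plus, sol.lambda_minus
    z = np.asarray(z, dtype=float)
    u = np.zeros_like(z)
    pref = a / (d * (a + b) * (lp - lm))
    mid = (z > 0) & (z < w)
    left = z <= 0
    u[mid] = pref * (
        lm * np.exp(lp * (z[mid] - w)) * (d - c * lp)
        - lp * np.exp(lm * (z[mid] - w)) * (d - c * lm)
        + d * (lp - lm)
    )
    u[left] = pref * (
        lm * (np.exp(-w * lp) - 1.0) * (d - c * lp) * np.exp(lp * z[left])
        + lp * (1.0 - np.exp(-w * lm)) * (d - c * lm) * np.exp(lm * z[left])
    )
    return u


# ---------------------------------------------------------------------------
# complex-eigenvalue closed form
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PulseSolutionComplex:
    """Closed-form pulse in the damped-oscillatory regime.

    Carries both the raw sinusoid coefficients c1..c4 and the simplified
    amplitude/phase data (D, phi1, phi2, A1..A4).  The identities
    A3 = r + exp(-f*w)*A1 and A4 = g + exp(-f*w)*A2 hold by construction.
    """

    params: RateParams
    shape: WaveShape
    r: float  # sqrt(4*beta*delta - (delta-alpha)^2), 1/ms
    g: float  # 2*beta + alpha - delta, 1/ms
    f: float  # (delta+alpha)/(2c), 1/um
    D: float
    phi1: float
    phi2: float
    A1: float
    A2: float
    A3: float
    A4: float
    c1: float
    c2: float
    c3: float
    c4: float

    def __call__(self, z):
        return eval_pulse_complex(self, z)


def _complex_coefficients(params: RateParams, shape: WaveShape) -> dict:
    a, b, d, c, w = params.alpha, params.beta, params.delta, shape.c, shape.w
    r = math.sqrt(4.0 * b * d - (d - a) ** 2)
    g = 2.0 * b + a - d
    f = (d + a) / (2.0 * c)
    th = r / (2.0 * c)  # spatial angular frequency, 1/um
    c3 = g * math.sin(th * w) - r * math.cos(th * w)
    c4 = -g * math.cos(th * w) - r * math.sin(th * w)
    c1 = math.exp(-f * w) * c3 + r
    c2 = math.exp(-f * w) * c4 + g
    A1, A2 = c3, c4
    A3 = r + math.exp(-f * w) * A1
    A4 = g + math.exp(-f * w) * A2
    D = math.sqrt(1.0 - 2.0 * math.exp(-f * w) * math.cos(th * w) + math.exp(-2.0 * f * w))
    # a*sin(x) + b*cos(x) = sqrt(a^2+b^2) sin(x + phi), phi quadrant-aware in
    # the denominator coefficient (+pi when it is negative)
    phi1 = math.atan2(A1, A2)
    phi2 = math.atan2(A3, A4)
    return dict(r=r, g=g, f=f, th=th, c1=c1, c2=c2, c3=c3, c4=c4,
                A1=A1, A2=A2, A3=A3, A4=A4, D=D, phi1=phi1, phi2=phi2)


def eval_pulse_complex(sol: PulseSolutionComplex, z) -> np.ndarray:
    """Activity u(z) of the complex-eigenvalue pulse.

    Inside the pulse the profile is alpha/(alpha+beta) plus a damped
    sinusoid pinned to 0 at the leading edge; behind the trailing edge the
    wake oscillates with decay exp(f*z), producing the depression and the
    positive reverberation lobe.
    """
    p, sh = sol.params, sol.shape
    if classify_eigenvalues(p).regime is not Regime.COMPLEX:
        raise RegimeMismatchError("params are in the REAL regime; use eval_pulse_real")
    a, b, w = p.alpha, p.beta, sh.w
    r, f, th = sol.r, sol.f, sol.r / (2.0 * sh.c)
    amp = a / (r * (a + b)) * math.hypot(sol.A1, sol.A2)
    z = np.asarray(z, dtype=float)
    u = np.zeros_like(z)
    mid = (z > 0) & (z < w)
    left = z <= 0
    u[mid] = a / (a + b) + amp * np.exp(f * (z[mid] - w)) * np.sin(th * z[mid] + sol.phi1)
    u[left] = amp * sol.D * np.exp(f * z[left]) * np.sin(th * z[left] + sol.phi2)
    return u


def make_pulse(params: RateParams, shape: WaveShape):
    """Construct the closed-form pulse solution for the parameters' regime."""
    regime = classify_eigenvalues(params).regime
    if regime is Regime.REAL:
        lp, lm = _real_rates(params, shape)
        return PulseSolutionReal(params=params, shape=shape, lambda_plus=lp, lambda_minus=lm)
    co = _complex_coefficients(params, shape)
    co.pop("th")
    return PulseSolutionComplex(params=params, shape=shape, **co)


# ---------------------------------------------------------------------------
# reverberation period and its inversion
# ---------------------------------------------------------------------------


def damped_period(params: RateParams) -> float:
    """Temporal period (ms) of the damped oscillatory wake: 4*pi/r.

    Only defined in the COMPLEX regime; diverges at the regime boundary.
    """
    regime = classify_eigenvalues(params)
    if regime.regime is not Regime.COMPLEX:
        raise RegimeMismatchError(
            "damped period is defined only in the COMPLEX regime "
            f"(discriminant {regime.discriminant:.3e} 1/ms^2)"
        )
    return 4.0 * math.pi / math.sqrt(regime.discriminant)


@dataclass(frozen=True)
class ReverberationFit:
    """Adaptation strength inferred from an observed reverberation time."""

    tau: float  # ms
    beta_empirical: float  # 1/ms
    beta0_empirical: float  # dimensionless


def beta_from_reverberation(tau: float, alpha: float, delta: float) -> ReverberationFit:
    """Invert the damped period for the adaptation rate.

    beta_empirical = (delta-alpha)^2/(4*delta) + 4*pi^2/(tau^2*delta); by
    construction the discriminant becomes 16*pi^2/tau^2 > 0, so the fitted
    parameters are strictly in the COMPLEX regime and
    ``damped_period == tau`` exactly.

    Parameters are in internal units: tau in ms, alpha and delta in 1/ms.
    """
    if not (tau > 0):
        raise ValueError(f"reverberation time tau must be > 0 ms, got {tau}")
    if not (alpha > 0 and delta > 0):
        raise ValueError("alpha and delta must be positive rates in 1/ms")
    beta = (delta - alpha) ** 2 / (4.0 * delta) + 4.0 * math.pi**2 / (tau**2 * delta)
    return ReverberationFit(tau=tau, beta_empirical=beta, beta0_empirical=beta / alpha)


def beta0_large_alpha_limit(delta_ratio: float) -> float:
    """Large-alpha limit of beta0 at fixed ratio delta = alpha/ratio.

    beta0 = beta_empirical/alpha -> (ratio-1)^2/(4*ratio); for the ratio 10
    used throughout the analysis this is 81/40 = 2.025.
    """
    if not (delta_ratio > 0):
        raise ValueError(f"delta_ratio must be > 0, got {delta_ratio}")
    return (delta_ratio - 1.0) ** 2 / (4.0 * delta_ratio)
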