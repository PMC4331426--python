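"""Shared fixtures and independent oracles for the test suite."""
from __future__ import annotations

import numpy as np
import pytest
from scipy.integrate import quad, solve_ivp

import termwave as tw


# ---------------------------------------------------------------------------
# canonical parameter sets
# ---------------------------------------------------------------------------


@pytest.fixture(scope="session")
def real_params() -> tw.RateParams:
    """Monotone-wake regime (alpha=20/s, delta=2/s, beta0=1.5, sigma=200 um)."""
    return tw.RateParams.from_per_second(20, 2, 1.5, 200)


@pytest.fixture(scope="session")
def real_shape() -> tw.WaveShape:
    return tw.WaveShape(c=180.0, w=3500.0)


@pytest.fixture(scope="session")
def complex_params() -> tw.RateParams:
    """Oscillatory-wake regime (alpha=20/s, delta=2/s, beta0=4.6, sigma=160 um)."""
    return tw.RateParams.from_per_second(20, 2, 4.6, 160)


@pytest.fixture(scope="session")
def complex_shape() -> tw.WaveShape:
    return tw.WaveShape(c=250.0, w=3000.0)


@pytest.fixture(scope="session")
def two_branch_config():
    """A threshold at which the model genuinely supports two coexisting waves.

    At alpha=20/s, delta=2/s, beta0=1.5, sigma=200 um and k=0.25 the
    matching conditions intersect twice; the branch shapes here were
    solved by the package and verified against direct simulation (the
    emergent wave from rest lands on the fast-wide branch within 2%).
    """
    params = tw.RateParams.from_per_second(20, 2, 1.5, 200, k=0.25)
    slow = tw.WaveShape(c=1.294, w=365.1)
    fast = tw.WaveShape(c=3.356, w=1460.0)
    return params, slow, fast


def random_regime_params(rng: np.random.Generator, regime: str) -> tw.RateParams:
    """Draw valid parameters in a prescribed eigenvalue regime."""
    while True:
        alpha = rng.uniform(5, 60) / 1000.0
        ratio = rng.uniform(5, 20)
        delta = alpha / ratio
        crit_beta0 = (alpha - delta) ** 2 / (4.0 * delta * alpha)
        if regime == "real":
            beta0 = rng.uniform(0.2, 0.95) * crit_beta0
        else:
            beta0 = rng.uniform(1.1, 4.0) * crit_beta0
        sigma = rng.uniform(40, 400)
        p = tw.RateParams(alpha=alpha, delta=delta, beta0=beta0, sigma=sigma)
        try:
            got = tw.classify_eigenvalues(p).regime
        except tw.CriticalDampingError:
            continue
        if got.value == regime:
            return p


def random_shape(rng: np.random.Generator) -> tw.WaveShape:
    return tw.WaveShape(c=rng.uniform(1.0, 300.0), w=rng.uniform(100.0, 5000.0))


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------


def shooting_oracle(params: tw.RateParams, shape: tw.WaveShape, z_targets):
    """Pulse profile by high-order backward integration of the frame ODEs.

    Integrates the piecewise-linear traveling-frame system from the
    leading-edge condition (u, q) = (0, 0) at z = w, with the firing term
    fixed to 1 on (0, w) and 0 behind; independent of the closed forms.
    """
    al, be, de, c, w = params.alpha, params.beta, params.delta, shape.c, shape.w

    def rhs(z, y, H):
        u, q = y
        return [(al * u - al * H + be * q) / c, (de * q - de * u) / c]

    out = {}
    sol = solve_ivp(rhs, [w, 0.0], [0.0, 0.0], args=(1.0,), rtol=1e-12, atol=1e-14,
                    dense_output=True, method="DOP853")
    for z in z_targets:
        if 0 < z < w:
            out[z] = float(sol.sol(z)[0])
    lefts = [z for z in z_targets if z <= 0]
    if lefts:
        sol2 = solve_ivp(rhs, [0.0, min(lefts)], sol.y[:, -1], args=(0.0,),
                         rtol=1e-12, atol=1e-14, dense_output=True, method="DOP853")
        for z in lefts:
            out[z] = float(sol2.sol(z)[0])
    for z in z_targets:
        if z >= shape.w:
            out[z] = 0.0
    return out


def quadrature_threshold(params: tw.RateParams, shape: tw.WaveShape, x: float) -> float:
    """(1/(2*sigma)) Int exp(-|x-y|/sigma) u(y) dy by adaptive quadrature."""
    sig = params.sigma
    w = shape.w

    def u(y):
        return tw.eval_pulse_uq(params, shape, np.array([y]))[0][0]

    decay = 2.0 * shape.c / (params.alpha + params.delta)
    lo = -40.0 * max(sig, decay, w)
    # geometric subdivision so the adaptive rule cannot step over features
    # much narrower than the full interval (profile scales ~ c/alpha, sigma)
    scale = min(sig, decay, w)
    pts = {lo, 0.0, w, min(max(x, lo), w)}
    m = scale
    while m < -lo:
        pts.add(-m)
        m *= 2.5
    m = min(scale, w)
    while m < w:
        pts.add(m)
        m *= 2.5
    pts = sorted(pts)
    total = 0.0
    for a, b in zip(pts[:-1], pts[1:]):
        if b <= a:
            continue
        val, _ = quad(lambda y: np.exp(-abs(x - y) / sig) * u(y), a, b, limit=400,
                      epsabs=1e-14, epsrel=1e-11)
        total += val
    return total / (2.0 * sig)
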