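"""1-D field simulation of the excitatory and excitatory-inhibitory models.

The models are integrated on a regular grid with classical fourth-order
Runge-Kutta (default dt = 0.005 ms, dx = 40 um, 2000 nodes).  The
exponential-kernel convolution is evaluated with piecewise-constant
activity per cell: node i receives the exact cell integral of
exp(-|x|/sigma)/(2*sigma) from each cell, which factorizes into two O(n)
recursive exponential passes (used in the fused integrator) or an FFT
product (the public array operation); both agree with the direct O(n^2)
summation to 1e-12.

The excitatory-inhibitory system is

    u_t = -alpha_e*u + alpha_e*H(g_ee*u - g_ie*v + P - k_e) - alpha_e*beta0*q
    q_t = delta*u - delta*q
    v_t = -alpha_i*v + alpha_i*H(g_ei*u - g_ii*v + Q - k_i)

with g_jk*x denoting the kernel convolution with extent sigma_jk scaled by
the binary coupling gbar_jk.  The single-population model is the special
case with all cross-couplings off, so both models share one integration
path and the reduction is exact.  A model variant moves the adaptation
term inside the firing nonlinearity (as -beta0*q in the Heaviside
argument), which abolishes the damped-oscillatory wake.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from numba import njit
from scipy import signal

from .params import RateParams, WaveShape
from .pulse import eval_pulse_uq, make_pulse
from .matching import matching_thresholds

__all__ = [
    "Grid",
    "StimulusSpec",
    "EIParams",
    "FieldState",
    "SimWaveFeatures",
    "SimulationResult",
    "SimulationDivergenceError",
    "exp_kernel_convolve",
    "exp_kernel_convolve_direct",
    "rhs_model1",
    "rhs_model2",
    "rk4_step",
    "run_simulation",
    "measure_sim_features",
    "probe_stability",
]


class SimulationDivergenceError(RuntimeError):
    pass


@dataclass(frozen=True)
class Grid:
    """Spatial/temporal discretization (defaults follow the study protocol)."""

    n_points: int = 2000
    dx: float = 40.0  # um
    dt: float = 0.005  # ms
    duration: float = 200.0  # ms

    def __post_init__(self) -> None:
        if self.n_points < 16:
            raise ValueError("n_points must be >= 16")
        if self.dx <= 0 or self.dt <= 0 or self.duration <= 0:
            raise ValueError("dx, dt and duration must be positive")

    @property
    def x(self) -> np.ndarray:
        return np.arange(self.n_points) * self.dx

    @property
    def length(self) -> float:
        return self.n_points * self.dx


@dataclass(frozen=True)
class StimulusSpec:
    """External input added inside the Heaviside argument.

    The input is a boxcar in space and time; ``amplitude`` must exceed the
    firing threshold to ignite activity.  Note that with a Heaviside
    nonlinearity the growth rate during stimulation is alpha regardless of
    amplitude, so igniting a wave requires duration > -ln(1-k)/alpha; the
    wave-initiation preset therefore uses a longer input than the 5 ms
    default duration of the field contract.
    """

    onset: float = 0.0  # ms
    duration: float = 5.0  # ms
    extent: float = 40.0  # um
    amplitude: float = 1.0
    position: float = 0.0  # um, left edge of the stimulated region
    target: str = "excitatory"  # or "inhibitory"

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("stimulus duration must be > 0 ms")
        if self.target not in ("excitatory", "inhibitory"):
            raise ValueError("target must be 'excitatory' or 'inhibitory'")

    @classmethod
    def ignition(cls, k: float, alpha: float, extent: float = 400.0) -> "StimulusSpec":
        """Preset long enough to lift u above threshold k at rate alpha."""
        t_min = -math.log(max(1e-9, 1.0 - 1.8 * k)) / alpha
        return cls(duration=max(5.0, t_min), extent=extent, amplitude=max(1.0, 2.0 * k))


@dataclass(frozen=True)
class EIParams:
    """Rates, thresholds and couplings of the excitatory-inhibitory model."""

    alpha_e: float  # 1/ms
    alpha_i: float  # 1/ms
    delta: float  # 1/ms
    beta0: float
    k_e: float
    k_i: float
    sigma_ee: float  # um
    sigma_ei: float = 20.0
    sigma_ie: float = 20.0
    sigma_ii: float = 0.0
    gbar_ee: int = 1
    gbar_ei: int = 0
    gbar_ie: int = 0
    gbar_ii: int = 0

    def __post_init__(self) -> None:
        if min(self.alpha_e, self.alpha_i, self.delta) <= 0:
            raise ValueError("rates must be positive (1/ms)")
        for g in (self.gbar_ee, self.gbar_ei, self.gbar_ie, self.gbar_ii):
            if g not in (0, 1):
                raise ValueError("gbar couplings must be binary")
        if min(self.sigma_ee, self.sigma_ei, self.sigma_ie, self.sigma_ii) < 0:
            raise ValueError("sigma_jk must be >= 0 (0 means a delta kernel)")

    @classmethod
    def from_rate_params(cls, params: RateParams, *, alpha_i: float = 0.0025,
                         k_i: float = 1.0, **kw) -> "EIParams":
        if params.k is None:
            raise ValueError("params.k must be set")
        return cls(
            alpha_e=params.alpha, alpha_i=alpha_i, delta=params.delta,
            beta0=params.beta0, k_e=params.k, k_i=k_i, sigma_ee=params.sigma, **kw,
        )


@dataclass
class FieldState:
    """Per-node activity u, adaptation q and (optionally) inhibition v."""

    u: np.ndarray
    q: np.ndarray
    v: np.ndarray | None = None

    def copy(self) -> "FieldState":
        return FieldState(self.u.copy(), self.q.copy(),
                          None if self.v is None else self.v.copy())


@dataclass(frozen=True)
class SimWaveFeatures:
    """Wave features measured from a simulation."""

    speed: float | None  # um/ms
    width: float | None  # um
    reverberation_time: float | None  # ms
    front_flag: bool = False

    @property
    def is_wave(self) -> bool:
        return self.speed is not None


# ---------------------------------------------------------------------------
# exponential-kernel convolution
# ---------------------------------------------------------------------------


def _cell_weights(sigma: float, dx: float, n: int) -> np.ndarray:
    """Exact cell integrals of the kernel at node offsets -(n-1)..(n-1)."""
    d = np.abs(np.arange(-(n - 1), n)) * dx
    a = dx / (2.0 * sigma)
    return np.where(d == 0, 1.0 - np.exp(-a), np.exp(-d / sigma) * np.sinh(a))


def exp_kernel_convolve(u: np.ndarray, sigma: float, dx: float) -> np.ndarray:
    """Discrete (1/(2*sigma)) Int exp(-|x-y|/sigma) u(y) dy, zero-padded.

    The activity is treated as constant within each dx cell, so the weight
    of cell j at node i is the analytic cell integral of the kernel; the
    weights sum to 1 on an unbounded domain.  Evaluated via FFT in
    O(n log n); sigma = 0 degenerates to the identity (delta kernel).
    """
    u = np.asarray(u, dtype=float)
    if sigma == 0.0:
        return u.copy()
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    w = _cell_weights(sigma, dx, u.size)
    return signal.fftconvolve(u, w, mode="same")


def exp_kernel_convolve_direct(u: np.ndarray, sigma: float, dx: float) -> np.ndarray:
    """O(n^2) direct-summation reference for the convolution."""
    u = np.asarray(u, dtype=float)
    if sigma == 0.0:
        return u.copy()
    n = u.size
    w = _cell_weights(sigma, dx, n)
    out = np.zeros(n)
    for i in range(n):
        out[i] = float(np.dot(w[n - 1 - i : 2 * n - 1 - i], u))
    return out


@njit(cache=True)
def _expconv_recursive(x, sigma, dx, out):  # pragma: no cover - exercised via wrappers
    n = x.shape[0]
    if sigma <= 0.0:
        for i in range(n):
            out[i] = x[i]
        return
    a = dx / (2.0 * sigma)
    rho = math.exp(-dx / sigma)
    w0 = 1.0 - math.exp(-a)
    s = math.sinh(a)
    for i in range(n):
        out[i] = w0 * x[i]
    t = 0.0
    for i in range(1, n):
        t = rho * (t + x[i - 1])
        out[i] += s * t
    t = 0.0
    for i in range(n - 2, -1, -1):
        t = rho * (t + x[i + 1])
        out[i] += s * t


def exp_kernel_convolve_recursive(u: np.ndarray, sigma: float, dx: float) -> np.ndarray:
    """Two-pass O(n) recursive evaluation (the integrator's code path)."""
    u = np.asarray(u, dtype=float)
    out = np.empty_like(u)
    _expconv_recursive(u, float(sigma), float(dx), out)
    return out


# ---------------------------------------------------------------------------
# right-hand sides and a reference RK4 step (numpy, for composability/tests)
# ---------------------------------------------------------------------------


def rhs_model1(
    state: FieldState,
    params: RateParams,
    P: np.ndarray,
    dx: float,
    variant: str = "adaptation_outside",
) -> FieldState:
    """Time derivative of the single-population model.

    ``adaptation_outside`` (the study model): the -alpha*beta0*q term acts
    directly on u_t.  ``adaptation_inside``: the term moves into the
    Heaviside argument as -beta0*q.
    """
    if params.k is None:
        raise ValueError("params.k must be set")
    if np.any(~np.isfinite(state.u)) or np.any(~np.isfinite(state.q)):
        bad = int(np.flatnonzero(~np.isfinite(state.u) | ~np.isfinite(state.q))[0])
        raise SimulationDivergenceError(f"non-finite state at node {bad}")
    a, be, de, k = params.alpha, params.beta, params.delta, params.k
    drive = exp_kernel_convolve(state.u, params.sigma, dx) + P - k
    if variant == "adaptation_inside":
        H = (drive - params.beta0 * state.q >= 0).astype(float)
        du = -a * state.u + a * H
    elif variant == "adaptation_outside":
        H = (drive >= 0).astype(float)
        du = -a * state.u + a * H - be * state.q
    else:
        raise ValueError(f"unknown variant {variant!r}")
    dq = de * state.u - de * state.q
    return FieldState(u=du, q=dq)


def rhs_model2(
    state: FieldState,
    ei: EIParams,
    P: np.ndarray,
    Q: np.ndarray,
    dx: float,
    variant: str = "adaptation_outside",
) -> FieldState:
    """Time derivative of the excitatory-inhibitory model."""
    if state.v is None:
        raise ValueError("model 2 requires an inhibitory field v")
    if (np.any(~np.isfinite(state.u)) or np.any(~np.isfinite(state.q))
            or np.any(~np.isfinite(state.v))):
        bad = int(np.flatnonzero(
            ~np.isfinite(state.u) | ~np.isfinite(state.q) | ~np.isfinite(state.v))[0])
        raise SimulationDivergenceError(f"non-finite state at node {bad}")
    be = ei.alpha_e * ei.beta0
    drive_e = P - ei.k_e
    if ei.gbar_ee:
        drive_e = drive_e + exp_kernel_convolve(state.u, ei.sigma_ee, dx)
    if ei.gbar_ie:
        drive_e = drive_e - exp_kernel_convolve(state.v, ei.sigma_ie, dx)
    drive_i = Q - ei.k_i
    if ei.gbar_ei:
        drive_i = drive_i + exp_kernel_convolve(state.u, ei.sigma_ei, dx)
    if ei.gbar_ii:
        drive_i = drive_i - exp_kernel_convolve(state.v, ei.sigma_ii, dx)
    if variant == "adaptation_inside":
        He = (drive_e - ei.beta0 * state.q >= 0).astype(float)
        du = -ei.alpha_e * state.u + ei.alpha_e * He
    else:
        He = (drive_e >= 0).astype(float)
        du = -ei.alpha_e * state.u + ei.alpha_e * He - be * state.q
    dq = ei.delta * state.u - ei.delta * state.q
    Hi = (drive_i >= 0).astype(float)
    dv = -ei.alpha_i * state.v + ei.alpha_i * Hi
    return FieldState(u=du, q=dq, v=dv)


def rk4_step(state: FieldState, rhs, dt: float) -> FieldState:
    """One classical RK4 update; ``rhs`` maps FieldState -> FieldState."""
    if dt <= 0:
        raise ValueError("dt must be > 0")

    def axpy(s: FieldState, d: FieldState, h: float) -> FieldState:
        return FieldState(
            u=s.u + h * d.u,
            q=s.q + h * d.q,
            v=None if s.v is None else s.v + h * d.v,
        )

    k1 = rhs(state)
    k2 = rhs(axpy(state, k1, dt / 2))
    k3 = rhs(axpy(state, k2, dt / 2))
    k4 = rhs(axpy(state, k3, dt))
    out = state.copy()
    out.u = state.u + dt / 6 * (k1.u + 2 * k2.u + 2 * k3.u + k4.u)
    out.q = state.q + dt / 6 * (k1.q + 2 * k2.q + 2 * k3.q + k4.q)
    if state.v is not None:
        out.v = state.v + dt / 6 * (k1.v + 2 * k2.v + 2 * k3.v + k4.v)
    return out


# ---------------------------------------------------------------------------
# fused integrator
# ---------------------------------------------------------------------------


@njit(cache=True)
def _ei_integrate(  # pragma: no cover - exercised via run_simulation
    u, q, v, n_steps, dt, dx,
    al_e, al_i, de, be, beta0, k_e, k_i,
    sig_ee, sig_ei, sig_ie, sig_ii,
    g_ee, g_ei, g_ie, g_ii,
    p_amp, p_i0, p_i1, p_t0, p_t1,
    q_amp, q_i0, q_i1, q_t0, q_t1,
    inside_variant, u_alarm,
    stride, U_out, Q_out, V_out, t_out, cross_time,
):
    n = u.shape[0]
    ce = np.empty(n)
    ci = np.empty(n)
    du1 = np.empty(n); dq1 = np.empty(n); dv1 = np.empty(n)
    du2 = np.empty(n); dq2 = np.empty(n); dv2 = np.empty(n)
    du3 = np.empty(n); dq3 = np.empty(n); dv3 = np.empty(n)
    du4 = np.empty(n); dq4 = np.empty(n); dv4 = np.empty(n)
    ut = np.empty(n); qt = np.empty(n); vt = np.empty(n)
    n_snap = 0
    status = 0
    bad_node = -1
    bad_time = 0.0
    for step in range(n_steps):
        t = step * dt
        p_on = (t >= p_t0) and (t < p_t1)
        q_on = (t >= q_t0) and (t < q_t1)

        for stage in range(4):
            if stage == 0:
                uu, qq, vv = u, q, v
                du, dq, dv = du1, dq1, dv1
            elif stage == 1:
                for i in range(n):
                    ut[i] = u[i] + 0.5 * dt * du1[i]
                    qt[i] = q[i] + 0.5 * dt * dq1[i]
                    vt[i] = v[i] + 0.5 * dt * dv1[i]
                uu, qq, vv = ut, qt, vt
                du, dq, dv = du2, dq2, dv2
            elif stage == 2:
                for i in range(n):
                    ut[i] = u[i] + 0.5 * dt * du2[i]
                    qt[i] = q[i] + 0.5 * dt * dq2[i]
                    vt[i] = v[i] + 0.5 * dt * dv2[i]
                uu, qq, vv = ut, qt, vt
                du, dq, dv = du3, dq3, dv3
            else:
                for i in range(n):
                    ut[i] = u[i] + dt * du3[i]
                    qt[i] = q[i] + dt * dq3[i]
                    vt[i] = v[i] + dt * dv3[i]
                uu, qq, vv = ut, qt, vt
                du, dq, dv = du4, dq4, dv4

            # excitatory drive
            if g_ee == 1:
                _expconv_recursive(uu, sig_ee, dx, ce)
            else:
                for i in range(n):
                    ce[i] = 0.0
            if g_ie == 1:
                _expconv_recursive(vv, sig_ie, dx, ci)
                for i in range(n):
                    ce[i] -= ci[i]
            if p_on:
                for i in range(p_i0, p_i1):
                    ce[i] += p_amp
            for i in range(n):
                d_e = ce[i] - k_e
                if inside_variant == 1:
                    h = 1.0 if d_e - beta0 * qq[i] >= 0.0 else 0.0
                    du[i] = -al_e * uu[i] + al_e * h
                else:
                    h = 1.0 if d_e >= 0.0 else 0.0
                    du[i] = -al_e * uu[i] + al_e * h - be * qq[i]
                dq[i] = de * uu[i] - de * qq[i]
            if stage == 0:
                for i in range(n):
                    if cross_time[i] < 0.0 and ce[i] - k_e >= 0.0:
                        cross_time[i] = t
            # inhibitory drive
            if g_ei == 1:
                _expconv_recursive(uu, sig_ei, dx, ci)
            else:
                for i in range(n):
                    ci[i] = 0.0
            if g_ii == 1:
                _expconv_recursive(vv, sig_ii, dx, ce)
                for i in range(n):
                    ci[i] -= ce[i]
            if q_on:
                for i in range(q_i0, q_i1):
                    ci[i] += q_amp
            for i in range(n):
                h = 1.0 if ci[i] - k_i >= 0.0 else 0.0
                dv[i] = -al_i * vv[i] + al_i * h

        for i in range(n):
            u[i] += dt / 6.0 * (du1[i] + 2.0 * du2[i] + 2.0 * du3[i] + du4[i])
            q[i] += dt / 6.0 * (dq1[i] + 2.0 * dq2[i] + 2.0 * dq3[i] + dq4[i])
            v[i] += dt / 6.0 * (dv1[i] + 2.0 * dv2[i] + 2.0 * dv3[i] + dv4[i])

        if (step + 1) % stride == 0:
            for i in range(n):
                U_out[n_snap, i] = u[i]
                Q_out[n_snap, i] = q[i]
                V_out[n_snap, i] = v[i]
                if not math.isfinite(u[i]) or abs(u[i]) > u_alarm:
                    status = 1
                    bad_node = i
                    bad_time = (step + 1) * dt
            t_out[n_snap] = (step + 1) * dt
            n_snap += 1
            if status != 0:
                return n_snap, status, bad_node, bad_time
    return n_snap, status, bad_node, bad_time


@dataclass
class SimulationResult:
    """Thinned space-time output of a simulation."""

    grid: Grid
    t: np.ndarray  # snapshot times, ms
    x: np.ndarray  # node positions, um
    u: np.ndarray  # (n_snap, n) activity
    q: np.ndarray
    v: np.ndarray | None
    cross_time: np.ndarray  # first time the excitatory drive was suprathreshold
    params: RateParams | None
    ei_params: EIParams | None
    variant: str
    warnings: list = field(default_factory=list)

    @property
    def k_e(self) -> float:
        return self.params.k if self.params is not None else self.ei_params.k_e

    @property
    def sigma_ee(self) -> float:
        return self.params.sigma if self.params is not None else self.ei_params.sigma_ee


def run_simulation(
    params: RateParams | EIParams,
    grid: Grid,
    stimulus: StimulusSpec | list[StimulusSpec] | None = None,
    *,
    variant: str = "adaptation_outside",
    initial_state: FieldState | None = None,
    output_stride_ms: float = 1.0,
    u_alarm: float = 2.0,
) -> SimulationResult:
    """Integrate a model from rest (or a given state) and record snapshots.

    Deterministic given its inputs.  Raises a divergence alarm naming the
    first offending node if the activity leaves [-u_alarm, u_alarm] or
    becomes non-finite, and records a domain-exit warning if suprathreshold
    drive reaches the far boundary.
    """
    if isinstance(params, RateParams):
        if params.k is None:
            raise ValueError("params.k must be set for a simulation")
        ei = EIParams.from_rate_params(params)
        rp: RateParams | None = params
    else:
        ei = params
        rp = None
    if variant not in ("adaptation_outside", "adaptation_inside"):
        raise ValueError(f"unknown variant {variant!r}")

    n = grid.n_points
    if initial_state is None:
        state = FieldState(u=np.zeros(n), q=np.zeros(n), v=np.zeros(n))
    else:
        state = initial_state.copy()
        if state.v is None:
            state.v = np.zeros(n)

    stims = [] if stimulus is None else ([stimulus] if isinstance(stimulus, StimulusSpec) else list(stimulus))
    pe = [s for s in stims if s.target == "excitatory"]
    pi = [s for s in stims if s.target == "inhibitory"]
    if len(pe) > 1 or len(pi) > 1:
        raise ValueError("at most one stimulus per population")

    def _box(s: StimulusSpec | None):
        if s is None:
            return 0.0, 0, 0, -1.0, -1.0
        i0 = int(round(s.position / grid.dx))
        i1 = max(i0 + 1, i0 + int(round(s.extent / grid.dx)))
        return s.amplitude, max(0, i0), min(n, i1), s.onset, s.onset + s.duration

    p_amp, p_i0, p_i1, p_t0, p_t1 = _box(pe[0] if pe else None)
    q_amp, q_i0, q_i1, q_t0, q_t1 = _box(pi[0] if pi else None)

    n_steps = int(round(grid.duration / grid.dt))
    stride = max(1, int(round(output_stride_ms / grid.dt)))
    n_snap_max = n_steps // stride
    U = np.empty((n_snap_max, n))
    Q = np.empty((n_snap_max, n))
    V = np.empty((n_snap_max, n))
    t_out = np.empty(n_snap_max)
    cross = np.full(n, -1.0)

    n_snap, status, bad_node, bad_time = _ei_integrate(
        state.u, state.q, state.v, n_steps, grid.dt, grid.dx,
        ei.alpha_e, ei.alpha_i, ei.delta, ei.alpha_e * ei.beta0, ei.beta0,
        ei.k_e, ei.k_i,
        ei.sigma_ee, ei.sigma_ei, ei.sigma_ie, ei.sigma_ii,
        ei.gbar_ee, ei.gbar_ei, ei.gbar_ie, ei.gbar_ii,
        p_amp, p_i0, p_i1, p_t0, p_t1,
        q_amp, q_i0, q_i1, q_t0, q_t1,
        1 if variant == "adaptation_inside" else 0, u_alarm,
        stride, U, Q, V, t_out, cross,
    )
    if status != 0:
        raise SimulationDivergenceError(
            f"activity diverged at node {bad_node} (x={bad_node * grid.dx:.0f} um) "
            f"around t={bad_time:.3f} ms"
        )
    cross = np.where(cross < 0, np.nan, cross)
    has_v = bool(ei.gbar_ei or ei.gbar_ie or q_amp > 0)
    result = SimulationResult(
        grid=grid, t=t_out[:n_snap], x=grid.x,
        u=U[:n_snap], q=Q[:n_snap], v=V[:n_snap] if has_v else None,
        cross_time=cross, params=rp, ei_params=ei if rp is None else None,
        variant=variant,
    )
    if np.any(np.isfinite(cross[-3:])):
        result.warnings.append("domain-exit: suprathreshold drive reached the far boundary")
        warnings.warn(result.warnings[-1], RuntimeWarning, stacklevel=2)
    return result


# ---------------------------------------------------------------------------
# feature measurement and stability probing
# ---------------------------------------------------------------------------


def _drive(result: SimulationResult, i_snap: int) -> np.ndarray:
    """Heaviside argument (synaptic input minus threshold) at a snapshot."""
    if result.params is not None:
        d = exp_kernel_convolve(result.u[i_snap], result.params.sigma, result.grid.dx)
        return d - result.params.k
    ei = result.ei_params
    d = np.zeros(result.grid.n_points)
    if ei.gbar_ee:
        d += exp_kernel_convolve(result.u[i_snap], ei.sigma_ee, result.grid.dx)
    if ei.gbar_ie and result.v is not None:
        d -= exp_kernel_convolve(result.v[i_snap], ei.sigma_ie, result.grid.dx)
    return d - ei.k_e


def _support_run(mask: np.ndarray) -> tuple[int, int] | None:
    """Longest contiguous True run as (start, stop) indices, or None."""
    if not mask.any():
        return None
    idx = np.flatnonzero(mask)
    breaks = np.where(np.diff(idx) > 1)[0]
    starts = np.r_[idx[0], idx[breaks + 1]]
    stops = np.r_[idx[breaks] + 1, idx[-1] + 1]
    j = int(np.argmax(stops - starts))
    return int(starts[j]), int(stops[j])


def measure_sim_features(
    result: SimulationResult,
    *,
    rev_frac: float = 0.1,
    rev_horizon: float = 500.0,
) -> SimWaveFeatures:
    """Measure speed, width and reverberation time of a simulated wave.

    Speed: least-squares slope of the per-node first crossing times of the
    suprathreshold drive against position, restricted to the middle half of
    the domain.  Width: length of the contiguous suprathreshold-drive
    interval at the snapshot whose support midpoint is nearest the domain
    center.  Reverberation time: at the center node, time between the
    activity's first drop below ``rev_frac`` of its peak and the subsequent
    recession of the next suprathreshold excursion below that level (the
    field analog of the LFP z-score rule).  A front (no trailing closure of
    the active region) is flagged instead of assigned a width.
    """
    grid = result.grid
    n = grid.n_points
    ct = result.cross_time
    lo, hi = n // 4, 3 * n // 4
    seg = np.arange(lo, hi)
    ok = np.isfinite(ct[seg])
    if ok.sum() < max(8, (hi - lo) // 10):
        return SimWaveFeatures(speed=None, width=None, reverberation_time=None)
    xs = seg[ok] * grid.dx
    ts = ct[seg][ok]
    slope = np.polyfit(xs, ts, 1)[0]  # ms per um
    speed = 1.0 / slope if slope > 0 else None
    if speed is None:
        return SimWaveFeatures(speed=None, width=None, reverberation_time=None)

    # width at mid-domain passage
    best = None
    for i in range(len(result.t)):
        run = _support_run(_drive(result, i) > 0)
        if run is None:
            continue
        mid = 0.5 * (run[0] + run[1]) * grid.dx
        score = abs(mid - 0.5 * grid.length)
        if best is None or score < best[0]:
            best = (score, i, run)
    if best is None:
        return SimWaveFeatures(speed=None, width=None, reverberation_time=None)
    _, i_mid, run = best
    width = (run[1] - run[0]) * grid.dx
    # front discrimination: behind the active region the pulse returns to
    # rest; a front keeps u high all the way back
    behind = result.u[i_mid][max(0, run[0] - 10):run[0]] if run[0] > 2 else np.array([])
    front_flag = bool(run[0] <= 2 or (behind.size and behind.min() > 0.5 * result.u[i_mid].max()))
    if front_flag:
        return SimWaveFeatures(speed=speed, width=None, reverberation_time=None, front_flag=True)

    # reverberation at the center node
    uc = result.u[:, n // 2]
    peak = float(uc.max())
    tau = None
    if peak > 0:
        thr = rev_frac * peak
        above = uc > thr
        i_peak = int(np.argmax(uc))
        after = np.flatnonzero(~above[i_peak:])
        if after.size:
            i_end = i_peak + int(after[0])
            t_end = result.t[i_end]
            rise = np.flatnonzero(above[i_end:])
            if rise.size:
                i_rise = i_end + int(rise[0])
                fall = np.flatnonzero(~above[i_rise:])
                if fall.size and result.t[i_rise + int(fall[0])] - t_end <= rev_horizon:
                    tau = float(result.t[i_rise + int(fall[0])] - t_end)
    return SimWaveFeatures(speed=speed, width=width, reverberation_time=tau)


def probe_stability(
    params: RateParams,
    shape: WaveShape,
    *,
    perturbation: float = 0.01,
    n_transits: float = 3.0,
    min_duration: float = 150.0,
    dx: float = 40.0,
    dt: float = 0.005,
    tol: float = 0.10,
) -> str:
    """Numerically probe linear stability of an analytic pulse branch.

    The simulator is initialized with the closed-form (u, q) pulse plus a
    smooth perturbation of the given relative amplitude and integrated for
    three transit times (at least ``min_duration`` ms).  Returns
    ``"persists"`` when measured speed and width stay within ``tol`` of the
    analytic ones, ``"collapses"`` when the activity dies or the wave
    leaves the branch, and ``"indeterminate"`` otherwise.
    """
    th = matching_thresholds(params, shape)
    k = 0.5 * (th.k_at_0 + th.k_at_w)
    p = params.with_k(k)
    duration = max(min_duration, n_transits * shape.transit_time)
    # domain: wake tail + pulse + travel room
    lam_min = (params.alpha + params.delta) / (2.0 * shape.c)  # slowest decay, 1/um
    tail = 8.0 / lam_min
    travel = shape.c * duration
    length = tail + shape.w + travel + 40 * dx
    n = int(np.ceil(length / dx))
    grid = Grid(n_points=n, dx=dx, dt=dt, duration=duration)
    # pulse coordinate: trailing edge at x = tail, leading edge at x = tail + w
    u, q = eval_pulse_uq(p, shape, grid.x - tail)
    bump = perturbation * np.abs(u).max() * np.exp(
        -((grid.x - (tail + 0.5 * shape.w)) ** 2) / (2.0 * (0.5 * shape.w) ** 2)
    )
    state = FieldState(u=u + bump, q=q)
    result = run_simulation(p, grid, initial_state=state, output_stride_ms=max(1.0, duration / 400))
    # follow the active region over time
    runs = [(t_i, _support_run(_drive(result, i) > 0)) for i, t_i in enumerate(result.t)]
    alive = [(t_i, r) for t_i, r in runs if r is not None]
    if not alive or alive[-1][0] < result.t[-1] - 1e-9:
        return "collapses"
    widths = np.array([(r[1] - r[0]) * dx for _, r in alive])
    fronts = np.array([r[1] * dx for _, r in alive])
    times = np.array([t for t, _ in alive])
    half = len(times) // 2
    if len(times) < 6:
        return "indeterminate"
    speed = np.polyfit(times[half:], fronts[half:], 1)[0]
    width_end = widths[-5:].mean()
    ok_speed = abs(speed - shape.c) / shape.c <= tol
    ok_width = abs(width_end - shape.w) / shape.w <= tol
    if ok_speed and ok_width:
        return "persists"
    if (abs(speed - shape.c) / shape.c > 0.5) or (abs(width_end - shape.w) / shape.w > 0.5):
        return "collapses"
    return "indeterminate"
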