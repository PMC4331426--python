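"""Matching conditions of the traveling pulse and their inverse problems.

A pulse of speed c and width w exists only if the synaptic input

    (w * u)(x) = (1/(2*sigma)) Int exp(-|x-y|/sigma) u(y) dy

equals the threshold k at both edges of the suprathreshold interval,
x = 0 (trailing) and x = w (leading), and exceeds k in between.  Because
the pulse profile is a piecewise sum of (complex) exponentials, both
threshold values have exact closed forms; they are evaluated here by exact
term-by-term integration of the profile against the exponential kernel,
arranged so that every exponential that appears is decaying (no
catastrophic cancellation near the regime boundary).

Fixing (alpha, delta, sigma, beta, k) and intersecting the two level
curves k_at_0(c, w) = k and k_at_w(c, w) = k in the (c, w) plane gives the
existence diagram: zero, one, or two waves, and when two coexist one is
slow and narrow and the other fast and wide.  Fixing (c, w, alpha, delta)
instead and solving k_at_0 = k_at_w along a sigma grid traces the
(sigma, beta) solution curve.  Feeding per-wave feature tables
(speed, width, reverberation time) through the reverberation inversion and
the sigma solve yields the feasibility sweep over the timescale alpha.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

from .params import (
    EigenRegime,
    RateParams,
    Regime,
    RegimeMismatchError,
    WaveShape,
    classify_eigenvalues,
)
from .pulse import beta_from_reverberation, profile_terms

logger = logging.getLogger(__name__)

__all__ = [
    "MatchingThresholds",
    "ExistenceDiagram",
    "SigmaBetaCurve",
    "FeasibilitySweep",
    "AnchorInconsistencyError",
    "matching_thresholds",
    "matching_thresholds_real",
    "matching_thresholds_complex",
    "solve_cw_intersections",
    "anchor_and_find_second_wave",
    "solve_sigma_beta_curve",
    "feasibility_sweep",
]


class AnchorInconsistencyError(ValueError):
    """The anchor point does not lie on the existence curve."""

    def __init__(self, k_at_0: float, k_at_w: float, rel: float, tol: float):
        self.k_at_0 = k_at_0
        self.k_at_w = k_at_w
        super().__init__(
            f"anchor thresholds disagree by {100 * rel:.1f}% (> {100 * tol:.0f}%): "
            f"k_at_0={k_at_0:.6g}, k_at_w={k_at_w:.6g}; the anchor is not on "
            "the existence curve"
        )


@dataclass(frozen=True)
class MatchingThresholds:
    """Synaptic input at the two threshold crossings of a candidate pulse.

    ``k_at_0`` is the value at the trailing edge, ``k_at_w`` at the leading
    edge.  For a self-consistent traveling wave the two coincide.
    """

    k_at_0: float
    k_at_w: float
    regime: EigenRegime

    @property
    def mismatch(self) -> float:
        """|k_at_0 - k_at_w| / max(|k_at_0|, |k_at_w|)."""
        scale = max(abs(self.k_at_0), abs(self.k_at_w))
        return abs(self.k_at_0 - self.k_at_w) / scale if scale > 0 else 0.0


def matching_thresholds(params: RateParams, shape: WaveShape) -> MatchingThresholds:
    """Exact threshold values at both edges, either regime.

    Each integral is assembled per profile piece: the wake contributes
    Re(C/(mu + 1/sigma)) terms, the interior contributes the plateau term
    (1 - exp(-w/sigma))/2 * alpha/(alpha+beta) plus damped-exponential
    corrections; all exponents that appear are negative.
    """
    regime = classify_eigenvalues(params)
    sig = params.sigma
    w = shape.w
    mc, mt, lt = profile_terms(params, shape)

    # integral_{-inf}^0 exp(y/sig) * u_left(y) dy
    tail = 0.0
    for Cu, _Cq, mu in lt:
        tail += (Cu / (mu + 1.0 / sig)).real

    # k at x = 0: (1/2sig)[tail + int_0^w exp(-y/sig) u_mid(y) dy]
    I = mc * sig * (1.0 - math.exp(-w / sig))
    for Cu, _Cq, mu in mt:
        s = mu - 1.0 / sig
        if abs(s) * w < 1e-9:
            I += (Cu * np.exp(-mu * w) * w).real
        else:
            I += (Cu * (np.exp(-w / sig) - np.exp(-mu * w)) / s).real
    k_at_0 = (tail + I) / (2.0 * sig)

    # k at x = w: (1/2sig)[exp(-w/sig)*tail + int_0^w exp((y-w)/sig) u_mid dy]
    J = mc * sig * (1.0 - math.exp(-w / sig))
    for Cu, _Cq, mu in mt:
        s = mu + 1.0 / sig
        J += (Cu * (1.0 - np.exp(-s * w)) / s).real
    k_at_w = (math.exp(-w / sig) * tail + J) / (2.0 * sig)

    return MatchingThresholds(k_at_0=float(k_at_0), k_at_w=float(k_at_w), regime=regime)


def matching_thresholds_real(params: RateParams, shape: WaveShape) -> MatchingThresholds:
    """Threshold pair for the real-eigenvalue (monotone-wake) pulse."""
    if classify_eigenvalues(params).regime is not Regime.REAL:
        raise RegimeMismatchError("params are in the COMPLEX regime")
    return matching_thresholds(params, shape)


def matching_thresholds_complex(params: RateParams, shape: WaveShape) -> MatchingThresholds:
    """Threshold pair for the complex-eigenvalue (oscillatory-wake) pulse."""
    if classify_eigenvalues(params).regime is not Regime.COMPLEX:
        raise RegimeMismatchError("params are in the REAL regime")
    return matching_thresholds(params, shape)


# ---------------------------------------------------------------------------
# existence diagram: intersections of the two level curves at fixed k
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ExistenceDiagram:
    """Intersections of the matching-condition curves at a fixed threshold."""

    params: RateParams  # includes k
    waves: tuple[WaveShape, ...]
    branch_labels: tuple[str, ...]  # "slow-narrow" / "fast-wide" / "wave"

    @property
    def n_waves(self) -> int:
        return len(self.waves)


class SolverDiagnosticError(RuntimeError):
    """Root finding failed to converge from every seed."""


def _threshold_residual(params: RateParams, k: float):
    def F(x):
        if not (abs(x[0]) < 25 and abs(x[1]) < 25):
            return [1e3, 1e3]
        c, w = math.exp(x[0]), math.exp(x[1])
        th = matching_thresholds(params, WaveShape(c=c, w=w))
        r0, r1 = th.k_at_0 - k, th.k_at_w - k
        if not (math.isfinite(r0) and math.isfinite(r1)):
            return [1e3, 1e3]
        return [r0, r1]

    return F


def solve_cw_intersections(
    params: RateParams,
    *,
    c_range: tuple[float, float] = (1.0, 3000.0),
    w_range: tuple[float, float] = (10.0, 10000.0),
    n_grid: int = 40,
    dedupe_rtol: float = 1e-3,
    residual_tol: float = 1e-8,
    max_seeds: int = 250,
) -> ExistenceDiagram:
    """Find all (c, w) where both matching conditions equal ``params.k``.

    A 40x40 log-spaced grid over the given ranges seeds damped-Newton
    solves (scipy ``root`` with numerical Jacobian) in (log c, log w);
    converged roots are re-checked against the residual tolerance and
    deduplicated at 0.1% relative distance.  No root is not an error (the
    diagram is empty); failure of every seed to converge raises a
    diagnostic error.
    """
    if params.k is None:
        raise ValueError("params.k must be set (use with_k or the anchoring helper)")
    k = params.k
    F = _threshold_residual(params, k)

    lc = np.log(np.geomspace(*c_range, n_grid))
    lw = np.log(np.geomspace(*w_range, n_grid))
    # coarse residual field to rank seeds
    seeds = []
    for x in lc:
        for y in lw:
            r = F([x, y])
            seeds.append((abs(r[0]) + abs(r[1]), x, y))
    seeds.sort()
    seeds = seeds[:max_seeds]

    roots: list[tuple[float, float]] = []
    n_converged = 0
    with np.errstate(all="ignore"):
        for _score, x, y in seeds:
            sol = optimize.root(F, [x, y], method="hybr")
            if not sol.success or np.max(np.abs(sol.fun)) > residual_tol:
                continue
            n_converged += 1
            c, w = math.exp(sol.x[0]), math.exp(sol.x[1])
            if not (c_range[0] * 0.5 <= c <= c_range[1] * 2 and w_range[0] * 0.5 <= w <= w_range[1] * 2):
                continue
            if any(
                abs(c - rc) / rc < dedupe_rtol and abs(w - rw) / rw < dedupe_rtol
                for rc, rw in roots
            ):
                continue
            roots.append((c, w))
    if n_converged == 0 and not roots:
        # distinguish "no waves" from "solver broke": accept emptiness when the
        # coarse field shows the level k is unattained by min(k_at_0, k_at_w)
        field_min = min(s[0] for s in seeds)
        if not math.isfinite(field_min):
            raise SolverDiagnosticError("matching-condition solver failed from every seed")
    roots.sort()
    waves = tuple(WaveShape(c=c, w=w) for c, w in roots)
    if len(waves) == 2:
        labels = ("slow-narrow", "fast-wide")
    else:
        labels = tuple("wave" for _ in waves)
    return ExistenceDiagram(params=params, waves=waves, branch_labels=labels)


def anchor_and_find_second_wave(
    params: RateParams,
    anchor: WaveShape,
    *,
    anchor_tol: float = 0.05,
    strict: bool = True,
    **solver_kwargs,
) -> ExistenceDiagram:
    """Derive the unprinted threshold from a known wave, then solve.

    Evaluates both matching thresholds at the anchor, requires them to
    agree within ``anchor_tol`` (the anchor must approximately lie on the
    existence curve), sets k to their mean and returns every intersection
    at that k.  With ``strict=False`` the consistency check only logs, so
    the level-set solve can be run diagnostically from an off-curve anchor.
    """
    th = matching_thresholds(params, anchor)
    rel = abs(th.k_at_0 - th.k_at_w) / abs(th.k_at_0)
    if rel > anchor_tol:
        if strict:
            raise AnchorInconsistencyError(th.k_at_0, th.k_at_w, rel, anchor_tol)
        logger.warning(
            "anchor thresholds disagree by %.1f%% (k_at_0=%.6g, k_at_w=%.6g); "
            "proceeding with their mean",
            100 * rel, th.k_at_0, th.k_at_w,
        )
    k = 0.5 * (th.k_at_0 + th.k_at_w)
    return solve_cw_intersections(params.with_k(k), **solver_kwargs)


# ---------------------------------------------------------------------------
# (sigma, beta) solution curve at fixed (c, w)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SigmaBetaCurve:
    """Samples (sigma, beta, k, regime) on which a wave of fixed (c, w) exists."""

    c: float
    w: float
    alpha: float
    delta: float
    sigma: np.ndarray  # um
    beta: np.ndarray  # 1/ms
    k: np.ndarray
    regime: tuple[Regime, ...]
    gaps: tuple[float, ...] = ()  # sigma values with no bracketed solution

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sigma_um": self.sigma,
                "beta_per_ms": self.beta,
                "k": self.k,
                "regime": [r.value for r in self.regime],
            }
        )


def _mismatch_at(alpha: float, delta: float, beta: float, shape: WaveShape, sigma: float) -> float:
    p = RateParams(alpha=alpha, delta=delta, beta0=beta / alpha, sigma=sigma)
    th = matching_thresholds(p, shape)
    return th.k_at_0 - th.k_at_w


def solve_sigma_beta_curve(
    c: float,
    w: float,
    alpha: float,
    delta: float,
    sigma_grid=None,
    *,
    beta_range: tuple[float, float] = (1e-5, 5.0),
    n_beta_scan: int = 240,
) -> SigmaBetaCurve:
    """Solve k_at_0 = k_at_w for beta along a sigma grid.

    For each sigma, the threshold mismatch is scanned over a log-spaced
    beta bracket; every sign change is refined by Brent's method and the
    root closest to the regime the discriminant implies is kept (when
    several betas solve the equality, all are kept as separate samples).
    Sigmas with no sign change are recorded as gaps, not errors.
    """
    shape = WaveShape(c=c, w=w)
    if sigma_grid is None:
        sigma_grid = np.geomspace(20.0, 1000.0, 40)
    sig_out, beta_out, k_out, reg_out, gaps = [], [], [], [], []
    betas = np.geomspace(*beta_range, n_beta_scan)
    crit = (alpha - delta) ** 2 / (4.0 * delta)  # regime-boundary beta
    for sig in np.asarray(sigma_grid, dtype=float):
        vals = np.array([_mismatch_at(alpha, delta, b, shape, sig) for b in betas])
        idx = np.where(np.sign(vals[:-1]) != np.sign(vals[1:]))[0]
        found = False
        for i in idx:
            try:
                b_root = optimize.brentq(
                    lambda b: _mismatch_at(alpha, delta, b, shape, sig),
                    betas[i], betas[i + 1], xtol=1e-14, rtol=1e-14,
                )
            except ValueError:
                continue
            if abs(4.0 * delta * b_root - (alpha - delta) ** 2) < 1e-13:
                continue  # critically damped: no closed form
            p = RateParams(alpha=alpha, delta=delta, beta0=b_root / alpha, sigma=sig)
            th = matching_thresholds(p, shape)
            sig_out.append(sig)
            beta_out.append(b_root)
            k_out.append(0.5 * (th.k_at_0 + th.k_at_w))
            reg_out.append(Regime.COMPLEX if b_root > crit else Regime.REAL)
            found = True
        if not found:
            gaps.append(sig)
            logger.info("sigma=%.1f um: no beta in [%g, %g] solves the matching equality",
                        sig, *beta_range)
    return SigmaBetaCurve(
        c=c, w=w, alpha=alpha, delta=delta,
        sigma=np.array(sig_out), beta=np.array(beta_out), k=np.array(k_out),
        regime=tuple(reg_out), gaps=tuple(gaps),
    )


# ---------------------------------------------------------------------------
# feasibility sweep over the timescale alpha
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FeasibilitySweep:
    """Percentage of observed waves with a physically reasonable sigma."""

    alpha_grid: np.ndarray  # 1/s (presentation units)
    ratio: float
    percent_feasible: np.ndarray
    sigma_floor: float = 20.0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"alpha_per_s": self.alpha_grid, "percent_feasible": self.percent_feasible}
        )


def _solve_sigma_for_wave(
    alpha: float, delta: float, beta: float, shape: WaveShape,
    sigma_range: tuple[float, float] = (1.0, 10000.0), n_scan: int = 120,
) -> list[float]:
    """All sigma at which the two matching conditions agree for this wave."""
    sigs = np.geomspace(*sigma_range, n_scan)
    vals = np.array([_mismatch_at(alpha, delta, beta, shape, s) for s in sigs])
    idx = np.where(np.sign(vals[:-1]) != np.sign(vals[1:]))[0]
    roots = []
    for i in idx:
        try:
            roots.append(
                optimize.brentq(
                    lambda s: _mismatch_at(alpha, delta, beta, shape, s),
                    sigs[i], sigs[i + 1], xtol=1e-10,
                )
            )
        except ValueError:
            continue
    return roots


def feasibility_sweep(
    features: pd.DataFrame,
    alpha_grid,
    ratio: float = 10.0,
    *,
    sigma_floor: float = 20.0,
) -> FeasibilitySweep:
    """Fraction of waves supporting a solution with sigma above the floor.

    ``features`` columns: ``speed_um_per_ms``, ``width_um``, ``tau_ms``.
    For each wave and each alpha (1/s) the adaptation rate is fixed by the
    reverberation inversion with delta = alpha/ratio, then sigma is solved
    from the matching equality at the observed (c, w); the wave counts as
    feasible iff at least one solved sigma exceeds the floor (20 um, below
    which the connectivity extent is smaller than a cortical column).
    Unsolvable waves count as infeasible.
    """
    required = {"speed_um_per_ms", "width_um", "tau_ms"}
    if not required.issubset(features.columns):
        raise ValueError(f"feature table must have columns {sorted(required)}")
    if len(features) == 0:
        raise ValueError("no waves: the feature table is empty")
    if (features[list(required)] <= 0).any().any():
        raise ValueError("speed, width and tau must all be positive")

    alpha_grid = np.asarray(alpha_grid, dtype=float)
    pct = np.zeros(len(alpha_grid))
    for ia, alpha_s in enumerate(alpha_grid):
        alpha = alpha_s / 1000.0
        delta = alpha / ratio
        n_ok = 0
        for _, row in features.iterrows():
            shape = WaveShape(c=float(row.speed_um_per_ms), w=float(row.width_um))
            fit = beta_from_reverberation(float(row.tau_ms), alpha, delta)
            roots = _solve_sigma_for_wave(alpha, delta, fit.beta_empirical, shape)
            if any(s > sigma_floor for s in roots):
                n_ok += 1
        pct[ia] = 100.0 * n_ok / len(features)
    return FeasibilitySweep(
        alpha_grid=alpha_grid, ratio=ratio, percent_feasible=pct, sigma_floor=sigma_floor
    )
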