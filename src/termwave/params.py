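"""Model parameterization and eigenvalue-regime classification.

The neural field couples a synaptic-activity variable u(x, t) to a linear
adaptation variable q(x, t):

    u_t = -alpha*u + alpha*H( (w * u)(x) + P(x,t) - k ) - alpha*beta0*q
    q_t = delta*u - delta*q

with exponential connectivity kernel w(x) = exp(-|x|/sigma)/(2*sigma) and a
Heaviside firing nonlinearity H.  Internal units are fixed: time in ms,
space in um, so all rates are 1/ms.  Constructors accept rates quoted in
1/s (the common convention in the experimental literature) and convert at
the boundary.

The shorthand beta = alpha*beta0 is used throughout the traveling-wave
algebra.  In the frame z = x - c*t the linearized return to rest is
governed by the discriminant

    disc = 4*delta*beta - (alpha - delta)**2        [1/ms^2]

whose sign splits solutions into a monotone (REAL) regime and a
damped-oscillatory (COMPLEX) regime; the oscillatory tail carries the
"reverberation" seen in the data.
"""
from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, replace

__all__ = [
    "RateParams",
    "WaveShape",
    "EigenRegime",
    "Regime",
    "CriticalDampingError",
    "RegimeMismatchError",
    "classify_eigenvalues",
    "discriminant",
]

#: tolerance on the discriminant (1/ms^2) below which the classification is
#: refused as critically damped
DISC_TOL = 1e-14


class CriticalDampingError(ValueError):
    """Discriminant is numerically zero: no closed form exists at the boundary."""


class RegimeMismatchError(ValueError):
    """A regime-specific closed form was requested for the wrong regime."""


class Regime(enum.Enum):
    REAL = "real"
    COMPLEX = "complex"


@dataclass(frozen=True)
class RateParams:
    """Rates, coupling and threshold of the single-population model.

    Parameters
    ----------
    alpha : float
        Synaptic activity decay rate, 1/ms.
    delta : float
        Adaptation decay rate, 1/ms.
    beta0 : float
        Dimensionless adaptation strength; the algebra uses
        ``beta = alpha * beta0``.
    sigma : float
        Connectivity decay length, um.
    k : float or None
        Synaptic input threshold (dimensionless); optional until solved
        for by the matching conditions.
    """

    alpha: float
    delta: float
    beta0: float
    sigma: float
    k: float | None = None

    def __post_init__(self) -> None:
        if not (self.alpha > 0):
            raise ValueError(f"alpha must be > 0 (1/ms), got {self.alpha}")
        if not (self.delta > 0):
            raise ValueError(f"delta must be > 0 (1/ms), got {self.delta}")
        if not (self.beta0 >= 0):
            raise ValueError(f"beta0 must be >= 0, got {self.beta0}")
        if not (self.sigma > 0):
            raise ValueError(f"sigma must be > 0 (um), got {self.sigma}")
        if self.k is not None and not (0 < self.k < 1):
            raise ValueError(f"k must lie in (0, 1), got {self.k}")

    @property
    def beta(self) -> float:
        """Adaptation rate beta = alpha * beta0, 1/ms."""
        return self.alpha * self.beta0

    @classmethod
    def from_per_second(
        cls,
        alpha: float,
        delta: float,
        beta0: float,
        sigma: float,
        k: float | None = None,
    ) -> "RateParams":
        """Build from rates quoted in 1/s (divided by 1000 to 1/ms)."""
        return cls(alpha=alpha / 1000.0, delta=delta / 1000.0, beta0=beta0, sigma=sigma, k=k)

    def to_per_second(self) -> dict:
        """Rates back in 1/s; exact inverse of :meth:`from_per_second`."""
        return {
            "alpha": self.alpha * 1000.0,
            "delta": self.delta * 1000.0,
            "beta0": self.beta0,
            "sigma": self.sigma,
            "k": self.k,
        }

    def with_k(self, k: float) -> "RateParams":
        return replace(self, k=k)

    def with_beta0(self, beta0: float) -> "RateParams":
        return replace(self, beta0=beta0)


@dataclass(frozen=True)
class WaveShape:
    """A traveling pulse's speed c (um/ms) and width w (um).

    The moving coordinate is z = x - c*t with c > 0 (rightward waves); the
    suprathreshold interval is (0, w), leading edge at z = w.
    """

    c: float
    w: float

    def __post_init__(self) -> None:
        if not (self.c > 0):
            raise ValueError(f"speed c must be > 0 (um/ms), got {self.c}")
        if not (self.w > 0):
            raise ValueError(f"width w must be > 0 (um), got {self.w}")

    @property
    def transit_time(self) -> float:
        """Time (ms) for the pulse to traverse its own width."""
        return self.w / self.c


@dataclass(frozen=True)
class EigenRegime:
    regime: Regime
    discriminant: float  # 4*delta*beta - (alpha-delta)^2, 1/ms^2


def discriminant(params: RateParams) -> float:
    """4*delta*beta - (alpha - delta)**2 in 1/ms^2."""
    return 4.0 * params.delta * params.beta - (params.alpha - params.delta) ** 2


def classify_eigenvalues(params: RateParams) -> EigenRegime:
    """Classify the return-to-rest dynamics of the traveling frame.

    COMPLEX iff the discriminant is positive (damped oscillations trail the
    pulse); REAL iff negative (monotone return).  A numerically zero
    discriminant (|disc| < 1e-14 1/ms^2) raises
    :class:`CriticalDampingError` rather than silently picking a side.
    """
    disc = discriminant(params)
    if abs(disc) < DISC_TOL:
        raise CriticalDampingError(
            f"discriminant {disc:.3e} 1/ms^2 is numerically zero (critical "
            "damping); no closed-form solution family applies"
        )
    regime = Regime.COMPLEX if disc > 0 else Regime.REAL
    return EigenRegime(regime=regime, discriminant=disc)
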