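"""Continuum-limit predictions for the uniform 1D model.

Coarse-graining the discrete model (non-dimensional units, ``beta0 = gamma =
1``, Hill exponent ``k = 2``) gives closed forms used throughout as analytic
oracles for the simulator:

* membrane loading: ``d(rho_m)/dt = 2*alpha*(rho - rho_m) - 4*rho_m/(rho_m**2 + 4)``,
  whose steady state defines ``rho_m(rho, alpha)``;
* linear stability: the zero-polarity state destabilizes when the membrane
  concentration exceeds ``rho_m = 2``, giving the critical total concentration
  ``rho_c(alpha) = 2 + 1/(2*alpha)``;
* gradient response below threshold:
  ``p = (2*rho_m**2/(rho_m**2 - 4)) * 2*alpha*epsilon/(2*alpha + 1)``;
* polarity decay from a deletion boundary above threshold:
  ``p(x) = p0 * exp(-x/d)`` with
  ``d = rho_m**2/(rho_m**2 + 4) * (alpha*(rho_m**2 - 4)/8)**-0.5``.

These formulas are derived in the ``k = 2`` non-dimensional regime only; the
functions refuse other parameter values rather than extrapolate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .kinetics import KineticParams

__all__ = [
    "ContinuumPoint",
    "membrane_steady_state",
    "critical_rho",
    "instability_threshold",
    "polarity_growth_coefficient",
    "linear_response_polarity",
    "decay_length",
    "decay_profile",
    "check_regime",
]


def check_regime(params: KineticParams) -> None:
    """Reject parameter regimes the closed forms were not derived for."""
    if not (params.beta0 == 1 and params.gamma == 1 and params.k == 2):
        raise ValueError(
            "continuum formulas are derived for the non-dimensional regime "
            "beta0 = 1, gamma = 1, k = 2"
        )


@dataclass(frozen=True)
class ContinuumPoint:
    """A point of the uniform continuum model: (rho, alpha) and the membrane
    steady state rho_m they determine."""

    rho: float
    alpha: float
    rho_m: float

    def __post_init__(self) -> None:
        if not 0 <= self.rho_m <= self.rho:
            raise ValueError("rho_m must lie in [0, rho]")


def _loading_balance(rho_m: float, rho: float, alpha: float) -> float:
    return 2 * alpha * (rho - rho_m) - 4 * rho_m / (rho_m**2 + 4)


def membrane_steady_state(rho: float, alpha: float) -> float:
    """Steady membrane-bound concentration ``rho_m`` of the uniform model.

    Unique root in ``[0, rho]`` of ``2*alpha*(rho - rho_m) = 4*rho_m/(rho_m**2 + 4)``
    (binding of the free pool balancing Hill-repressed unbinding).
    """
    if rho < 0:
        raise ValueError("rho must be non-negative")
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    if rho == 0:
        return 0.0
    lo, hi = 0.0, float(rho)
    f_lo, f_hi = _loading_balance(lo, rho, alpha), _loading_balance(hi, rho, alpha)
    if not (f_lo > 0 >= f_hi):
        raise RuntimeError("root bracket [0, rho] failed; no steady state found")
    return float(brentq(_loading_balance, lo, hi, args=(rho, alpha), xtol=1e-12, rtol=1e-15))


def critical_rho(alpha: float) -> float:
    """Critical total protein concentration ``rho_c = 2 + 1/(2*alpha)``.

    Above ``rho_c`` the uniform tissue polarizes spontaneously.  Strictly
    decreasing in ``alpha`` with infimum 2.
    """
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    return 2.0 + 1.0 / (2.0 * alpha)


def polarity_growth_coefficient(rho_m: float) -> float:
    """Linear growth coefficient of tissue polarity about ``p = 0``:
    ``-4*(4 - rho_m**2)/(rho_m**2 + 4)**2``.  Negative (stable) below the
    instability threshold, positive above."""
    return -4.0 * (4.0 - rho_m**2) / (rho_m**2 + 4.0) ** 2


def instability_threshold() -> float:
    """Membrane concentration at which the zero-polarity state loses linear
    stability, located from the sign change of the growth coefficient."""
    return float(brentq(polarity_growth_coefficient, 0.5, 10.0, xtol=1e-14))


def linear_response_polarity(rho_m: float, alpha: float, epsilon: float) -> float:
    """Below-threshold tissue polarity induced by a weak Ft gradient:
    ``p = (2*rho_m**2/(rho_m**2 - 4)) * 2*alpha*epsilon/(2*alpha + 1)``.

    Valid for ``rho_m < 2`` (where the factor is negative: for a positive
    gradient Ft polarizes down-gradient and Ds up-gradient, so ``p = <pf - pd>``
    is negative).  The susceptibility diverges as ``rho_m`` approaches 2.
    """
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    if rho_m >= 2:
        raise ValueError("linear gradient response is only valid below threshold (rho_m < 2)")
    return (2 * rho_m**2 / (rho_m**2 - 4)) * 2 * alpha * epsilon / (2 * alpha + 1)


def decay_length(rho_m: float, alpha: float) -> float:
    """Decay length of boundary-induced polarity above threshold (cell units):
    ``d = rho_m**2/(rho_m**2 + 4) * (alpha*(rho_m**2 - 4)/8)**-0.5``.

    Diverges as ``rho_m`` approaches 2 from above; below threshold the
    boundary-induced polarity vanishes identically and the formula does not
    apply (domain error).
    """
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    if rho_m <= 2:
        raise ValueError("decay length is defined for rho_m > 2 (p = 0 below threshold)")
    return rho_m**2 / (rho_m**2 + 4.0) / np.sqrt(alpha * (rho_m**2 - 4.0) / 8.0)


def decay_profile(p0: float, x, d: float):
    """Exponential polarity profile ``p(x) = p0 * exp(-x/d)``."""
    if d <= 0:
        raise ValueError("decay length d must be positive")
    return p0 * np.exp(-np.asarray(x, dtype=float) / d)
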