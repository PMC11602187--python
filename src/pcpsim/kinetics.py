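"""Kinetic parameterization and the Hill factors that modulate unbinding.

The model describes two atypical cadherins (Ft and Ds) that bind to the cell
membrane at rate ``alpha`` and unbind at a bare rate ``beta0``.  A
membrane-bound protein is stabilized by its heterodimer partner on the facing
membrane of the neighboring cell: the unbinding rate is multiplied by the
repressive Hill factor ``H2(c) = 1 / (1 + (gamma*c)**k)`` where ``c`` is the
partner concentration across the cell-cell interface.

All quantities default to the non-dimensional scheme in which time is measured
in units of ``1/beta0``, concentrations in units of ``1/gamma`` and lengths in
cell diameters, so ``beta0 = gamma = 1`` unless a dimensional calculation is
explicitly wanted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["KineticParams", "hill_repress", "hill_activate", "unbinding_rate"]


@dataclass(frozen=True)
class KineticParams:
    """Rate constants and Hill parameters of the binding/unbinding kinetics.

    Parameters
    ----------
    alpha
        Membrane binding rate (per unit time ``1/beta0``).
    beta0
        Bare unbinding rate; 1 after non-dimensionalization.
    gamma
        Inverse concentration scale of the Hill factor; 1 after
        non-dimensionalization.
    k
        Hill cooperativity exponent (integer >= 1).  The published results use
        ``k = 2`` but are qualitatively insensitive to this choice.
    d_theta
        Diffusion coefficient of membrane-bound protein along the angular
        membrane coordinate of a hexagonal cell (2D model only; default 0).
    """

    alpha: float = 1.0
    beta0: float = 1.0
    gamma: float = 1.0
    k: int = 2
    d_theta: float = 0.0

    def __post_init__(self) -> None:
        if not self.alpha > 0:
            raise ValueError(f"alpha must be positive, got {self.alpha}")
        if not self.beta0 > 0:
            raise ValueError(f"beta0 must be positive, got {self.beta0}")
        if not self.gamma > 0:
            raise ValueError(f"gamma must be positive, got {self.gamma}")
        if int(self.k) != self.k or self.k < 1:
            raise ValueError(f"k must be an integer >= 1, got {self.k}")
        if self.d_theta < 0:
            raise ValueError(f"d_theta must be non-negative, got {self.d_theta}")


def _check_nonnegative(c) -> np.ndarray:
    c = np.asarray(c, dtype=float)
    if np.any(c < 0):
        raise ValueError("partner concentration must be non-negative")
    return c


def hill_repress(c, params: KineticParams = KineticParams()):
    """Repressive Hill factor ``H2(c) = 1 / (1 + (gamma*c)**k)``.

    Strictly decreasing in ``c``; equals 1 at ``c = 0`` (no partner, unbinding
    unmodified) and tends to 0 as ``c`` grows (full heterodimer stabilization).
    Accepts scalars or arrays.
    """
    c = _check_nonnegative(c)
    x = (params.gamma * c) ** params.k
    out = 1.0 / (1.0 + x)
    return out if out.shape else float(out)


def hill_activate(c, params: KineticParams = KineticParams()):
    """Activating Hill factor ``H1(c) = (gamma*c)**k / (1 + (gamma*c)**k)``.

    Defined as the exact complement of :func:`hill_repress`, so that
    ``H1 + H2 == 1`` and ``dH2/dc = -(k/c) * H1(c) * H2(c)``, the identity the
    continuum expansion of the model relies on.
    """
    c = _check_nonnegative(c)
    x = (params.gamma * c) ** params.k
    out = x / (1.0 + x)
    return out if out.shape else float(out)


def unbinding_rate(c_partner, params: KineticParams = KineticParams()):
    """Hill-modulated unbinding rate ``beta(c) = beta0 * H2(c_partner)``.

    ``c_partner`` is the partner cadherin's concentration on the facing
    membrane of the neighboring cell.
    """
    return params.beta0 * hill_repress(c_partner, params)
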