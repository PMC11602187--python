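"""Polarity-field statistics and derived analyses.

Covers the quantitative read-outs of the model: the polarity-polarity
correlation function and its integral correlation length, exponential decay
fits of boundary-induced polarity, discrete curl/divergence maps for
swirl/aster defects, radial polarity profiles around clones, phase-diagram
sweeps of the 1D model, and averaging over noise realizations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .expression import uniform_profile
from .kinetics import KineticParams
from .lattice1d import Sim1DConfig, initial_state, simulate_1d, tissue_polarity_1d
from .lattice2d import EDGE_VECTORS, HexLattice

__all__ = [
    "CorrelationResult",
    "DecayFit",
    "SweepResult",
    "correlation_function",
    "correlation_length",
    "fit_decay_length",
    "curl_divergence",
    "radial_polarity",
    "phase_diagram",
    "polarization_onset",
    "realization_average",
]


@dataclass
class CorrelationResult:
    """Binned correlation function C(r) and the integral correlation length
    zeta (area under the C(0)-normalized, time-averaged curve up to L/2)."""

    r_bins: np.ndarray
    C: np.ndarray
    zeta: float = np.nan
    zeta_normalized: float = np.nan
    L: float = np.nan


@dataclass
class DecayFit:
    """Log-linear exponential fit ``|p(x)| = p0 * exp(-x/d)``."""

    p0: float
    d_fit: float
    r_squared: float
    n_points: int
    success: bool


@dataclass
class SweepResult:
    """Grid sweep summary; ``table`` has one row per grid point."""

    table: pd.DataFrame
    meta: Dict = field(default_factory=dict)


def _as_vectors(pol: np.ndarray) -> np.ndarray:
    pol = np.asarray(pol, dtype=float)
    if pol.ndim == 1:
        pol = pol[:, None]
    return pol


def correlation_function(
    polarity: np.ndarray,
    positions: np.ndarray,
    bin_width: float = 1.0,
) -> Tuple[np.ndarray, np.ndarray]:
    """Pair correlation ``C(r) = <p_i . p_j>`` over all ordered cell pairs
    whose center distance falls in the bin at ``r`` (bin centers ``0, w, 2w,
    ...``; the r = 0 bin holds the self-terms ``<|p|^2>``).

    ``polarity`` is (n,) for scalar 1D fields or (n, 2) for vector fields;
    ``positions`` is (n,) or (n, k) cell-center coordinates.
    """
    P = _as_vectors(polarity)
    X = np.asarray(positions, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n = P.shape[0]
    if n < 2:
        raise ValueError("correlation function needs at least 2 cells")
    diff = X[:, None, :] - X[None, :, :]
    dist = np.sqrt((diff**2).sum(axis=-1))
    dots = P @ P.T
    idx = np.round(dist / bin_width).astype(int).ravel()
    sums = np.bincount(idx, weights=dots.ravel())
    counts = np.bincount(idx)
    populated = counts > 0
    r_bins = np.arange(sums.size)[populated] * bin_width
    C = sums[populated] / counts[populated]
    return r_bins, C


def correlation_length(
    frames: Sequence[np.ndarray],
    positions: np.ndarray,
    L: Optional[float] = None,
    bin_width: float = 1.0,
    tail_fraction: float = 0.6,
    protocol_frames: int = 500,
) -> CorrelationResult:
    """Integral correlation length of a polarity-field trajectory.

    The correlation function is averaged over the final ``tail_fraction`` of
    the saved frames (the published protocol: last 300 of 500), normalized to
    ``C(0) = 1`` and trapezoid-integrated from ``r = 0`` to ``r = L/2``.  For
    a perfectly uniform field zeta equals ``L/2``; for spatial white noise it
    is of order one bin width.  ``L`` is the linear extent of the system in
    cell units (used both as the integration cutoff and for
    ``zeta_normalized = zeta / L``).
    """
    frames = list(frames)
    if not frames:
        raise ValueError("empty trajectory")
    if len(frames) < protocol_frames:
        warnings.warn(
            f"only {len(frames)} saved frames; the reference protocol "
            f"time-averages over the tail of {protocol_frames}",
            stacklevel=2,
        )
    X = np.asarray(positions, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if L is None:
        L = float(np.ptp(X, axis=0).max() + 1.0)
    n_tail = max(int(np.ceil(tail_fraction * len(frames))), 1)
    acc = None
    for fr in frames[-n_tail:]:
        r_bins, C = correlation_function(fr, X, bin_width)
        acc = C if acc is None else acc + C
    C_avg = acc / n_tail
    if C_avg[0] <= 0:
        warnings.warn("null polarity field: correlation length set to 0", stacklevel=2)
        return CorrelationResult(r_bins, C_avg, zeta=0.0, zeta_normalized=0.0, L=L)
    C_norm = C_avg / C_avg[0]
    r_max = L / 2.0
    sel = r_bins <= r_max
    zeta = float(np.trapezoid(C_norm[sel], r_bins[sel]))
    return CorrelationResult(r_bins, C_norm, zeta=zeta, zeta_normalized=zeta / L, L=L)


def fit_decay_length(
    pf: np.ndarray,
    boundary_index: int,
    side: str = "right",
    floor: float = 1e-10,
    far_field: Optional[object] = None,
) -> DecayFit:
    """Least-squares exponential fit of a polarity profile from a boundary.

    Fits ``|pf(x)| = p0 * exp(-x/d)`` in log-linear form over the cells on the
    intact side of ``boundary_index`` (distance x measured in cells from the
    boundary) whose magnitude exceeds ``floor``.  Returns a flagged failure if
    fewer than 3 cells carry polarity above the floor.

    Above the spontaneous-polarization threshold the converged profile tends
    to a polarized bulk value far from the boundary; the exponentially
    decaying observable is then the boundary-layer deviation from that value.
    Pass ``far_field='auto'`` to subtract a robust interior estimate of the
    bulk value (or a number to subtract explicitly) before fitting; in that
    mode only the asymptotic tail of the deviation is fitted, excluding the
    nonlinear core of the boundary domain wall.
    """
    pf = np.asarray(pf, dtype=float)
    if side == "right":
        seq = pf[boundary_index:]
    elif side == "left":
        seq = pf[:boundary_index + 1][::-1]
    else:
        raise ValueError("side must be 'left' or 'right'")
    if seq.size < 10:
        raise ValueError("need at least 10 cells on the intact side of the boundary")
    floor_eff = floor
    if far_field == "auto":
        # reference = median of an interior window (second half of the intact
        # side, excluding the trailing 10% so the opposite boundary's own
        # layer does not bias it); the fit cutoff is raised to the reference
        # scatter so subtraction noise is never fitted
        win = seq[seq.size // 2 : -max(seq.size // 10, 1)]
        if win.size < 3:
            win = seq[seq.size // 2 :]
        ref = float(np.median(win))
        sigma = 1.4826 * float(np.median(np.abs(win - ref)))
        seq = seq - ref
        floor_eff = max(floor, 4.0 * sigma)
        # drop the nonlinear core of a boundary domain wall: keep only the
        # asymptotic tail where the deviation is small against the bulk value
        small = np.abs(seq) <= 0.25 * abs(ref)
        if small.any() and not small.all() and abs(ref) > 0:
            start = int(np.argmax(small))
            seq = seq[start:]
    elif far_field is not None:
        seq = seq - float(far_field)
    vals = np.abs(seq)
    x = np.arange(vals.size, dtype=float)
    # fit the contiguous above-floor run from the boundary outward: past it the
    # profile is numerical zero and log-space noise would dominate
    above = vals > floor_eff
    n_run = int(np.argmin(above)) if not above.all() else vals.size
    x_fit, y_fit = x[:n_run], vals[:n_run]
    if n_run < 3:
        return DecayFit(np.nan, np.nan, np.nan, n_run, success=False)
    logy = np.log(y_fit)
    slope, intercept = np.polyfit(x_fit, logy, 1)
    if slope >= 0:
        return DecayFit(np.nan, np.nan, np.nan, n_run, success=False)
    pred = slope * x_fit + intercept
    ss_res = float(np.sum((logy - pred) ** 2))
    ss_tot = float(np.sum((logy - logy.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return DecayFit(float(np.exp(intercept)), float(-1.0 / slope), r2, n_run, success=True)


def curl_divergence(
    polarity: np.ndarray,
    lattice: HexLattice,
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Discrete curl (z-component) and divergence of a 2D polarity field.

    Projects neighbor differences onto the six edge directions: with all six
    neighbors present, ``div = (1/3) * sum_b u_b . (p(x + u_b) - p(x))`` and
    ``curl = (1/3) * sum_b (u_b x (p(x + u_b) - p(x)))_z``, which reduce to
    the continuum operators for slowly varying fields.  Boundary cells use
    their available neighbors only (weight rescaled to 2/n_available) and are
    flagged in the returned boolean mask.
    """
    P = np.asarray(polarity, dtype=float)
    if P.ndim != 2 or P.shape[1] != 2:
        raise ValueError("polarity must have shape (n_cells, 2)")
    nbr = lattice.neighbors
    valid = nbr >= 0
    n_valid = valid.sum(axis=1)
    div = np.zeros(P.shape[0])
    curl = np.zeros(P.shape[0])
    for b in range(6):
        m = valid[:, b]
        dp = np.zeros_like(P)
        dp[m] = P[nbr[m, b]] - P[m]
        u = EDGE_VECTORS[b]
        div += dp @ u
        curl += u[0] * dp[:, 1] - u[1] * dp[:, 0]
    w = np.where(n_valid > 0, 2.0 / np.maximum(n_valid, 1), 0.0)
    return curl * w, div * w, n_valid < 6


def radial_polarity(
    polarity: np.ndarray,
    lattice: HexLattice,
    center: Optional[Sequence[float]] = None,
    gradient_axis: Optional[str] = None,
    bin_width: float = 1.0,
) -> pd.DataFrame:
    """Radial polarity component vs distance from a clone center, by sector.

    For each cell the projection ``p . r_hat`` onto the outward unit vector
    from ``center`` is binned by distance.  With ``gradient_axis = 'x'`` cells
    are split into sectors: 'up' (within 45 degrees of +x, up-gradient),
    'down' (within 45 degrees of -x) and 'normal' (the rest); without a
    gradient a single 'all' sector is used.  Returns a table with columns
    (sector, r, radial_mean, n_cells).
    """
    P = np.asarray(polarity, dtype=float)
    X = lattice.centers
    c = X.mean(axis=0) if center is None else np.asarray(center, dtype=float)
    rel = X - c
    r = np.linalg.norm(rel, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        rhat = np.where(r[:, None] > 0, rel / np.maximum(r, 1e-300)[:, None], 0.0)
    radial = (P * rhat).sum(axis=1)
    if gradient_axis is None:
        sector = np.full(r.size, "all", dtype=object)
    elif gradient_axis == "x":
        cosphi = np.where(r > 0, rhat[:, 0], 0.0)
        sector = np.where(
            cosphi > np.cos(np.pi / 4), "up",
            np.where(cosphi < -np.cos(np.pi / 4), "down", "normal"),
        ).astype(object)
    else:
        raise ValueError("gradient_axis must be None or 'x'")
    rbin = np.round(r / bin_width) * bin_width
    df = pd.DataFrame({"sector": sector, "r": rbin, "radial": radial})
    out = (
        df.groupby(["sector", "r"], as_index=False)
        .agg(radial_mean=("radial", "mean"), n_cells=("radial", "size"))
        .sort_values(["sector", "r"])
        .reset_index(drop=True)
    )
    return out


def _classify_point(
    alpha: float,
    rho: float,
    n_cells: int,
    boundary: str,
    config: Sim1DConfig,
    threshold: float,
) -> Tuple[float, bool]:
    params = KineticParams(alpha=alpha)
    profile = uniform_profile(n_cells, rho, rho)
    state0 = initial_state(profile, config)
    res = simulate_1d(state0, profile, params, config)
    return tissue_polarity_1d(res.state), res.converged


def phase_diagram(
    alpha_grid: Sequence[float],
    rho_grid: Sequence[float],
    n_cells: int = 100,
    boundary: str = "periodic",
    threshold: float = 1e-3,
    max_time: float = 3000.0,
) -> SweepResult:
    """Polarized/unpolarized classification of the uniform 1D model over an
    (alpha, rho) grid.

    Each point is relaxed from the canonical 1%-asymmetry initial state and
    classified polarized iff ``|p| > threshold``.  Non-converged points carry
    ``converged = False`` and are left unclassified (NaN).
    """
    rows = []
    config = Sim1DConfig(n_cells=n_cells, boundary=boundary, max_time=max_time)
    for alpha in alpha_grid:
        for rho in rho_grid:
            p, conv = _classify_point(alpha, rho, n_cells, boundary, config, threshold)
            rows.append(
                dict(alpha=alpha, rho=rho, p=p, abs_p=abs(p),
                     polarized=(abs(p) > threshold) if conv or abs(p) > threshold else np.nan,
                     converged=conv)
            )
    table = pd.DataFrame(rows)
    return SweepResult(table, meta=dict(n_cells=n_cells, boundary=boundary, threshold=threshold))


def polarization_onset(
    alpha: float,
    rho_bracket: Tuple[float, float] = (1.5, 6.0),
    resolution: float = 0.05,
    n_cells: int = 100,
    boundary: str = "periodic",
    threshold: float = 1e-3,
    max_time: float = 3000.0,
) -> float:
    """Onset total concentration of spontaneous polarization, by bisection.

    Bisects ``rho`` between an unpolarized and a polarized endpoint of
    ``rho_bracket`` until the bracket is narrower than ``resolution``; returns
    the bracket midpoint.  Classification is ``|p| > threshold`` after
    relaxation of the uniform model.
    """
    config = Sim1DConfig(n_cells=n_cells, boundary=boundary, max_time=max_time)
    lo, hi = rho_bracket

    def polarized(rho: float) -> bool:
        p, _ = _classify_point(alpha, rho, n_cells, boundary, config, threshold)
        return abs(p) > threshold

    if polarized(lo):
        raise ValueError(f"lower bracket rho={lo} is already polarized")
    if not polarized(hi):
        raise ValueError(f"upper bracket rho={hi} is not polarized")
    while hi - lo > resolution:
        mid = 0.5 * (lo + hi)
        if polarized(mid):
            hi = mid
        else:
            lo = mid
    return 0.5 * (lo + hi)


def realization_average(
    experiment: Callable[[int], Dict[str, float]],
    n_realizations: int,
    base_seed: int,
) -> Tuple[Dict[str, float], Dict[str, float], int]:
    """Mean and sample SD of an experiment's outputs over seeds
    ``base_seed .. base_seed + n - 1``.

    ``experiment(seed)`` returns a dict of scalar quantities.  Failed
    realizations (raised exceptions) are excluded and counted.  Deterministic
    given ``base_seed``.
    """
    if n_realizations < 2:
        raise ValueError("need at least 2 realizations")
    results = []
    n_failed = 0
    for s in range(base_seed, base_seed + n_realizations):
        try:
            results.append(experiment(s))
        except Exception:
            n_failed += 1
    if not results:
        raise RuntimeError("all realizations failed")
    keys = results[0].keys()
    mean = {k: float(np.mean([r[k] for r in results])) for k in keys}
    sd = {k: float(np.std([r[k] for r in results], ddof=1)) if len(results) > 1 else 0.0
          for k in keys}
    return mean, sd, n_failed
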