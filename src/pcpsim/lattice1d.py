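"""One-dimensional row-of-cells model.

Each cell ``i`` carries membrane-bound Ft on its left and right edges,
``fl(i)`` and ``fr(i)``, and likewise ``dl(i)``, ``dr(i)`` for Ds.  The
dynamics couple neighboring cells through heterodimer stabilization: the
unbinding of Ft from the left edge of cell ``i`` is repressed by Ds on the
right edge of cell ``i - 1`` (the facing membrane), and symmetrically for the
other three populations:

    d(fl)/dt = alpha * (fT - fm) - beta0 * fl * H2(dr(i-1))
    d(fr)/dt = alpha * (fT - fm) - beta0 * fr * H2(dl(i+1))
    d(dl)/dt = alpha * (dT - dm) - beta0 * dl * H2(fr(i-1))
    d(dr)/dt = alpha * (dT - dm) - beta0 * dr * H2(fl(i+1))

with ``fm = fl + fr`` the total membrane-bound Ft of the cell (cytoplasmic
remainder ``fT - fm`` implicit).  Deterministic steady states are obtained
with an adaptive stiff-capable ODE solver; stochastic (Langevin) dynamics use
fixed-step Euler-Maruyama with additive white noise per edge, protein and
cell.

Cell polarity is the right-left asymmetry ``pf = fr - fl``, ``pd = dr - dl``;
tissue polarity is the cell average of ``pf - pd``.
"""

from __future__ import annotations


from dataclasses import dataclass
from typing import List, Optional, Tuple

import numpy as np
from scipy.integrate import solve_ivp

from .expression import ExpressionProfile
from .kinetics import KineticParams

__all__ = [
    "State1D",
    "Sim1DConfig",
    "DynNoiseSpec",
    "SimResult",
    "initial_state",
    "rhs_1d",
    "simulate_1d",
    "simulate_1d_langevin",
    "cell_polarity_1d",
    "tissue_polarity_1d",
]


@dataclass
class State1D:
    """Membrane-bound protein amounts per cell edge."""

    fl: np.ndarray
    fr: np.ndarray
    dl: np.ndarray
    dr: np.ndarray

    def __post_init__(self) -> None:
        arrs = [np.asarray(a, dtype=float) for a in (self.fl, self.fr, self.dl, self.dr)]
        n = arrs[0].size
        if any(a.shape != (n,) for a in arrs):
            raise ValueError("fl, fr, dl, dr must be 1D arrays of equal length")
        if any(np.any(a < 0) for a in arrs):
            raise ValueError("membrane-bound amounts must be non-negative")
        self.fl, self.fr, self.dl, self.dr = arrs

    @property
    def n_cells(self) -> int:
        return self.fl.size

    @property
    def fm(self) -> np.ndarray:
        """Total membrane-bound Ft per cell."""
        return self.fl + self.fr

    @property
    def dm(self) -> np.ndarray:
        """Total membrane-bound Ds per cell."""
        return self.dl + self.dr

    def pack(self) -> np.ndarray:
        return np.concatenate([self.fl, self.fr, self.dl, self.dr])

    @classmethod
    def unpack(cls, y: np.ndarray, n: int) -> "State1D":
        return cls(y[:n], y[n : 2 * n], y[2 * n : 3 * n], y[3 * n :])

    def mirror(self) -> "State1D":
        """Spatial reflection of the lattice (left and right edges swap)."""
        return State1D(self.fr[::-1], self.fl[::-1], self.dr[::-1], self.dl[::-1])


@dataclass(frozen=True)
class Sim1DConfig:
    """Integration settings for the 1D model.

    ``convergence_tol`` bounds the max-norm rate of change per unit time at
    the accepted steady state; ``init_asymmetry`` seeds a small symmetry-
    breaking bias (fraction of the cell's total protein) in the initial
    membrane distribution.
    """

    n_cells: int = 500
    boundary: str = "periodic"
    dt: float = 0.01
    convergence_tol: float = 1e-8
    max_time: float = 20000.0
    max_steps: int = 5_000_000
    init_asymmetry: float = 0.01
    init_direction: str = "fixed"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.convergence_tol <= 0:
            raise ValueError("convergence_tol must be positive")
        if self.boundary not in ("periodic", "open"):
            raise ValueError("boundary must be 'periodic' or 'open'")
        if self.init_direction not in ("fixed", "random"):
            raise ValueError("init_direction must be 'fixed' or 'random'")
        if not 0 <= self.init_asymmetry <= 0.5:
            raise ValueError("init_asymmetry must lie in [0, 0.5]")


@dataclass(frozen=True)
class DynNoiseSpec:
    """Dynamic (Langevin) noise in the binding/unbinding kinetics.

    ``eta`` is the white-noise amplitude; each edge, protein, cell and time
    step receives an independent zero-mean Gaussian kick ``eta * sqrt(dt) *
    N(0, 1)``.  After the deterministic convergence time ``T`` the stochastic
    run lasts ``duration_factor * T`` and the reported state is averaged over
    the final ``tail_average_steps`` steps.
    """

    eta: float
    seed: int = 0
    n_realizations: int = 50
    duration_factor: float = 1.5
    tail_average_steps: int = 1000
    duration: Optional[float] = None

    def __post_init__(self) -> None:
        if self.eta < 0:
            raise ValueError("eta must be non-negative")


@dataclass
class SimResult:
    """Steady (or tail-averaged) state plus a convergence record."""

    state: State1D
    converged: bool
    t_final: float
    n_steps: int
    max_rate: float
    n_clamped: int = 0
    frames: Optional[List[np.ndarray]] = None
    frame_times: Optional[List[float]] = None


def initial_state(profile: ExpressionProfile, config: Sim1DConfig) -> State1D:
    """Nearly-empty membrane with a small symmetry-breaking asymmetry.

    A fraction ``init_asymmetry`` of each cell's total Ft is placed on one
    edge and the same fraction of its Ds on the opposite edge (rightward Ft
    bias by default, or a per-cell random direction under ``init_direction =
    'random'``).
    """
    n = profile.n_cells
    a = config.init_asymmetry
    fl = np.zeros(n)
    fr = np.zeros(n)
    dl = np.zeros(n)
    dr = np.zeros(n)
    if config.init_direction == "fixed":
        right = np.ones(n, dtype=bool)
    else:
        rng = np.random.default_rng(config.seed)
        right = rng.random(n) < 0.5
    fr[right] = a * profile.f_total[right]
    dl[right] = a * profile.d_total[right]
    fl[~right] = a * profile.f_total[~right]
    dr[~right] = a * profile.d_total[~right]
    return State1D(fl, fr, dl, dr)


def _neighbor_arrays(state: State1D, boundary: str) -> Tuple[np.ndarray, ...]:
    """Partner concentrations on the facing membranes.

    Returns ``(dr(i-1), dl(i+1), fr(i-1), fl(i+1))``; with open boundaries a
    missing neighbor contributes partner concentration 0, i.e. edge cells
    unbind at the full bare rate.
    """
    dr_left = np.roll(state.dr, 1)
    dl_right = np.roll(state.dl, -1)
    fr_left = np.roll(state.fr, 1)
    fl_right = np.roll(state.fl, -1)
    if boundary == "open":
        dr_left[0] = 0.0
        fr_left[0] = 0.0
        dl_right[-1] = 0.0
        fl_right[-1] = 0.0
    return dr_left, dl_right, fr_left, fl_right


def rhs_1d(
    state: State1D,
    profile: ExpressionProfile,
    params: KineticParams,
    boundary: str = "periodic",
) -> Tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Time derivatives ``(d_fl, d_fr, d_dl, d_dr)`` of the 1D model."""
    if state.n_cells != profile.n_cells:
        raise ValueError("state and profile sizes disagree")
    if any(np.any(~np.isfinite(a)) for a in (state.fl, state.fr, state.dl, state.dr)):
        raise FloatingPointError("non-finite value in state")
    gamma, k, b0, al = params.gamma, params.k, params.beta0, params.alpha
    fm, dm = state.fm, state.dm
    if profile.unlimited_pool is not None:
        bind_f = np.full(state.n_cells, al * profile.unlimited_pool)
        bind_d = bind_f
    else:
        bind_f = al * (profile.f_total - fm)
        bind_d = al * (profile.d_total - dm)
    dr_left, dl_right, fr_left, fl_right = _neighbor_arrays(state, boundary)

    def h2(c):
        return 1.0 / (1.0 + (gamma * c) ** k)

    d_fl = bind_f - b0 * state.fl * h2(dr_left)
    d_fr = bind_f - b0 * state.fr * h2(dl_right)
    d_dl = bind_d - b0 * state.dl * h2(fr_left)
    d_dr = bind_d - b0 * state.dr * h2(fl_right)
    return d_fl, d_fr, d_dl, d_dr


def _rhs_packed(y: np.ndarray, profile: ExpressionProfile, params: KineticParams, boundary: str) -> np.ndarray:
    n = profile.n_cells
    st = State1D(
        np.maximum(y[:n], 0.0),
        np.maximum(y[n : 2 * n], 0.0),
        np.maximum(y[2 * n : 3 * n], 0.0),
        np.maximum(y[3 * n :], 0.0),
    )
    return np.concatenate(rhs_1d(st, profile, params, boundary))


def simulate_1d(
    state0: State1D,
    profile: ExpressionProfile,
    params: KineticParams,
    config: Sim1DConfig,
) -> SimResult:
    """Relax the deterministic 1D model to steady state.

    Integrates with an adaptive stiff-capable solver (LSODA) in time windows
    and stops once the max-norm rate of change per unit time drops below
    ``config.convergence_tol``.  Non-convergence within ``max_time`` yields a
    flagged (not raised) result.
    """
    y = state0.pack()
    t = 0.0
    window = 50.0
    nfev = 0
    rate = float(np.max(np.abs(_rhs_packed(y, profile, params, config.boundary))))
    while rate >= config.convergence_tol and t < config.max_time:
        sol = solve_ivp(
            lambda _t, yy: _rhs_packed(yy, profile, params, config.boundary),
            (0.0, min(window, config.max_time - t)),
            y,
            method="LSODA",
            rtol=1e-9,
            atol=1e-12,
        )
        if not sol.success:
            raise RuntimeError(f"ODE solver failed: {sol.message}")
        y = sol.y[:, -1]
        t += sol.t[-1]
        nfev += sol.nfev
        window = min(window * 2, 800.0)  # grow windows: solver restarts dominate cost
        rate = float(np.max(np.abs(_rhs_packed(y, profile, params, config.boundary))))
    n = profile.n_cells
    y = np.maximum(y, 0.0)
    return SimResult(
        state=State1D.unpack(y, n),
        converged=bool(rate < config.convergence_tol),
        t_final=t,
        n_steps=nfev,
        max_rate=rate,
    )


def simulate_1d_langevin(
    state0: State1D,
    profile: ExpressionProfile,
    params: KineticParams,
    config: Sim1DConfig,
    noise: DynNoiseSpec,
    record_frames: int = 0,
) -> SimResult:
    """Euler-Maruyama integration of the 1D Langevin model.

    Drift is the deterministic right-hand side; each of the ``4 N`` membrane
    populations receives an independent additive kick ``eta * sqrt(dt) *
    N(0,1)`` per step.  Negative amounts are clamped to 0 after each step
    (counted in the result).  The run lasts ``duration_factor`` times the
    deterministic convergence time (or ``noise.duration`` when given) and the
    reported state is the average over the last ``tail_average_steps`` steps.
    When ``record_frames > 0`` that many per-cell polarity snapshots
    ``pf - pd`` are kept, evenly spaced over the run.
    """
    if noise.duration is not None:
        duration = float(noise.duration)
    else:
        det = simulate_1d(state0, profile, params, config)
        duration = noise.duration_factor * max(det.t_final, config.dt)
    dt = config.dt
    n_steps = max(int(np.ceil(duration / dt)), 1)
    tail = min(noise.tail_average_steps, n_steps)
    rng = np.random.default_rng(noise.seed)
    n = profile.n_cells
    y = state0.pack()
    acc = np.zeros_like(y)
    n_clamped = 0
    frames: List[np.ndarray] = []
    frame_times: List[float] = []
    record_every = max(n_steps // record_frames, 1) if record_frames else 0
    sqdt = np.sqrt(dt)
    for step in range(1, n_steps + 1):
        drift = _rhs_packed(y, profile, params, config.boundary)
        y = y + drift * dt + noise.eta * sqdt * rng.standard_normal(y.size)
        neg = y < 0
        n_clamped += int(np.count_nonzero(neg))
        np.maximum(y, 0.0, out=y)
        if step > n_steps - tail:
            acc += y
        if record_every and step % record_every == 0:
            st = State1D.unpack(y, n)
            pf, pd_ = cell_polarity_1d(st)
            frames.append(pf - pd_)
            frame_times.append(step * dt)
    mean_y = acc / tail
    final_rate = float(np.max(np.abs(_rhs_packed(mean_y, profile, params, config.boundary))))
    return SimResult(
        state=State1D.unpack(np.maximum(mean_y, 0.0), n),
        converged=True,
        t_final=n_steps * dt,
        n_steps=n_steps,
        max_rate=final_rate,
        n_clamped=n_clamped,
        frames=frames or None,
        frame_times=frame_times or None,
    )


def cell_polarity_1d(state: State1D) -> Tuple[np.ndarray, np.ndarray]:
    """Per-cell polarity ``(pf, pd) = (fr - fl, dr - dl)``."""
    return state.fr - state.fl, state.dr - state.dl


def tissue_polarity_1d(state: State1D) -> float:
    """Tissue polarity ``p = <pf(i) - pd(i)>`` averaged over all cells."""
    pf, pd_ = cell_polarity_1d(state)
    return float(np.mean(pf - pd_))
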