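"""Two-dimensional hexagonal-lattice model.

Cells are regular hexagons; each cell's membrane is discretized into six
angular bins facing its six neighbors, at angles ``theta_i = 0, pi/3, ...,
5*pi/3``.  A membrane-bound protein in bin ``theta_i`` is stabilized by its
heterodimer partner in the facing bin ``theta_i + pi`` of the neighbor across
that edge.  Optionally the membrane-bound pools diffuse along the angular
coordinate with coefficient ``d_theta``.

Cells are stored in axial coordinates ``(i, j)`` with centers at
``i*(1, 0) + j*(1/2, sqrt(3)/2)`` (unit cell-center spacing), so the neighbor
across bin ``b`` lies at a fixed axial offset and sees the shared edge at bin
``(b + 3) % 6``.

Integration is fixed-step Euler (deterministic) or Euler-Maruyama with
independent additive noise per bin (stochastic), as in the 1D model.  Cell
polarity is the vector first moment of the bin distribution,
``pf = sum_i f(theta_i) * (cos theta_i, sin theta_i)``.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import cached_property
from typing import List, Optional, Tuple

import numpy as np

from .expression import ExpressionProfile
from .kinetics import KineticParams
from .lattice1d import DynNoiseSpec

__all__ = [
    "HexLattice",
    "Sim2DConfig",
    "State2D",
    "Sim2DResult",
    "THETA",
    "EDGE_VECTORS",
    "hex_neighbors",
    "initial_state_2d",
    "rhs_2d",
    "simulate_2d",
    "cell_polarity_2d",
    "tissue_polarity_2d",
]

THETA = np.arange(6) * np.pi / 3
EDGE_VECTORS = np.column_stack([np.cos(THETA), np.sin(THETA)])
# axial offsets of the neighbor across each angular bin
_OFFSETS = np.array([(1, 0), (0, 1), (-1, 1), (-1, 0), (0, -1), (1, -1)])
_BASIS = np.array([[1.0, 0.0], [0.5, np.sqrt(3) / 2]])


@dataclass(frozen=True)
class HexLattice:
    """A ``nx`` x ``ny`` rhombus of hexagonal cells (axial storage)."""

    nx: int = 50
    ny: int = 50
    boundary: str = "open"

    def __post_init__(self) -> None:
        if self.nx < 1 or self.ny < 1:
            raise ValueError("lattice dimensions must be >= 1")
        if self.boundary not in ("periodic", "open"):
            raise ValueError("boundary must be 'periodic' or 'open'")

    @property
    def n_cells(self) -> int:
        return self.nx * self.ny

    def index(self, i: int, j: int) -> int:
        return i + self.nx * j

    def axial(self, cell: int) -> Tuple[int, int]:
        return cell % self.nx, cell // self.nx

    @cached_property
    def centers(self) -> np.ndarray:
        """Cell-center coordinates, shape (n_cells, 2), unit spacing."""
        i, j = np.meshgrid(np.arange(self.nx), np.arange(self.ny), indexing="xy")
        ij = np.column_stack([i.ravel(), j.ravel()])
        return ij @ _BASIS

    @cached_property
    def neighbors(self) -> np.ndarray:
        """Neighbor cell index across each bin, shape (n_cells, 6); -1 if the
        neighbor is outside an open lattice."""
        nbr = np.empty((self.n_cells, 6), dtype=int)
        for c in range(self.n_cells):
            i, j = self.axial(c)
            for b, (di, dj) in enumerate(_OFFSETS):
                ii, jj = i + di, j + dj
                if self.boundary == "periodic":
                    nbr[c, b] = self.index(ii % self.nx, jj % self.ny)
                elif 0 <= ii < self.nx and 0 <= jj < self.ny:
                    nbr[c, b] = self.index(ii, jj)
                else:
                    nbr[c, b] = -1
        return nbr


def hex_neighbors(lattice: HexLattice, cell: int) -> List[Tuple[Optional[int], int, int]]:
    """The six ``(neighbor cell or None, own bin, facing bin)`` triples of a
    cell; the facing bin is always ``(own bin + 3) % 6``."""
    if not 0 <= cell < lattice.n_cells:
        raise IndexError(f"cell {cell} outside lattice of {lattice.n_cells} cells")
    out = []
    for b in range(6):
        n = int(lattice.neighbors[cell, b])
        out.append((n if n >= 0 else None, b, (b + 3) % 6))
    return out


@dataclass
class State2D:
    """Membrane-bound amounts per cell and angular bin, shape (n_cells, 6)."""

    f: np.ndarray
    d: np.ndarray

    def __post_init__(self) -> None:
        f = np.asarray(self.f, dtype=float)
        d = np.asarray(self.d, dtype=float)
        if f.ndim != 2 or f.shape[1] != 6 or d.shape != f.shape:
            raise ValueError("f and d must both have shape (n_cells, 6)")
        if np.any(f < 0) or np.any(d < 0):
            raise ValueError("membrane-bound amounts must be non-negative")
        self.f, self.d = f, d

    @property
    def n_cells(self) -> int:
        return self.f.shape[0]

    @property
    def fm(self) -> np.ndarray:
        return self.f.sum(axis=1)

    @property
    def dm(self) -> np.ndarray:
        return self.d.sum(axis=1)


@dataclass(frozen=True)
class Sim2DConfig:
    """Fixed-step Euler settings for the 2D model."""

    dt: float = 0.01
    convergence_tol: float = 1e-8
    max_steps: int = 2_000_000
    init_asymmetry: float = 0.01
    init_direction: str = "fixed"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.convergence_tol <= 0:
            raise ValueError("convergence_tol must be positive")
        if not 0 <= self.init_asymmetry <= 0.5:
            raise ValueError("init_asymmetry must lie in [0, 0.5]")
        if self.init_direction not in ("fixed", "random"):
            raise ValueError("init_direction must be 'fixed' or 'random'")


@dataclass
class Sim2DResult:
    state: State2D
    converged: bool
    t_final: float
    n_steps: int
    max_rate: float
    n_clamped: int = 0
    dt_used: float = 0.0
    frames: Optional[List[np.ndarray]] = None
    frame_times: Optional[List[float]] = None


def initial_state_2d(profile: ExpressionProfile, lattice: HexLattice, config: Sim2DConfig) -> State2D:
    """Nearly-empty membrane with a small symmetry-breaking asymmetry: a
    fraction of each cell's Ft in one bin and of its Ds in the opposite bin
    (bin 0 / bin 3 by default, or a per-cell random bin)."""
    n = lattice.n_cells
    f = np.zeros((n, 6))
    d = np.zeros((n, 6))
    a = config.init_asymmetry
    if a > 0:
        if config.init_direction == "fixed":
            bins = np.zeros(n, dtype=int)
        else:
            bins = np.random.default_rng(config.seed).integers(0, 6, size=n)
        idx = np.arange(n)
        f[idx, bins] = a * profile.f_total
        d[idx, (bins + 3) % 6] = a * profile.d_total
    return State2D(f, d)


def _facing(arr: np.ndarray, lattice: HexLattice) -> np.ndarray:
    """Partner concentration on the facing bin of the neighbor across each
    edge; 0 where the neighbor is missing (open boundary)."""
    nbr = lattice.neighbors
    facing_bins = (np.arange(6) + 3) % 6
    out = arr[np.maximum(nbr, 0), facing_bins[None, :]]
    out[nbr < 0] = 0.0
    return out


def rhs_2d(
    state: State2D,
    profile: ExpressionProfile,
    params: KineticParams,
    lattice: HexLattice,
    active_bins: Optional[np.ndarray] = None,
) -> Tuple[np.ndarray, np.ndarray]:
    """Time derivatives ``(df, dd)`` of the hexagonal model.

    Per cell and bin: binding of the free pool, minus Hill-stabilized
    unbinding against the facing neighbor bin, plus the discrete angular
    Laplacian of membrane diffusion.  ``active_bins`` (boolean mask of the 6
    bins) freezes the complementary bins at zero so a single row with only the
    left/right couplings reproduces the 1D model exactly.
    """
    if state.n_cells != lattice.n_cells or state.n_cells != profile.n_cells:
        raise ValueError("state, profile and lattice sizes disagree")
    if np.any(~np.isfinite(state.f)) or np.any(~np.isfinite(state.d)):
        raise FloatingPointError("non-finite value in state")
    gamma, k, b0, al = params.gamma, params.k, params.beta0, params.alpha
    fm, dm = state.fm, state.dm
    if profile.unlimited_pool is not None:
        bind_f = np.full(state.n_cells, al * profile.unlimited_pool)
        bind_d = bind_f
    else:
        bind_f = al * (profile.f_total - fm)
        bind_d = al * (profile.d_total - dm)

    def h2(c):
        return 1.0 / (1.0 + (gamma * c) ** k)

    df = bind_f[:, None] - b0 * state.f * h2(_facing(state.d, lattice))
    dd = bind_d[:, None] - b0 * state.d * h2(_facing(state.f, lattice))
    if params.d_theta > 0:
        h = np.pi / 3
        df += params.d_theta * (
            np.roll(state.f, 1, axis=1) + np.roll(state.f, -1, axis=1) - 2 * state.f
        ) / h**2
        dd += params.d_theta * (
            np.roll(state.d, 1, axis=1) + np.roll(state.d, -1, axis=1) - 2 * state.d
        ) / h**2
    if active_bins is not None:
        mask = np.asarray(active_bins, dtype=bool)
        if mask.shape != (6,):
            raise ValueError("active_bins must be a boolean mask of the 6 bins")
        df[:, ~mask] = 0.0
        dd[:, ~mask] = 0.0
    return df, dd


def simulate_2d(
    state0: State2D,
    profile: ExpressionProfile,
    params: KineticParams,
    lattice: HexLattice,
    config: Sim2DConfig,
    noise: Optional[DynNoiseSpec] = None,
    record_frames: int = 0,
    active_bins: Optional[np.ndarray] = None,
) -> Sim2DResult:
    """Fixed-step (Euler / Euler-Maruyama) integration of the 2D model.

    Deterministic runs stop when the max-norm rate of change per unit time
    drops below ``config.convergence_tol``; stochastic runs last
    ``duration_factor`` times the deterministic convergence time (or
    ``noise.duration``) and report the tail-averaged state.  On divergence the
    step is halved once and the run restarted; a second divergence flags the
    result.  ``record_frames`` evenly-spaced per-cell polarity snapshots
    ``pf - pd`` (shape ``(n_cells, 2)``) are kept when requested.
    """
    eta = noise.eta if noise is not None else 0.0
    if noise is not None and eta > 0:
        if noise.duration is not None:
            duration = float(noise.duration)
        else:
            det = simulate_2d(state0, profile, params, lattice, config,
                              active_bins=active_bins)
            duration = noise.duration_factor * max(det.t_final, config.dt)
    else:
        duration = None

    dt = config.dt
    for _attempt in range(2):
        result = _euler_loop(state0, profile, params, lattice, config, dt,
                             noise, duration, record_frames, active_bins)
        if result is not None:
            return result
        dt /= 2.0  # diverged: halve the step once and retry
    # diverged even after halving dt: flag, do not raise
    return Sim2DResult(
        state=State2D(state0.f.copy(), state0.d.copy()),
        converged=False,
        t_final=0.0,
        n_steps=0,
        max_rate=np.inf,
        dt_used=dt,
    )


def _euler_loop(state0, profile, params, lattice, config, dt, noise, duration,
                record_frames, active_bins) -> Optional[Sim2DResult]:
    eta = noise.eta if noise is not None else 0.0
    stochastic = eta > 0
    if stochastic:
        n_steps = max(int(np.ceil(duration / dt)), 1)
        tail = min(noise.tail_average_steps, n_steps)
        rng = np.random.default_rng(noise.seed)
    else:
        n_steps = config.max_steps
        tail = 0
    f = state0.f.copy()
    d = state0.d.copy()
    acc_f = np.zeros_like(f)
    acc_d = np.zeros_like(d)
    n_clamped = 0
    frames: List[np.ndarray] = []
    frame_times: List[float] = []
    record_every = max(n_steps // record_frames, 1) if record_frames else 0
    sqdt = np.sqrt(dt)
    converged = False
    step = 0
    rate = np.inf
    while step < n_steps:
        step += 1
        df, dd = _rhs_raw(f, d, profile, params, lattice, active_bins)
        if not stochastic:
            rate = max(float(np.max(np.abs(df))), float(np.max(np.abs(dd))))
            if rate < config.convergence_tol:
                converged = True
                step -= 1
                break
        f = f + df * dt
        d = d + dd * dt
        if stochastic:
            f = f + eta * sqdt * rng.standard_normal(f.shape)
            d = d + eta * sqdt * rng.standard_normal(d.shape)
            if active_bins is not None:
                mask = np.asarray(active_bins, dtype=bool)
                f[:, ~mask] = 0.0
                d[:, ~mask] = 0.0
        neg = (f < 0).sum() + (d < 0).sum()
        n_clamped += int(neg)
        np.maximum(f, 0.0, out=f)
        np.maximum(d, 0.0, out=d)
        if not np.isfinite(f).all() or not np.isfinite(d).all() or f.max() > 1e9:
            return None  # diverged
        if stochastic and step > n_steps - tail:
            acc_f += f
            acc_d += d
        if record_every and step % record_every == 0:
            pf = f @ EDGE_VECTORS
            pd_ = d @ EDGE_VECTORS
            frames.append(pf - pd_)
            frame_times.append(step * dt)
    if stochastic:
        f, d = acc_f / tail, acc_d / tail
        converged = True
        df, dd = _rhs_raw(f, d, profile, params, lattice, active_bins)
        rate = max(float(np.max(np.abs(df))), float(np.max(np.abs(dd))))
    return Sim2DResult(
        state=State2D(np.maximum(f, 0.0), np.maximum(d, 0.0)),
        converged=converged,
        t_final=step * dt,
        n_steps=step,
        max_rate=float(rate),
        n_clamped=n_clamped,
        dt_used=dt,
        frames=frames or None,
        frame_times=frame_times or None,
    )


def _rhs_raw(f, d, profile, params, lattice, active_bins):
    st = State2D.__new__(State2D)
    st.f = f
    st.d = d
    return rhs_2d(st, profile, params, lattice, active_bins)


def cell_polarity_2d(state: State2D) -> Tuple[np.ndarray, np.ndarray]:
    """Per-cell polarity vectors ``(pf, pd)``, each of shape (n_cells, 2):
    the bin distribution's first moment against the six edge directions."""
    return state.f @ EDGE_VECTORS, state.d @ EDGE_VECTORS


def tissue_polarity_2d(state: State2D) -> np.ndarray:
    """Tissue polarity vector ``p = <pf(x) - pd(x)>`` averaged over cells."""
    pf, pd_ = cell_polarity_2d(state)
    return np.asarray((pf - pd_).mean(axis=0))
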