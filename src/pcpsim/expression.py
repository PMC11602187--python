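"""Per-cell total protein expression profiles.

A profile holds the total (cytoplasmic + membrane-bound) amounts of Ft and Ds
per cell, ``f_total`` and ``d_total``, on either a 1D row of cells or a 2D
hexagonal lattice.  Profiles are built by composing constructors:

uniform -> linear gradient -> quenched (static) noise -> clone override

Quenched noise models frozen cell-to-cell variability in expression; a clone
models a contiguous region where one protein is deleted (level 0) or
up-regulated (level above ambient).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionProfile",
    "GradientSpec",
    "StaticNoiseSpec",
    "CloneSpec",
    "uniform_profile",
    "gradient_profile",
    "apply_static_noise",
    "apply_clone",
    "disc_mask",
]


def _cell_positions(lattice) -> np.ndarray:
    """x-coordinate of every cell center, in cell-diameter units."""
    if isinstance(lattice, (int, np.integer)):
        return np.arange(int(lattice), dtype=float)
    return np.asarray(lattice.centers[:, 0], dtype=float)


def _n_cells(lattice) -> int:
    if isinstance(lattice, (int, np.integer)):
        if lattice < 1:
            raise ValueError("lattice size must be >= 1")
        return int(lattice)
    return int(lattice.n_cells)


@dataclass(frozen=True)
class ExpressionProfile:
    """Total Ft and Ds levels per cell (concentration units ``1/gamma``).

    ``lattice`` is either the number of cells of a 1D row or a
    :class:`~pcpsim.lattice2d.HexLattice`.  ``unlimited_pool``, when set,
    switches the binding term of the dynamics from pool depletion
    ``alpha * (f_total - f_membrane)`` to the constant ``alpha * unlimited_pool``
    for both proteins (a control ruling out finite-pool feedback).
    """

    f_total: np.ndarray
    d_total: np.ndarray
    lattice: Union[int, object]
    unlimited_pool: Optional[float] = None

    def __post_init__(self) -> None:
        ft = np.atleast_1d(np.asarray(self.f_total, dtype=float))
        dt = np.atleast_1d(np.asarray(self.d_total, dtype=float))
        n = _n_cells(self.lattice)
        if ft.shape != (n,) or dt.shape != (n,):
            raise ValueError(
                f"profile shape mismatch: expected ({n},), got {ft.shape} / {dt.shape}"
            )
        if np.any(ft < 0) or np.any(dt < 0):
            raise ValueError("total protein levels must be non-negative")
        if self.unlimited_pool is not None and self.unlimited_pool < 0:
            raise ValueError("unlimited_pool must be non-negative")
        object.__setattr__(self, "f_total", ft)
        object.__setattr__(self, "d_total", dt)

    @property
    def n_cells(self) -> int:
        return self.f_total.size

    @property
    def is_1d(self) -> bool:
        return isinstance(self.lattice, (int, np.integer))

    def to_frame(self) -> pd.DataFrame:
        """Tabular form with columns (cell, x[, y], fT, dT)."""
        data = {"cell": np.arange(self.n_cells)}
        if self.is_1d:
            data["x"] = np.arange(self.n_cells, dtype=float)
        else:
            data["x"] = self.lattice.centers[:, 0]
            data["y"] = self.lattice.centers[:, 1]
        data["fT"] = self.f_total
        data["dT"] = self.d_total
        return pd.DataFrame(data)


@dataclass(frozen=True)
class GradientSpec:
    """Linear expression gradient ``f_total(i) = rho + epsilon * (x_i - x_ref)``.

    ``epsilon`` is the steepness per cell diameter (any sign); the profile must
    stay non-negative everywhere.  ``reference_index`` is the cell at which the
    level equals ``rho`` (default: leftmost cell / column, x = 0).
    """

    rho: float
    epsilon: float
    axis: str = "x"
    reference_index: int = 0

    def __post_init__(self) -> None:
        if self.rho < 0:
            raise ValueError("rho must be non-negative")
        if self.axis != "x":
            raise ValueError("gradients vary along the lattice x-axis only")


@dataclass(frozen=True)
class StaticNoiseSpec:
    """Quenched cell-to-cell noise: independent N(0, S^2) offsets per cell and
    per protein, frozen in time."""

    S: float
    seed: int = 0

    def __post_init__(self) -> None:
        if self.S < 0:
            raise ValueError("noise amplitude S must be non-negative")


@dataclass(frozen=True)
class CloneSpec:
    """Override one protein's total level inside a set of cells.

    ``value = 0`` is a deletion clone; ``value`` above ambient an
    up-regulation clone.
    """

    mask: Sequence[int] = field(default_factory=list)
    protein: str = "ft"
    value: float = 0.0

    def __post_init__(self) -> None:
        if self.protein.lower() not in ("ft", "ds"):
            raise ValueError(f"protein must be 'ft' or 'ds', got {self.protein!r}")
        if self.value < 0:
            raise ValueError("clone override value must be non-negative")


def uniform_profile(lattice, rho_f: float, rho_d: Optional[float] = None) -> ExpressionProfile:
    """Constant expression: every cell holds ``rho_f`` Ft and ``rho_d`` Ds."""
    if rho_d is None:
        rho_d = rho_f
    if rho_f < 0 or rho_d < 0:
        raise ValueError("total protein levels must be non-negative")
    n = _n_cells(lattice)
    return ExpressionProfile(np.full(n, float(rho_f)), np.full(n, float(rho_d)), lattice)


def gradient_profile(lattice, spec: GradientSpec, uniform_other: Optional[float] = None) -> ExpressionProfile:
    """Linear Ft gradient along x with uniform Ds.

    ``f_total(i) = rho + epsilon * (x_i - x_ref)``; Ds is uniform at
    ``uniform_other`` (default ``rho``).  Raises if any cell would get a
    negative level, naming the offending cell.
    """
    x = _cell_positions(lattice)
    n = x.size
    if not 0 <= spec.reference_index < n:
        raise ValueError(f"reference_index {spec.reference_index} outside lattice of {n} cells")
    ft = spec.rho + spec.epsilon * (x - x[spec.reference_index])
    if np.any(ft < 0):
        bad = int(np.argmin(ft))
        raise ValueError(
            f"gradient drives f_total negative at cell {bad} "
            f"(level {ft[bad]:.4g}); choose another reference_index or epsilon"
        )
    rho_d = spec.rho if uniform_other is None else float(uniform_other)
    if rho_d < 0:
        raise ValueError("uniform_other must be non-negative")
    return ExpressionProfile(ft, np.full(n, rho_d), lattice)


def apply_static_noise(profile: ExpressionProfile, spec: StaticNoiseSpec) -> ExpressionProfile:
    """Add quenched N(0, S^2) offsets, independently per cell and per protein.

    Negative resulting totals are clamped to 0 (a rare-event guard: the model
    assumes S small relative to the mean level).  Deterministic under a fixed
    seed.
    """
    mean_level = float(np.mean(np.concatenate([profile.f_total, profile.d_total])))
    if mean_level > 0 and spec.S > 0.1 * mean_level:
        warnings.warn(
            f"static noise amplitude S={spec.S:g} exceeds 10% of the mean "
            f"expression level {mean_level:g}; the small-noise assumption is violated",
            stacklevel=2,
        )
    rng = np.random.default_rng(spec.seed)
    n = profile.n_cells
    ft = profile.f_total + spec.S * rng.standard_normal(n)
    dt = profile.d_total + spec.S * rng.standard_normal(n)
    n_clamped = int(np.sum(ft < 0) + np.sum(dt < 0))
    if n_clamped:
        warnings.warn(f"clamped {n_clamped} negative noisy totals to 0", stacklevel=2)
    return replace(profile, f_total=np.maximum(ft, 0.0), d_total=np.maximum(dt, 0.0))


def apply_clone(profile: ExpressionProfile, spec: CloneSpec) -> ExpressionProfile:
    """Override the clone protein's total level inside the masked cells."""
    mask = np.asarray(list(spec.mask), dtype=int)
    if mask.size == 0:
        warnings.warn("clone mask is empty; profile unchanged", stacklevel=2)
        return profile
    n = profile.n_cells
    if np.any(mask < 0) or np.any(mask >= n):
        raise ValueError("clone mask contains indices outside the lattice")
    if spec.protein.lower() == "ft":
        ft = profile.f_total.copy()
        ft[mask] = spec.value
        return replace(profile, f_total=ft)
    dt = profile.d_total.copy()
    dt[mask] = spec.value
    return replace(profile, d_total=dt)


def disc_mask(lattice, center: Optional[Sequence[float]] = None, radius: float = 5.0) -> np.ndarray:
    """Cell indices within Euclidean distance ``radius`` of ``center``.

    ``center`` defaults to the lattice centroid.  Works for 2D lattices (cell
    centers) and 1D rows (interval of cells).
    """
    if isinstance(lattice, (int, np.integer)):
        pts = np.arange(int(lattice), dtype=float)[:, None]
    else:
        pts = np.asarray(lattice.centers, dtype=float)
    c = pts.mean(axis=0) if center is None else np.asarray(center, dtype=float)
    dist = np.linalg.norm(pts - c, axis=1)
    return np.flatnonzero(dist <= radius)
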