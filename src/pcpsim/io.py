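"""Delimited-text tables for states, profiles and polarity fields.

All outputs are tab-separated tables with a header row, plus JSON sidecars
for run metadata, so every experiment can be re-analyzed from its saved
files.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, Union

import numpy as np
import pandas as pd

from .expression import ExpressionProfile
from .lattice1d import State1D, cell_polarity_1d
from .lattice2d import THETA, HexLattice, State2D, cell_polarity_2d

__all__ = [
    "write_profile",
    "read_profile",
    "write_state_1d",
    "read_state_1d",
    "write_state_2d",
    "read_state_2d",
    "write_polarity_2d",
    "write_metadata",
    "read_metadata",
]

_SEP = "\t"


def write_profile(profile: ExpressionProfile, path: Union[str, Path]) -> None:
    profile.to_frame().to_csv(path, sep=_SEP, index=False)


def read_profile(path: Union[str, Path], lattice=None) -> ExpressionProfile:
    """Read a profile table; ``lattice`` (int or HexLattice) defaults to a 1D
    row of as many cells as the table has."""
    df = pd.read_csv(path, sep=_SEP)
    if lattice is None:
        lattice = len(df)
    return ExpressionProfile(df["fT"].to_numpy(), df["dT"].to_numpy(), lattice)


def write_state_1d(state: State1D, path: Union[str, Path]) -> None:
    pf, pd_ = cell_polarity_1d(state)
    pd.DataFrame(
        {
            "cell": np.arange(state.n_cells),
            "fl": state.fl,
            "fr": state.fr,
            "dl": state.dl,
            "dr": state.dr,
            "pf": pf,
            "pd": pd_,
        }
    ).to_csv(path, sep=_SEP, index=False)


def read_state_1d(path: Union[str, Path]) -> State1D:
    df = pd.read_csv(path, sep=_SEP)
    return State1D(
        df["fl"].to_numpy(), df["fr"].to_numpy(), df["dl"].to_numpy(), df["dr"].to_numpy()
    )


def write_state_2d(state: State2D, lattice: HexLattice, path: Union[str, Path]) -> None:
    """Long-format state table with one row per (cell, bin)."""
    n = state.n_cells
    cells = np.repeat(np.arange(n), 6)
    bins = np.tile(np.arange(6), n)
    cols = cells % lattice.nx
    rows = cells // lattice.nx
    pd.DataFrame(
        {
            "col": cols,
            "row": rows,
            "bin": bins,
            "theta": THETA[bins],
            "f": state.f.ravel(),
            "d": state.d.ravel(),
        }
    ).to_csv(path, sep=_SEP, index=False)


def read_state_2d(path: Union[str, Path]) -> State2D:
    df = pd.read_csv(path, sep=_SEP)
    n = df["col"].size // 6
    return State2D(df["f"].to_numpy().reshape(n, 6), df["d"].to_numpy().reshape(n, 6))


def write_polarity_2d(state: State2D, lattice: HexLattice, path: Union[str, Path]) -> None:
    pf, pd_ = cell_polarity_2d(state)
    p = pf - pd_
    cells = np.arange(state.n_cells)
    pd.DataFrame(
        {
            "col": cells % lattice.nx,
            "row": cells // lattice.nx,
            "x_center": lattice.centers[:, 0],
            "y_center": lattice.centers[:, 1],
            "pfx": pf[:, 0],
            "pfy": pf[:, 1],
            "pdx": pd_[:, 0],
            "pdy": pd_[:, 1],
            "px": p[:, 0],
            "py": p[:, 1],
        }
    ).to_csv(path, sep=_SEP, index=False)


def write_metadata(meta: Dict, path: Union[str, Path]) -> None:
    Path(path).write_text(json.dumps(meta, indent=2, default=_json_default) + "\n")


def read_metadata(path: Union[str, Path]) -> Dict:
    return json.loads(Path(path).read_text())


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.bool_, bool)):
        return bool(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")
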