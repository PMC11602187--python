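"""Named experiment presets, one per figure-class experiment of the model.

Each preset is a complete configuration for :func:`pcpsim.config.run_experiment`,
scaled so it runs in minutes on one CPU.  The 1D critical concentration at
binding rate ``alpha`` is ``2 + 1/(2*alpha)``; on the hexagonal lattice the
membrane is split over six bins instead of two, which raises the spontaneous
threshold to about ``6 + 1/(2*alpha)``, so the 2D uniform/noise presets use
correspondingly higher total concentrations.
"""

from __future__ import annotations

import copy
from typing import Dict

__all__ = ["presets", "get_preset"]

_PRESETS: Dict[str, Dict] = {
    # spontaneous polarization phase diagram (reduced alpha x rho grid)
    "fig2-phase-diagram": {
        "name": "fig2-phase-diagram",
        "sweep": {
            "alpha_grid": [0.5, 1.0, 2.0],
            "rho_grid": [2.0, 2.2, 2.4, 2.6, 2.8, 3.0, 3.2],
            "n_cells": 50,
        },
    },
    # quenched expression noise fragments 1D polarity into domains
    "fig3-static-noise-1d": {
        "name": "fig3-static-noise-1d",
        "lattice": {"dimension": 1, "n_cells": 100, "boundary": "periodic"},
        "expression": {"rho_f": 4.0, "static_noise": {"S": 1e-2}},
        "simulation": {"init_direction": "random", "max_time": 2000.0},
        "analysis": {"statistics": ["tissue_polarity", "cell_polarity"]},
    },
    # dynamic (kinetic) noise counterpart
    "fig3-dynamic-noise-1d": {
        "name": "fig3-dynamic-noise-1d",
        "lattice": {"dimension": 1, "n_cells": 100, "boundary": "periodic"},
        "expression": {"rho_f": 4.0},
        "simulation": {"kind": "langevin", "eta": 1e-2, "duration": 150.0,
                       "init_direction": "random"},
        "analysis": {"statistics": ["tissue_polarity", "cell_polarity"]},
    },
    # uniform 2D lattice polarizes above the (2D) threshold
    "fig4-2d-uniform": {
        "name": "fig4-2d-uniform",
        "lattice": {"dimension": 2, "nx": 10, "ny": 10, "boundary": "periodic"},
        "expression": {"rho_f": 8.0},
        "simulation": {"dt": 0.05},
        "analysis": {"statistics": ["tissue_polarity", "curl_divergence"]},
    },
    # correlation length under quenched noise (reduced lattice)
    "fig5-correlation-2d": {
        "name": "fig5-correlation-2d",
        "lattice": {"dimension": 2, "nx": 15, "ny": 15, "boundary": "open"},
        "expression": {"rho_f": 7.5, "static_noise": {"S": 1e-2}},
        "simulation": {"dt": 0.05, "init_asymmetry": 0.0, "max_steps": 100000,
                       "record_frames": 50},
        "analysis": {"statistics": ["tissue_polarity", "correlation_length"]},
    },
    # weak Ft gradient polarizes a below-threshold tissue
    "fig6-gradient-1d": {
        "name": "fig6-gradient-1d",
        "lattice": {"dimension": 1, "n_cells": 100, "boundary": "open"},
        "expression": {"rho_f": 1.5, "gradient": {"epsilon": 0.01}},
        "analysis": {"statistics": ["tissue_polarity", "cell_polarity"]},
    },
    # gradient vs dynamic noise
    "fig7-gradient-noise-1d": {
        "name": "fig7-gradient-noise-1d",
        "lattice": {"dimension": 1, "n_cells": 100, "boundary": "open"},
        "expression": {"rho_f": 1.5, "gradient": {"epsilon": 0.01}},
        "simulation": {"kind": "langevin", "eta": 1e-3, "duration": 150.0},
        "analysis": {"statistics": ["tissue_polarity", "cell_polarity"]},
    },
    # half-tissue Ft deletion: boundary-layer polarity decay
    "fig8-deletion-1d": {
        "name": "fig8-deletion-1d",
        "lattice": {"dimension": 1, "n_cells": 500, "boundary": "open"},
        "expression": {"rho_f": 4.0, "clone": {"protein": "ft", "value": 0.0,
                                               "region": "left_half"}},
        "simulation": {"max_time": 3000.0},
        "analysis": {"statistics": ["tissue_polarity", "decay_fit"],
                     "decay_boundary": 250},
    },
    # circular Ft deletion clone: inward radial polarity
    "fig9-clone-2d": {
        "name": "fig9-clone-2d",
        "lattice": {"dimension": 2, "nx": 20, "ny": 20, "boundary": "open"},
        "expression": {"rho_f": 4.0, "clone": {"protein": "ft", "value": 0.0,
                                               "region": "disc", "radius": 3.5}},
        "simulation": {"dt": 0.05, "init_asymmetry": 0.0},
        "analysis": {"statistics": ["tissue_polarity", "radial_polarity"]},
    },
    # clone + gradient: domineering non-autonomy
    "fig10-clone-gradient-2d": {
        "name": "fig10-clone-gradient-2d",
        "lattice": {"dimension": 2, "nx": 20, "ny": 20, "boundary": "open"},
        "expression": {
            "rho_f": 4.0,
            "gradient": {"epsilon": 0.05},
            "clone": {"protein": "ft", "value": 0.0, "region": "disc", "radius": 3.5},
        },
        "simulation": {"dt": 0.05, "init_asymmetry": 0.0},
        "analysis": {"statistics": ["tissue_polarity", "radial_polarity"]},
    },
}


def presets() -> Dict[str, Dict]:
    """The catalogue of named experiment presets (deep copies)."""
    return copy.deepcopy(_PRESETS)


def get_preset(name: str) -> Dict:
    try:
        return copy.deepcopy(_PRESETS[name])
    except KeyError:
        raise KeyError(
            f"unknown preset {name!r}; available: {', '.join(sorted(_PRESETS))}"
        ) from None
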