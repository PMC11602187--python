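"""Structured experiment configuration and the experiment runner.

An experiment is described by a nested mapping (usually a YAML file) with
sections ``model``, ``lattice``, ``expression``, ``simulation``, ``analysis``,
``sweep`` and ``output``.  Validation is strict: unknown keys are rejected
before any computation, and every run writes back the fully resolved
configuration so it can be re-run verbatim.
"""

from __future__ import annotations

import copy
import json
import time
from pathlib import Path
from typing import Dict

import numpy as np
import yaml

from . import analysis as an
from . import io as pio
from .expression import (
    CloneSpec,
    GradientSpec,
    StaticNoiseSpec,
    apply_clone,
    apply_static_noise,
    disc_mask,
    gradient_profile,
    uniform_profile,
)
from .kinetics import KineticParams
from .lattice1d import (
    DynNoiseSpec,
    Sim1DConfig,
    cell_polarity_1d,
    initial_state,
    simulate_1d,
    simulate_1d_langevin,
    tissue_polarity_1d,
)
from .lattice2d import (
    HexLattice,
    Sim2DConfig,
    cell_polarity_2d,
    initial_state_2d,
    simulate_2d,
    tissue_polarity_2d,
)

__all__ = ["DEFAULT_CONFIG", "validate_config", "resolve_config", "run_experiment"]

DEFAULT_CONFIG: Dict = {
    "name": "experiment",
    "seed": 0,
    "model": {"alpha": 1.0, "beta0": 1.0, "gamma": 1.0, "k": 2, "d_theta": 0.0},
    "lattice": {"dimension": 1, "n_cells": 500, "nx": 50, "ny": 50, "boundary": "periodic"},
    "expression": {
        "rho_f": 3.0,
        "rho_d": None,
        "gradient": None,       # {epsilon, reference_index}
        "static_noise": None,   # {S}
        "clone": None,          # {protein, value, region: left_half|disc, radius, center}
        "unlimited_pool": None,
    },
    "simulation": {
        "kind": "deterministic",  # or "langevin"
        "dt": 0.01,
        "convergence_tol": 1e-8,
        "max_time": 20000.0,
        "max_steps": 2_000_000,
        "init_asymmetry": 0.01,
        "init_direction": "fixed",
        "eta": 0.0,
        "duration_factor": 1.5,
        "duration": None,
        "tail_average_steps": 1000,
        "record_frames": 0,
    },
    "analysis": {
        "statistics": ["tissue_polarity"],
        "decay_boundary": None,
        "decay_far_field": True,
        "clone_center": None,
        "correlation_bin_width": 1.0,
    },
    "sweep": None,  # {alpha_grid, rho_grid, n_cells, threshold}
    "output": {"formats": ["tsv"]},
}

_KNOWN_STATS = {
    "tissue_polarity",
    "cell_polarity",
    "correlation_length",
    "decay_fit",
    "radial_polarity",
    "curl_divergence",
}


def _check_keys(section: Dict, template: Dict, path: str) -> None:
    unknown = set(section) - set(template)
    if unknown:
        raise ValueError(f"unknown configuration key(s) {sorted(unknown)} in section '{path}'")


def validate_config(config: Dict) -> None:
    """Reject unknown keys and structurally invalid sections."""
    _check_keys(config, DEFAULT_CONFIG, "<root>")
    for sec in ("model", "lattice", "simulation", "analysis", "output"):
        if sec in config and config[sec] is not None:
            if not isinstance(config[sec], dict):
                raise ValueError(f"section '{sec}' must be a mapping")
            _check_keys(config[sec], DEFAULT_CONFIG[sec], sec)
    expr = config.get("expression") or {}
    _check_keys(expr, DEFAULT_CONFIG["expression"], "expression")
    if expr.get("gradient") is not None:
        _check_keys(expr["gradient"], {"epsilon": 0, "reference_index": 0}, "expression.gradient")
    if expr.get("static_noise") is not None:
        _check_keys(expr["static_noise"], {"S": 0}, "expression.static_noise")
    if expr.get("clone") is not None:
        _check_keys(
            expr["clone"],
            {"protein": "", "value": 0, "region": "", "radius": 0, "center": None},
            "expression.clone",
        )
    if config.get("sweep") is not None:
        _check_keys(
            config["sweep"],
            {"alpha_grid": [], "rho_grid": [], "n_cells": 0, "threshold": 0},
            "sweep",
        )
    stats = (config.get("analysis") or {}).get("statistics", [])
    unknown_stats = set(stats) - _KNOWN_STATS
    if unknown_stats:
        raise ValueError(f"unknown analysis statistics: {sorted(unknown_stats)}")


def resolve_config(config: Dict) -> Dict:
    """Overlay a (validated) partial configuration onto the defaults."""
    validate_config(config)
    resolved = copy.deepcopy(DEFAULT_CONFIG)
    for key, val in config.items():
        if isinstance(val, dict) and isinstance(resolved.get(key), dict):
            resolved[key] = {**resolved[key], **val}
        else:
            resolved[key] = copy.deepcopy(val)
    return resolved


def _build_profile(cfg: Dict, lattice, log):
    expr = cfg["expression"]
    rho_f = expr["rho_f"]
    rho_d = expr["rho_d"] if expr["rho_d"] is not None else rho_f
    if expr["gradient"] is not None:
        g = expr["gradient"]
        spec = GradientSpec(
            rho=rho_f, epsilon=g["epsilon"], reference_index=g.get("reference_index", 0)
        )
        profile = gradient_profile(lattice, spec, uniform_other=rho_d)
    else:
        profile = uniform_profile(lattice, rho_f, rho_d)
    if expr["static_noise"] is not None:
        s = StaticNoiseSpec(S=expr["static_noise"]["S"], seed=cfg["seed"] + 1_000_003)
        profile = apply_static_noise(profile, s)
        log.append(f"applied quenched expression noise S={s.S}")
    if expr["clone"] is not None:
        c = expr["clone"]
        n = profile.n_cells
        if c["region"] == "left_half":
            mask = np.arange(n // 2)
        elif c["region"] == "disc":
            mask = disc_mask(lattice, center=c.get("center"), radius=c.get("radius", 5.0))
        else:
            raise ValueError(f"unknown clone region {c['region']!r}")
        profile = apply_clone(profile, CloneSpec(mask=mask, protein=c["protein"], value=c["value"]))
        log.append(f"applied {c['protein']} clone ({c['region']}, value={c['value']}, {mask.size} cells)")
    if expr["unlimited_pool"] is not None:
        from dataclasses import replace

        profile = replace(profile, unlimited_pool=expr["unlimited_pool"])
        log.append(f"unlimited-pool binding at alpha*{expr['unlimited_pool']}")
    return profile


def run_experiment(config: Dict, outdir) -> Dict:
    """Run one configured experiment and write its outputs.

    Returns the summary dict (also written to ``summary.json``).  Output
    files: ``resolved_config.yaml``, state and polarity tables, analysis
    tables, ``summary.json``, ``log.txt``.
    """
    t_wall = time.time()
    cfg = resolve_config(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log: list = []
    (outdir / "resolved_config.yaml").write_text(yaml.safe_dump(cfg, sort_keys=False))

    params = KineticParams(**cfg["model"])
    summary: Dict = {"name": cfg["name"], "seed": cfg["seed"]}

    if cfg["sweep"] is not None:
        sw = cfg["sweep"]
        sweep = an.phase_diagram(
            sw["alpha_grid"],
            sw["rho_grid"],
            n_cells=sw.get("n_cells", 100),
            threshold=sw.get("threshold", 1e-3),
        )
        sweep.table.to_csv(outdir / "sweep.tsv", sep="\t", index=False)
        summary["sweep_points"] = len(sweep.table)
        summary["converged"] = bool(sweep.table["converged"].all())
        # empirical polarization boundary vs the continuum critical curve
        from .theory import critical_rho

        summary["critical_rho_theory"] = {
            str(a): critical_rho(a) for a in sw["alpha_grid"]
        }
        _finish(summary, log, outdir, t_wall)
        return summary

    dim = cfg["lattice"]["dimension"]
    sim = cfg["simulation"]
    stats = cfg["analysis"]["statistics"]
    if dim == 1:
        n = cfg["lattice"]["n_cells"]
        lattice = n
        profile = _build_profile(cfg, n, log)
        sconf = Sim1DConfig(
            n_cells=n,
            boundary=cfg["lattice"]["boundary"],
            dt=sim["dt"],
            convergence_tol=sim["convergence_tol"],
            max_time=sim["max_time"],
            max_steps=sim["max_steps"],
            init_asymmetry=sim["init_asymmetry"],
            init_direction=sim["init_direction"],
            seed=cfg["seed"],
        )
        state0 = initial_state(profile, sconf)
        if sim["kind"] == "langevin":
            noise = DynNoiseSpec(
                eta=sim["eta"],
                seed=cfg["seed"] + 7,
                duration_factor=sim["duration_factor"],
                duration=sim["duration"],
                tail_average_steps=sim["tail_average_steps"],
            )
            res = simulate_1d_langevin(
                state0, profile, params, sconf, noise, record_frames=sim["record_frames"]
            )
        else:
            res = simulate_1d(state0, profile, params, sconf)
        pio.write_state_1d(res.state, outdir / "state.tsv")
        pio.write_profile(profile, outdir / "profile.tsv")
        summary["tissue_polarity"] = tissue_polarity_1d(res.state)
        pf, pd_ = cell_polarity_1d(res.state)
        if "decay_fit" in stats:
            b = cfg["analysis"]["decay_boundary"]
            b = n // 2 if b is None else int(b)
            far = None
            if cfg["analysis"]["decay_far_field"]:
                far = "auto"
            fit = an.fit_decay_length(pf, b, far_field=far)
            summary["decay_fit"] = {
                "p0": fit.p0, "d_fit": fit.d_fit, "r_squared": fit.r_squared,
                "n_points": fit.n_points, "success": fit.success,
            }
        if "correlation_length" in stats and res.frames:
            cr = an.correlation_length(
                res.frames, np.arange(n, dtype=float), L=float(n),
                bin_width=cfg["analysis"]["correlation_bin_width"],
            )
            summary["correlation_length"] = {"zeta": cr.zeta, "zeta_normalized": cr.zeta_normalized}
    elif dim == 2:
        lattice = HexLattice(cfg["lattice"]["nx"], cfg["lattice"]["ny"], cfg["lattice"]["boundary"])
        profile = _build_profile(cfg, lattice, log)
        sconf = Sim2DConfig(
            dt=sim["dt"],
            convergence_tol=sim["convergence_tol"],
            max_steps=sim["max_steps"],
            init_asymmetry=sim["init_asymmetry"],
            init_direction=sim["init_direction"],
            seed=cfg["seed"],
        )
        state0 = initial_state_2d(profile, lattice, sconf)
        noise = None
        if sim["kind"] == "langevin":
            noise = DynNoiseSpec(
                eta=sim["eta"],
                seed=cfg["seed"] + 7,
                duration_factor=sim["duration_factor"],
                duration=sim["duration"],
                tail_average_steps=sim["tail_average_steps"],
            )
        res = simulate_2d(
            state0, profile, params, lattice, sconf, noise=noise,
            record_frames=sim["record_frames"],
        )
        pio.write_state_2d(res.state, lattice, outdir / "state.tsv")
        pio.write_polarity_2d(res.state, lattice, outdir / "polarity.tsv")
        pio.write_profile(profile, outdir / "profile.tsv")
        p = tissue_polarity_2d(res.state)
        summary["tissue_polarity"] = {"px": p[0], "py": p[1], "magnitude": float(np.hypot(*p))}
        pf, pd_ = cell_polarity_2d(res.state)
        pol = pf - pd_
        if "radial_polarity" in stats:
            center = cfg["analysis"]["clone_center"]
            grad_axis = "x" if cfg["expression"]["gradient"] is not None else None
            tab = an.radial_polarity(pol, lattice, center=center, gradient_axis=grad_axis)
            tab.to_csv(outdir / "radial_polarity.tsv", sep="\t", index=False)
        if "curl_divergence" in stats:
            curl, div, bnd = an.curl_divergence(pol, lattice)
            import pandas as pd

            pd.DataFrame(
                {"cell": np.arange(lattice.n_cells), "curl": curl, "div": div, "boundary": bnd}
            ).to_csv(outdir / "curl_divergence.tsv", sep="\t", index=False)
        if "correlation_length" in stats and res.frames:
            cr = an.correlation_length(
                res.frames, lattice.centers, L=float(max(lattice.nx, lattice.ny)),
                bin_width=cfg["analysis"]["correlation_bin_width"],
            )
            summary["correlation_length"] = {"zeta": cr.zeta, "zeta_normalized": cr.zeta_normalized}
    else:
        raise ValueError("lattice.dimension must be 1 or 2")

    summary["converged"] = bool(res.converged)
    summary["t_final"] = float(res.t_final)
    summary["n_steps"] = int(res.n_steps)
    summary["n_clamped"] = int(getattr(res, "n_clamped", 0))
    if summary["n_clamped"]:
        log.append(f"clamped {summary['n_clamped']} negative concentrations during integration")
    log.append(f"converged={summary['converged']} t_final={summary['t_final']}")
    _finish(summary, log, outdir, t_wall)
    return summary


def _finish(summary: Dict, log: list, outdir: Path, t_wall: float) -> None:
    log.append(f"wall time {time.time() - t_wall:.2f} s")
    (outdir / "log.txt").write_text("\n".join(str(x) for x in log) + "\n")
    (outdir / "summary.json").write_text(
        json.dumps(summary, indent=2, default=pio._json_default) + "\n"
    )
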