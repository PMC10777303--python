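"""Run configuration and command runners.

A :class:`RunConfig` collects everything a command needs (model and
growth-curve parameters, grids, tolerances, seed, output directory) from
a JSON or YAML file plus flag overrides.  Every runner writes a
reproducibility header — the fully resolved configuration — to
``run.json`` in the output directory, so re-running the header reproduces
the outputs bit for bit for the deterministic commands.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .abm import AbmConfig, simulate_population, snapshot_histogram
from .batch_dynamics import GrowthCurveParams, simulate_batch
from .fitting import fit_binding_intensity, generate_fixture_histogram
from .io import (
    read_histogram,
    write_histogram,
    write_steady_state,
    write_trajectory,
)
from .model_core import ModelParams, ValueGrid, default_value_grid
from .population_balance import solve_growth_rate
from .steady_state import distribution_stats, solve_fixed_point

__all__ = [
    "RunConfig",
    "load_config",
    "run_steady",
    "run_batch",
    "run_abm",
    "run_fit",
    "run_fixtures",
]

logger = logging.getLogger("luxvar")


@dataclass
class RunConfig:
    params: ModelParams = field(default_factory=ModelParams)
    growth: GrowthCurveParams | None = None
    sampling_times: list[float] | None = None
    z_max: float | None = None
    n_bins: int = 2048
    tol: float = 1e-8
    max_iter: int = 200
    seed: int = 0
    n_cells: int = 50_000
    t_end: float = 12.0
    population_cap: int = 50_000
    a_grid: list[float] = field(default_factory=lambda: [0.5, 1.0, 2.0, 4.0, 8.0])
    observed: str | None = None
    outdir: Path = Path("luxvar_out")

    def value_grid(self) -> ValueGrid:
        if self.z_max is None:
            return default_value_grid(self.params, self.n_bins)
        return ValueGrid(z_max=self.z_max, n_bins=self.n_bins)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["outdir"] = str(self.outdir)
        return d


def load_config(path: str | Path | None = None, **overrides) -> RunConfig:
    """Build a RunConfig from an optional JSON/YAML file and overrides.

    File keys: ``params`` (A, alpha, C, tau1), ``growth`` (mu_max,
    carrying_capacity, n0, lag_time, t_end, dt), and any top-level
    RunConfig field.  Explicit overrides win over the file.
    """
    raw: dict = {}
    if path is not None:
        text = Path(path).read_text()
        raw = yaml.safe_load(text) if str(path).endswith((".yml", ".yaml")) else json.loads(text)
        if not isinstance(raw, dict):
            raise ValueError(f"config file {path} must contain a mapping")
    raw.update({k: v for k, v in overrides.items() if v is not None})

    params_kw = raw.pop("params", {})
    for key in ("A", "alpha", "C", "tau1"):
        if key in raw:
            params_kw[key] = raw.pop(key)
    growth_kw = raw.pop("growth", None)

    cfg = RunConfig(params=ModelParams(**params_kw))
    if growth_kw is not None:
        cfg.growth = GrowthCurveParams(**growth_kw)
    for key, value in raw.items():
        if not hasattr(cfg, key):
            raise ValueError(f"unknown config key {key!r}")
        setattr(cfg, key, value)
    cfg.outdir = Path(cfg.outdir)
    return cfg


def _write_header(cfg: RunConfig, command: str) -> None:
    cfg.outdir.mkdir(parents=True, exist_ok=True)
    header = {"command": command, "version": __version__, "config": cfg.to_dict()}
    (cfg.outdir / "run.json").write_text(json.dumps(header, indent=2))
    logger.info("luxvar %s %s: %s", __version__, command, json.dumps(header["config"]))


def run_steady(cfg: RunConfig) -> dict:
    """Solve the steady state and write f, Phi, Phi_dividing and a summary.
    Returns the summary dict; ``converged`` is False on failure."""
    _write_header(cfg, "steady")
    state = solve_fixed_point(
        cfg.params, value_grid=cfg.value_grid(), tol=cfg.tol, max_iter=cfg.max_iter
    )
    stats = distribution_stats(state.phi_population)
    paths = write_steady_state(state, cfg.outdir, stats=stats)
    summary = json.loads(paths["summary"].read_text())
    if not state.converged:
        logger.error(
            "fixed point did not converge in %d iterations (residual %.3e)",
            state.n_iterations, state.final_residual,
        )
    return summary


def run_batch(cfg: RunConfig) -> dict:
    """Simulate a batch culture and write the trajectory and per-sample
    distributions."""
    if cfg.growth is None:
        mu_ref = solve_growth_rate(cfg.params.C, cfg.params.tau1)
        cfg.growth = GrowthCurveParams(mu_max=mu_ref)
    if cfg.sampling_times is None:
        cfg.sampling_times = [1.0, 4.0, 8.0, 11.0, 14.0, 18.0, 22.0]
    _write_header(cfg, "batch")
    traj = simulate_batch(
        cfg.params, cfg.growth, cfg.sampling_times, value_grid=cfg.value_grid()
    )
    paths = write_trajectory(traj, cfg.outdir)
    return {
        "trajectory": str(paths["trajectory"]),
        "n_samples": len(traj.phi),
        "inflection_time": traj.inflection_time(),
        "mean_intensity": traj.mean_intensity.tolist(),
    }


def run_abm(cfg: RunConfig) -> dict:
    """Run the agent-based simulator and write its snapshot histogram and
    summary statistics."""
    _write_header(cfg, "abm")
    abm_cfg = AbmConfig(
        params=cfg.params,
        n_initial=cfg.n_cells,
        population_cap=cfg.population_cap,
        t_end=cfg.t_end,
        seed=cfg.seed,
    )
    result = simulate_population(abm_cfg)
    hist = snapshot_histogram(result.amounts, cfg.value_grid())
    write_histogram(hist, cfg.outdir / "abm_histogram.csv")
    stats = distribution_stats(hist)
    summary = {
        "n_cells": int(result.amounts.size),
        "n_divisions": result.n_divisions,
        "growth_rate": result.growth_rate(),
        "mean": stats.mean,
        "cv": stats.cv,
    }
    (cfg.outdir / "abm_stats.json").write_text(json.dumps(summary, indent=2))
    return summary


def run_fit(cfg: RunConfig) -> dict:
    """Fit the binding intensity A to an observed histogram file."""
    if cfg.observed is None:
        raise ValueError("fit requires an observed histogram file")
    _write_header(cfg, "fit")
    observed = read_histogram(cfg.observed)
    result = fit_binding_intensity(observed, cfg.params, cfg.a_grid)
    result.objective.to_csv(cfg.outdir / "fit_objective.csv", index=False)
    summary = {
        "best_A": result.best_A,
        "observed_mean": result.observed_mean,
        "observed_cv": result.observed_cv,
    }
    (cfg.outdir / "fit.json").write_text(json.dumps(summary, indent=2))
    return summary


def run_fixtures(cfg: RunConfig) -> dict:
    """Generate a pseudo-experimental histogram fixture."""
    _write_header(cfg, "fixtures")
    path = cfg.outdir / "fixture_histogram.csv"
    mv = generate_fixture_histogram(
        cfg.params, cfg.n_cells, noise_seed=cfg.seed, grid=cfg.value_grid(), path=path
    )
    stats = distribution_stats(mv)
    return {"path": str(path), "n_cells": cfg.n_cells, "mean": stats.mean, "cv": stats.cv}


def configure_logging(outdir: Path | None = None) -> None:
    handlers: list[logging.Handler] = [logging.StreamHandler(sys.stderr)]
    if outdir is not None:
        outdir.mkdir(parents=True, exist_ok=True)
        handlers.append(logging.FileHandler(outdir / "luxvar.log"))
    logging.basicConfig(
        level=logging.INFO,
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
        handlers=handlers,
        force=True,
    )
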