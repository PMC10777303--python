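"""Serialization of histograms, age profiles and trajectories.

Histogram dialect: comma-separated, header ``bin_left,bin_right,mass``,
UTF-8, '.' decimal.  A JSON variant carries the grid metadata and the
overflow mass explicitly.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .model_core import MassVector, ValueGrid
from .population_balance import AgeProfile

__all__ = [
    "write_histogram",
    "read_histogram",
    "write_histogram_json",
    "read_histogram_json",
    "write_age_profile",
    "write_steady_state",
    "write_trajectory",
]


def write_histogram(mv: MassVector, path: str | Path) -> Path:
    path = Path(path)
    edges = mv.grid.edges
    pd.DataFrame(
        {"bin_left": edges[:-1], "bin_right": edges[1:], "mass": mv.mass}
    ).to_csv(path, index=False)
    return path


def read_histogram(path: str | Path) -> MassVector:
    df = pd.read_csv(path)
    for col in ("bin_left", "bin_right", "mass"):
        if col not in df.columns:
            raise ValueError(f"histogram file missing column {col!r}")
    left = df["bin_left"].to_numpy(float)
    right = df["bin_right"].to_numpy(float)
    widths = right - left
    if left[0] != 0.0 or not np.allclose(widths, widths[0], rtol=1e-9, atol=1e-12):
        raise ValueError("histogram bins must be uniform and start at 0")
    grid = ValueGrid(z_max=float(right[-1]), n_bins=len(df))
    mass = df["mass"].to_numpy(float)
    total = mass.sum()
    if total <= 0:
        raise ValueError("histogram has no mass")
    # accept either normalized masses or raw counts
    overflow = max(1.0 - total, 0.0) if abs(total - 1.0) <= 0.5 else 0.0
    if abs(total - 1.0) > 1e-6:
        mass = mass / total
        overflow = 0.0
    return MassVector(grid, mass, overflow)


def write_histogram_json(mv: MassVector, path: str | Path) -> Path:
    path = Path(path)
    payload = {
        "grid": {"z_max": mv.grid.z_max, "n_bins": mv.grid.n_bins},
        "mass": mv.mass.tolist(),
        "overflow": mv.overflow,
    }
    path.write_text(json.dumps(payload))
    return path


def read_histogram_json(path: str | Path) -> MassVector:
    payload = json.loads(Path(path).read_text())
    grid = ValueGrid(**payload["grid"])
    return MassVector(grid, np.array(payload["mass"]), payload.get("overflow", 0.0))


def write_age_profile(profile: AgeProfile, path: str | Path) -> tuple[Path, Path]:
    """Delimited table (tau, psi, omega_div) plus a JSON sidecar with mu,
    C and tau1."""
    path = Path(path)
    omega = (
        profile.omega_div
        if profile.omega_div is not None
        else np.full(profile.taus.size, np.nan)
    )
    pd.DataFrame({"tau": profile.taus, "psi": profile.psi, "omega_div": omega}).to_csv(
        path, index=False
    )
    meta = path.with_suffix(path.suffix + ".json")
    meta.write_text(
        json.dumps({"mu": profile.mu, "C": profile.C, "tau1": profile.tau1})
    )
    return path, meta


def write_steady_state(state, outdir: str | Path, stats=None) -> dict[str, Path]:
    """Histogram tables for f, Phi and Phi_dividing plus a JSON summary."""
    from .steady_state import distribution_stats

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "f_newborn": write_histogram(state.f_newborn, outdir / "f_newborn.csv"),
        "phi_population": write_histogram(state.phi_population, outdir / "phi_population.csv"),
        "phi_dividing": write_histogram(state.phi_dividing, outdir / "phi_dividing.csv"),
    }
    if stats is None:
        stats = distribution_stats(state.phi_population)
    summary = {
        "converged": state.converged,
        "iterations": state.n_iterations,
        "residual": state.final_residual,
        "mu": state.mu,
        "mean": stats.mean,
        "sd": stats.sd,
        "cv": stats.cv,
        "params": {
            "A": state.params.A,
            "alpha": state.params.alpha,
            "C": state.params.C,
            "tau1": state.params.tau1,
        },
    }
    summary_path = outdir / "summary.json"
    summary_path.write_text(json.dumps(summary, indent=2))
    paths["summary"] = summary_path
    return paths


def write_trajectory(traj, outdir: str | Path) -> dict[str, Path]:
    """Trajectory table plus one histogram per sampling time."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    table = pd.DataFrame(
        {
            "t": traj.sample_times,
            "N": traj.sample_biomass,
            "mu": traj.sample_mu,
            "A_eff": traj.sample_a_eff,
            "mean_intensity": traj.mean_intensity,
            "culture_intensity": traj.culture_intensity,
        }
    )
    paths = {"trajectory": outdir / "trajectory.csv"}
    table.to_csv(paths["trajectory"], index=False)
    for k, phi in enumerate(traj.phi, start=1):
        paths[f"phi_{k}"] = write_histogram(phi, outdir / f"phi_sample_{k}.csv")
    return paths
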