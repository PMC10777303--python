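"""Batch-culture dynamics of the luminescence distribution.

A closed culture passes through lag, exponential and stationary phases.
The growth curve supplies a time-varying specific growth rate mu(t); on
the cell's own time scale (generation time as the unit) the synthesis
rate stays fixed while the operon shut-off intensity scales inversely
with the growth rate:

    A_eff(t) = A * mu_ref / max(mu(t), mu_floor),

mu_ref being the exponential-phase growth rate from the characteristic
equation.  Slow growth therefore means many shut-off events per cycle and
dim cells — the mechanism behind both the dim stationary inoculum and the
late-phase shift of the distributions toward zero.

Coupling is quasi-static: the newborn distribution advances by one
generation-map application per generation time elapsed on the growth
curve (elapsed generations accumulate as the integral of mu/mu_ref), and
the whole-culture distribution at a sampling time is composed with the
stationary age structure at the current effective parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model_core import MassVector, ModelParams, ValueGrid, _mixture_kernel, default_value_grid
from .population_balance import AgeGrid, age_profile, solve_growth_rate
from .steady_state import (
    compose_population,
    generation_map,
    solve_fixed_point,
)

__all__ = [
    "GrowthCurveParams",
    "BatchTrajectory",
    "logistic_growth_curve",
    "effective_params",
    "simulate_batch",
]


@dataclass(frozen=True)
class GrowthCurveParams:
    """Lagged-logistic growth curve.

    mu(t, N) = mu_max * (1 - exp(-t / lag_time)) * (1 - N / K): the lag
    factor delays growth after inoculation, the logistic factor shuts it
    down at the carrying capacity.  Times are in units of the mean
    generation time of the exponential phase.
    """

    mu_max: float
    carrying_capacity: float = 1000.0
    n0: float = 1.0
    lag_time: float = 1.0
    t_end: float = 24.0
    dt: float = 0.01

    def __post_init__(self) -> None:
        if min(self.mu_max, self.carrying_capacity, self.n0, self.lag_time,
               self.t_end, self.dt) <= 0:
            raise ValueError("all growth-curve parameters must be > 0")
        if self.n0 >= self.carrying_capacity:
            raise ValueError("initial biomass must be below the carrying capacity")


@dataclass
class BatchTrajectory:
    """Sampled state of a simulated batch culture."""

    times: np.ndarray            # full growth-curve time axis
    biomass: np.ndarray          # N(t) on the full axis
    mu: np.ndarray               # mu(t) on the full axis
    sample_times: np.ndarray
    sample_biomass: np.ndarray
    sample_mu: np.ndarray
    sample_a_eff: np.ndarray
    newborn: list[MassVector] = field(repr=False, default_factory=list)
    phi: list[MassVector] = field(repr=False, default_factory=list)
    mean_intensity: np.ndarray = field(default_factory=lambda: np.empty(0))
    culture_intensity: np.ndarray = field(default_factory=lambda: np.empty(0))

    def inflection_time(self) -> float:
        """Time of the biomass inflection (maximum of dN/dt)."""
        growth = self.mu * self.biomass
        return float(self.times[int(np.argmax(growth))])


def logistic_growth_curve(gp: GrowthCurveParams) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Integrate dN/dt = mu(t, N) * N by fixed-step RK4; returns
    (times, N, mu)."""

    def rate(t: float, n: float) -> float:
        return gp.mu_max * (1.0 - np.exp(-t / gp.lag_time)) * (1.0 - n / gp.carrying_capacity)

    n_steps = int(np.ceil(gp.t_end / gp.dt))
    times = np.linspace(0.0, n_steps * gp.dt, n_steps + 1)
    biomass = np.empty(n_steps + 1)
    biomass[0] = gp.n0
    h = gp.dt
    for i in range(n_steps):
        t, n = times[i], biomass[i]
        k1 = rate(t, n) * n
        k2 = rate(t + h / 2, n + h / 2 * k1) * (n + h / 2 * k1)
        k3 = rate(t + h / 2, n + h / 2 * k2) * (n + h / 2 * k2)
        k4 = rate(t + h, n + h * k3) * (n + h * k3)
        biomass[i + 1] = n + h / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
        if biomass[i + 1] > 1.01 * gp.carrying_capacity:
            raise ValueError("biomass overshot the carrying capacity; reduce dt")
    mu = np.array([rate(t, n) for t, n in zip(times, biomass)])
    return times, biomass, np.clip(mu, 0.0, None)


def effective_params(
    mu_t: float, base: ModelParams, mu_ref: float, mu_floor: float | None = None
) -> ModelParams:
    """Rescale the binding intensity to the cell's own time scale.

    With the generation time as the unit, alpha, C and tau1 are unchanged
    while A scales as mu_ref / mu(t); ``mu_floor`` (default mu_ref / 20)
    caps the slowdown so A_eff stays finite in deep stationary phase.
    """
    if mu_t < 0:
        raise ValueError(f"growth rate must be >= 0, got {mu_t}")
    if mu_ref <= 0:
        raise ValueError(f"reference growth rate must be > 0, got {mu_ref}")
    if mu_floor is None:
        mu_floor = mu_ref / 20.0
    return base.replace(A=base.A * mu_ref / max(mu_t, mu_floor))


def simulate_batch(
    base: ModelParams,
    gp: GrowthCurveParams,
    sampling_times,
    value_grid: ValueGrid | None = None,
    age_grid: AgeGrid | None = None,
    mu_floor: float | None = None,
) -> BatchTrajectory:
    """Quasi-static batch simulation.

    The inoculum newborn distribution is the fixed point at the effective
    parameters of the initial (near-zero) growth rate — dim cells from a
    stationary pre-culture.  One generation-map application is made per
    generation time elapsed on the growth curve, each at the effective
    binding intensity of that moment.
    """
    sampling_times = np.sort(np.asarray(sampling_times, dtype=float))
    if sampling_times.size == 0:
        raise ValueError("at least one sampling time required")
    if sampling_times[0] < 0 or sampling_times[-1] > gp.t_end:
        raise ValueError("sampling times must lie within [0, t_end]")
    if value_grid is None:
        value_grid = default_value_grid(base)

    times, biomass, mu_curve = logistic_growth_curve(gp)
    mu_ref = solve_growth_rate(base.C, base.tau1)
    profile = age_profile(base, age_grid)  # Psi/Omega depend only on C, tau1

    f = solve_fixed_point(
        effective_params(mu_curve[0], base, mu_ref, mu_floor), value_grid
    ).f_newborn

    traj = BatchTrajectory(
        times=times, biomass=biomass, mu=mu_curve,
        sample_times=sampling_times,
        sample_biomass=np.empty(sampling_times.size),
        sample_mu=np.empty(sampling_times.size),
        sample_a_eff=np.empty(sampling_times.size),
    )
    means = np.empty(sampling_times.size)

    gen_accum = 0.0
    next_sample = 0
    for i in range(times.size):
        while next_sample < sampling_times.size and times[i] >= sampling_times[next_sample]:
            eff = effective_params(mu_curve[i], base, mu_ref, mu_floor)
            phi = compose_population(f, profile, eff, value_grid)
            traj.newborn.append(f.copy())
            traj.phi.append(phi)
            traj.sample_biomass[next_sample] = biomass[i]
            traj.sample_mu[next_sample] = mu_curve[i]
            traj.sample_a_eff[next_sample] = eff.A
            means[next_sample] = phi.mean()
            next_sample += 1
        if i + 1 < times.size:
            gen_accum += (mu_curve[i] / mu_ref) * gp.dt
            while gen_accum >= 1.0:
                eff = effective_params(mu_curve[i], base, mu_ref, mu_floor)
                kernel = _mixture_kernel(
                    profile.taus, profile.omega_weights, eff, value_grid
                )
                f = generation_map(f, eff, profile, value_grid, dividing_kernel=kernel)
                gen_accum -= 1.0

    traj.mean_intensity = means
    traj.culture_intensity = means * traj.sample_biomass
    return traj
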