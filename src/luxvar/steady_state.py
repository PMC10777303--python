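"""Self-consistent steady state of the inheritance–synthesis loop.

The newborn distribution f(x) (amount inherited at birth) determines, via
synthesis during the cycle and halving at division, the next generation's
newborn distribution.  The steady state is the fixed point of

    f  ->  halve( int Omega(tau) [f * P(., tau)] dtau ),

where * is convolution, P(., tau) the age-conditional synthesized-amount
distribution and Omega the dividing-age density.  The map contracts —
inherited variance is quartered and only half the daughter amount is
"new" — so successive approximations from any start converge geometrically;
we start from an atom at 0.  The whole-culture distribution is then

    Phi(z) = int Psi(tau) [f * P(., tau)](z) dtau.

By linearity of convolution both age integrals are evaluated as a single
convolution of f with the age-mixture kernel int w(tau) P(., tau) dtau,
which makes one fixed-point sweep one FFT-free convolution.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model_core import (
    MassVector,
    ModelParams,
    ValueGrid,
    _mixture_kernel,
    convolve_mass,
    default_value_grid,
    narrow_age_distribution,
    rescale_axis,
)
from .population_balance import AgeGrid, AgeProfile, age_profile

__all__ = [
    "SteadyState",
    "DistStats",
    "age_conditional_distribution",
    "compose_population",
    "compose_dividing",
    "halve_at_division",
    "generation_map",
    "solve_fixed_point",
    "distribution_stats",
]


@dataclass
class SteadyState:
    """Converged (or last-iterate) state of the successive approximations."""

    f_newborn: MassVector
    phi_population: MassVector
    phi_dividing: MassVector
    n_iterations: int
    final_residual: float
    converged: bool
    mu: float
    params: ModelParams
    residual_history: list[float] = field(default_factory=list)


@dataclass(frozen=True)
class DistStats:
    mean: float
    sd: float
    cv: float
    q25: float
    median: float
    q75: float


def age_conditional_distribution(
    f: MassVector, tau: float, params: ModelParams, grid: ValueGrid
) -> MassVector:
    """Distribution of total amount z = x + y for cells of exact age tau:
    convolution of the newborn distribution with P(., tau)."""
    return convolve_mass(f, narrow_age_distribution(tau, params, grid))


def _compose(f: MassVector, weights: np.ndarray, profile: AgeProfile,
             params: ModelParams, grid: ValueGrid) -> MassVector:
    kernel = _mixture_kernel(profile.taus, weights, params, grid)
    return convolve_mass(f, kernel)


def compose_population(
    f: MassVector, profile: AgeProfile, params: ModelParams, grid: ValueGrid
) -> MassVector:
    """Whole-culture amount distribution Phi(z) = int Psi(tau) Phi_tau(z) dtau
    (trapezoidal age quadrature)."""
    return _compose(f, profile.psi_weights, profile, params, grid)


def compose_dividing(
    f: MassVector, profile: AgeProfile, params: ModelParams, grid: ValueGrid
) -> MassVector:
    """Amount distribution over cells at the moment of division
    (Omega-weighted age quadrature)."""
    return _compose(f, profile.omega_weights, profile, params, grid)


def halve_at_division(phi_div: MassVector) -> MassVector:
    """Each daughter inherits half the mother's content: z -> z/2 with
    linear interpolation between the two nearest bins."""
    return rescale_axis(phi_div, 0.5)


def generation_map(
    f: MassVector,
    params: ModelParams,
    profile: AgeProfile,
    grid: ValueGrid,
    dividing_kernel: MassVector | None = None,
) -> MassVector:
    """One generation: synthesize to division age, then halve.

    ``dividing_kernel`` may carry the precomputed Omega-mixture kernel so
    repeated applications cost a single convolution each.
    """
    if dividing_kernel is None:
        dividing_kernel = _mixture_kernel(profile.taus, profile.omega_weights, params, grid)
    return halve_at_division(convolve_mass(f, dividing_kernel))


def solve_fixed_point(
    params: ModelParams,
    value_grid: ValueGrid | None = None,
    age_grid: AgeGrid | None = None,
    tol: float = 1e-8,
    max_iter: int = 200,
    initial: MassVector | None = None,
) -> SteadyState:
    """Successive approximations for the newborn distribution.

    Iterates the generation map from ``initial`` (default: atom at 0) until
    the L1 change drops to ``tol`` or ``max_iter`` is reached; the result
    reports convergence explicitly rather than raising, so callers can
    inspect the last residual.
    """
    if tol <= 0:
        raise ValueError(f"tolerance must be > 0, got {tol}")
    if value_grid is None:
        value_grid = default_value_grid(params)
    profile = age_profile(params, age_grid)
    dividing_kernel = _mixture_kernel(profile.taus, profile.omega_weights, params, value_grid)

    f = MassVector.point_mass(value_grid, 0.0) if initial is None else initial.copy()
    history: list[float] = []
    residual = np.inf
    iterations = 0
    for iterations in range(1, max_iter + 1):
        f_next = halve_at_division(convolve_mass(f, dividing_kernel))
        residual = f.l1_distance(f_next)
        history.append(residual)
        f = f_next
        if residual <= tol:
            break
    converged = residual <= tol

    phi = compose_population(f, profile, params, value_grid)
    phi_div = convolve_mass(f, dividing_kernel)
    return SteadyState(
        f_newborn=f,
        phi_population=phi,
        phi_dividing=phi_div,
        n_iterations=iterations,
        final_residual=float(residual),
        converged=converged,
        mu=profile.mu,
        params=params,
        residual_history=history,
    )


def distribution_stats(phi: MassVector) -> DistStats:
    """Moments and quartiles from bin centers.  The mean must be positive
    for the CV to be defined."""
    if abs(phi.total - 1.0) > 1e-6:
        raise ValueError(f"distribution mass {phi.total} is not ~1")
    centers = phi.grid.centers
    mean = float(phi.mass @ centers)
    if mean <= 0:
        raise ValueError("mean is zero; CV undefined")
    var = float(phi.mass @ centers**2) - mean**2
    sd = float(np.sqrt(max(var, 0.0)))
    cum = np.concatenate(([0.0], np.cumsum(phi.mass)))
    q25, median, q75 = np.interp([0.25, 0.5, 0.75], cum, phi.grid.edges)
    return DistStats(mean=mean, sd=sd, cv=sd / mean, q25=float(q25),
                     median=float(median), q75=float(q75))
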