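"""Stationary age structure of an exponentially growing culture.

Division is an age-dependent hazard: cells younger than the minimum
division age ``tau1`` never divide; older cells divide with constant
intensity ``C``, so the cycle length along a lineage is
``T = tau1 + Exp(C)``.  In a culture growing exponentially at specific
rate ``mu`` the age-frequency density obeys

    dPsi/dtau = -(mu + omega(tau)) * Psi(tau),

i.e. Psi(tau) is proportional to exp(-mu*tau) times the division-survival
function, and ``mu`` itself is pinned by the binary-fission renewal
closure: the newborn flux equals twice the division flux,

    1 = 2 * int_0^inf omega(tau) exp(-mu*tau) S(tau) dtau,

which for the step hazard reduces to the characteristic equation
``(mu + C) * exp(mu * tau1) = 2 C``.  The age density of *dividing* cells
is ``Omega(tau) ∝ omega(tau) * Psi(tau)`` — a shifted exponential with
rate ``mu + C`` starting at ``tau1``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from .model_core import ModelParams

__all__ = [
    "AgeGrid",
    "AgeProfile",
    "default_age_grid",
    "division_hazard",
    "solve_growth_rate",
    "stationary_age_distribution",
    "dividing_age_distribution",
    "age_profile",
    "cycle_length_stats",
]


@dataclass(frozen=True)
class AgeGrid:
    """Uniform age grid on [0, tau_max] with ``n_steps`` intervals."""

    tau_max: float
    n_steps: int

    def __post_init__(self) -> None:
        if self.tau_max <= 0:
            raise ValueError(f"tau_max must be > 0, got {self.tau_max}")
        if self.n_steps < 2:
            raise ValueError(f"n_steps must be >= 2, got {self.n_steps}")

    @property
    def step(self) -> float:
        return self.tau_max / self.n_steps

    @property
    def taus(self) -> np.ndarray:
        return np.linspace(0.0, self.tau_max, self.n_steps + 1)

    @property
    def trapezoid_weights(self) -> np.ndarray:
        w = np.full(self.n_steps + 1, self.step)
        w[0] *= 0.5
        w[-1] *= 0.5
        return w


def default_age_grid(C: float, tau1: float, step: float = 1.0 / 512.0) -> AgeGrid:
    """Default grid: step 1/512, truncated at ``tau1 + 30/C`` where the
    survivor mass is below e^-30 ~ 1e-13."""
    tau_max = tau1 + 30.0 / C
    return AgeGrid(tau_max=tau_max, n_steps=int(np.ceil(tau_max / step)))


@dataclass
class AgeProfile:
    """Stationary age structure: density values on an :class:`AgeGrid`.

    ``psi`` integrates to 1 (trapezoidal rule); ``omega_div`` is the
    dividing-age density (filled by :func:`dividing_age_distribution`),
    zero below ``tau1``.
    """

    grid: AgeGrid
    psi: np.ndarray
    mu: float
    C: float
    tau1: float
    omega_div: np.ndarray | None = field(default=None)

    @property
    def taus(self) -> np.ndarray:
        return self.grid.taus

    def _quadrature_weights(self, density: np.ndarray) -> np.ndarray:
        w = self.grid.trapezoid_weights * density
        total = w.sum()
        if total <= 0:
            raise ValueError("density has no mass on this grid")
        return w / total

    @property
    def psi_weights(self) -> np.ndarray:
        """Normalized quadrature weights for averaging over the whole culture."""
        return self._quadrature_weights(self.psi)

    @property
    def omega_weights(self) -> np.ndarray:
        """Normalized quadrature weights for averaging over dividing cells."""
        if self.omega_div is None:
            raise ValueError("omega_div not filled; call dividing_age_distribution first")
        return self._quadrature_weights(self.omega_div)

    def mean_age(self) -> float:
        return float(self.psi_weights @ self.taus)

    def mean_dividing_age(self) -> float:
        return float(self.omega_weights @ self.taus)


def division_hazard(tau, C: float, tau1: float):
    """Age-dependent division rate ``omega(tau) = C * theta(tau - tau1)``
    (the boundary age ``tau1`` is included).  Accepts scalars or arrays."""
    tau_arr = np.asarray(tau, dtype=float)
    if (tau_arr < 0).any():
        raise ValueError("age must be >= 0")
    if C <= 0:
        raise ValueError(f"division intensity must be > 0, got {C}")
    if tau1 < 0:
        raise ValueError(f"minimum division age must be >= 0, got {tau1}")
    out = np.where(tau_arr >= tau1, C, 0.0)
    return float(out) if np.isscalar(tau) else out


def solve_growth_rate(C: float, tau1: float) -> float:
    """Specific population growth rate from the characteristic equation
    ``(mu + C) * exp(mu * tau1) = 2 C``; the unique root in (0, C]."""
    if C <= 0:
        raise ValueError(f"division intensity must be > 0, got {C}")
    if tau1 < 0:
        raise ValueError(f"minimum division age must be >= 0, got {tau1}")
    if tau1 == 0.0:
        return float(C)

    def residual(mu: float) -> float:
        return (mu + C) * np.exp(mu * tau1) - 2.0 * C

    return float(brentq(residual, 1e-15, C, xtol=1e-13, rtol=8.9e-16))


def stationary_age_distribution(
    mu: float, C: float, tau1: float, grid: AgeGrid | None = None
) -> AgeProfile:
    """Closed-form stationary age density, trapezoid-normalized:

        Psi(tau) ∝ exp(-mu*tau)                       for tau < tau1,
        Psi(tau) ∝ exp(-mu*tau - C*(tau - tau1))      for tau >= tau1.
    """
    if grid is None:
        grid = default_age_grid(C, tau1)
    if grid.tau_max <= tau1:
        raise ValueError("age grid must extend beyond the minimum division age")
    taus = grid.taus
    log_psi = -mu * taus - C * np.clip(taus - tau1, 0.0, None)
    psi = np.exp(log_psi)
    psi /= (grid.trapezoid_weights * psi).sum()
    return AgeProfile(grid=grid, psi=psi, mu=mu, C=C, tau1=tau1)


def dividing_age_distribution(profile: AgeProfile) -> AgeProfile:
    """Fill ``omega_div(tau) ∝ omega(tau) * Psi(tau)``, normalized."""
    hazard = division_hazard(profile.taus, profile.C, profile.tau1)
    raw = hazard * profile.psi
    total = (profile.grid.trapezoid_weights * raw).sum()
    if total <= 0:
        raise ValueError("hazard * Psi has no mass: grid does not cover dividing ages")
    profile.omega_div = raw / total
    return profile


def age_profile(params: ModelParams, grid: AgeGrid | None = None) -> AgeProfile:
    """Convenience: solve mu and build the full stationary profile
    (Psi and Omega) for a parameter set."""
    mu = solve_growth_rate(params.C, params.tau1)
    profile = stationary_age_distribution(mu, params.C, params.tau1, grid)
    return dividing_age_distribution(profile)


def cycle_length_stats(C: float, tau1: float) -> tuple[float, float]:
    """Mean and CV of the intrinsic (lineage) cycle length
    ``T = tau1 + Exp(C)``: mean ``tau1 + 1/C``, CV ``(1/C)/(tau1 + 1/C)``."""
    if C <= 0:
        raise ValueError(f"division intensity must be > 0, got {C}")
    if tau1 < 0:
        raise ValueError(f"minimum division age must be >= 0, got {tau1}")
    mean = tau1 + 1.0 / C
    cv = (1.0 / C) / mean
    return mean, cv
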