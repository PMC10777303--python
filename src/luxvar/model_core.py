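"""Elementary probabilistic objects of the operon shut-off model.

A cell of age ``tau`` carries luciferase ``z = x + y(tau)``: the inherited
amount ``x`` (half the mother's content at division) plus the amount
synthesized since birth.  Synthesis starts at birth, proceeds at constant
rate ``alpha`` and stops irreversibly when the repressor binds the operator,
an exponential waiting time with intensity ``A``.  Hence

    y(tau) = alpha * min(tau, tau_prime),     tau_prime ~ Exp(A),

and the age-conditional distribution of ``y`` is a truncated exponential
density on [0, alpha*tau) plus a "survivor" point mass exp(-A*tau) at
y = alpha*tau (cells whose operon is still on).

All distributions over amounts are represented as bin-mass vectors on a
uniform grid (:class:`MassVector`); Dirac atoms are folded into bins, which
keeps convolution and halving exactly mass-conserving.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np

__all__ = [
    "ModelParams",
    "ValueGrid",
    "MassVector",
    "default_value_grid",
    "binding_time_density",
    "binding_survivor",
    "synthesized_amount",
    "narrow_age_distribution",
    "convolve_mass",
    "rescale_axis",
    "apply_inactivation",
    "rebin",
]

_MASS_TOL = 1e-6


@dataclass(frozen=True)
class ModelParams:
    """Parameters of the stochastic shut-off model, in generation-time units.

    Attributes
    ----------
    A : float
        Intensity of repressor–operator binding events per mean generation
        time.  ``A = 0`` means constitutive synthesis (the operon never
        shuts off within a cycle).
    alpha : float
        Luciferase synthesis rate (amount per generation time).  A pure
        scale factor for the amount axis.
    C : float
        Intensity of division events once a cell is old enough to divide.
    tau1 : float
        Minimum age at which division can begin.  With ``C = 4`` and
        ``tau1 = 0.75`` the mean cycle length is exactly one generation
        time and its CV is 25 %.
    tau0 : float
        The time unit, the mean generation time.  Fixed at 1: all rates and
        ages are dimensionless multiples of it.
    """

    A: float = 2.0
    alpha: float = 1.0
    C: float = 4.0
    tau1: float = 0.75
    tau0: float = 1.0

    def __post_init__(self) -> None:
        if self.A < 0:
            raise ValueError(f"binding intensity A must be >= 0, got {self.A}")
        if self.alpha <= 0:
            raise ValueError(f"synthesis rate alpha must be > 0, got {self.alpha}")
        if self.C <= 0:
            raise ValueError(f"division intensity C must be > 0, got {self.C}")
        if self.tau1 < 0:
            raise ValueError(f"minimum division age tau1 must be >= 0, got {self.tau1}")
        if self.tau0 != 1.0:
            raise ValueError(
                "tau0 is the time unit and is fixed at 1; express C, A and tau1 "
                "as multiples of the mean generation time instead"
            )

    def replace(self, **changes) -> "ModelParams":
        return dataclasses.replace(self, **changes)


@dataclass(frozen=True)
class ValueGrid:
    """Uniform discretization of the luciferase-amount axis ``[0, z_max)``.

    Bins are half-open ``[z_i, z_i + bin_width)`` with the left edge of the
    first bin at 0.
    """

    z_max: float
    n_bins: int

    def __post_init__(self) -> None:
        if self.z_max <= 0:
            raise ValueError(f"z_max must be > 0, got {self.z_max}")
        if self.n_bins < 2:
            raise ValueError(f"n_bins must be >= 2, got {self.n_bins}")

    @property
    def bin_width(self) -> float:
        return self.z_max / self.n_bins

    @property
    def edges(self) -> np.ndarray:
        return np.linspace(0.0, self.z_max, self.n_bins + 1)

    @property
    def centers(self) -> np.ndarray:
        dz = self.bin_width
        return dz * (np.arange(self.n_bins) + 0.5)

    def bin_index(self, z: float) -> int:
        """Index of the bin containing ``z`` (left-closed), or ``n_bins`` if beyond."""
        if z < 0:
            raise ValueError(f"amount must be >= 0, got {z}")
        return min(int(np.floor(z / self.bin_width)), self.n_bins)


def default_value_grid(params: ModelParams, n_bins: int = 2048) -> ValueGrid:
    """Default amount grid: ``z_max = 8 * alpha * tau0`` (ample headroom above
    the steady-state mean of roughly ``1.4 * alpha``)."""
    return ValueGrid(z_max=8.0 * params.alpha * params.tau0, n_bins=n_bins)


@dataclass
class MassVector:
    """A probability distribution over luciferase amount as bin masses.

    ``sum(mass) + overflow == 1`` within tolerance; ``overflow`` is the
    probability that fell beyond ``grid.z_max``.
    """

    grid: ValueGrid
    mass: np.ndarray
    overflow: float = 0.0

    def __post_init__(self) -> None:
        self.mass = np.asarray(self.mass, dtype=float)
        if self.mass.shape != (self.grid.n_bins,):
            raise ValueError(
                f"mass has shape {self.mass.shape}, grid expects ({self.grid.n_bins},)"
            )
        if self.mass.min(initial=0.0) < -1e-12 or self.overflow < -1e-12:
            raise ValueError("bin masses must be non-negative")
        # clip floating-point dust
        np.maximum(self.mass, 0.0, out=self.mass)
        self.overflow = max(self.overflow, 0.0)
        total = self.mass.sum() + self.overflow
        if abs(total - 1.0) > _MASS_TOL:
            raise ValueError(f"total mass {total} deviates from 1 beyond tolerance")

    @property
    def total(self) -> float:
        return float(self.mass.sum() + self.overflow)

    def mean(self) -> float:
        """First moment over bin centers (overflow ignored)."""
        return float(self.mass @ self.grid.centers)

    def copy(self) -> "MassVector":
        return MassVector(self.grid, self.mass.copy(), self.overflow)

    def l1_distance(self, other: "MassVector") -> float:
        _require_same_grid(self, other)
        return float(np.abs(self.mass - other.mass).sum() + abs(self.overflow - other.overflow))

    @classmethod
    def point_mass(cls, grid: ValueGrid, z: float) -> "MassVector":
        """Unit atom at amount ``z`` placed in its (left-closed) bin."""
        mass = np.zeros(grid.n_bins)
        idx = grid.bin_index(z)
        if idx >= grid.n_bins:
            return cls(grid, mass, overflow=1.0)
        mass[idx] = 1.0
        return cls(grid, mass)


def _require_same_grid(a: MassVector, b: MassVector) -> None:
    if a.grid != b.grid:
        raise ValueError("MassVectors are on different grids")


def binding_time_density(t_prime: float, A: float) -> float:
    """Exponential density of the repressor–operator binding time:
    ``g(t') = A * exp(-A * t')``; identically 0 for A = 0 (never binds)."""
    if t_prime < 0:
        raise ValueError(f"binding time must be >= 0, got {t_prime}")
    if A < 0:
        raise ValueError(f"binding intensity must be >= 0, got {A}")
    return float(A * np.exp(-A * t_prime))


def binding_survivor(tau: float, A: float) -> float:
    """Probability the operon is still on at age ``tau``: ``exp(-A * tau)``."""
    if tau < 0:
        raise ValueError(f"age must be >= 0, got {tau}")
    if A < 0:
        raise ValueError(f"binding intensity must be >= 0, got {A}")
    return float(np.exp(-A * tau))


def synthesized_amount(tau: float, t_prime: float, alpha: float) -> float:
    """Amount synthesized by age ``tau`` given binding at ``t_prime``:
    ``alpha * min(tau, t_prime)``."""
    if tau < 0 or t_prime < 0:
        raise ValueError("age and binding time must be >= 0")
    if alpha <= 0:
        raise ValueError(f"synthesis rate must be > 0, got {alpha}")
    return float(alpha * min(tau, t_prime))


def _mixture_kernel(
    taus: np.ndarray, weights: np.ndarray, params: ModelParams, grid: ValueGrid
) -> MassVector:
    """Mixture over ages of the synthesized-amount distribution:

        K(y) = sum_i w_i * P(y, tau_i),    sum_i w_i = 1.

    For each age the continuous part is the truncated exponential
    ``(A/alpha) exp(-A y/alpha)`` on [0, alpha*tau), integrated exactly per
    bin; the survivor atom ``exp(-A tau)`` lands in the bin containing
    ``alpha * tau``.  Vectorized over ages in chunks.
    """
    taus = np.asarray(taus, dtype=float)
    weights = np.asarray(weights, dtype=float)
    if taus.shape != weights.shape:
        raise ValueError("ages and weights must have matching shapes")
    if (taus < 0).any():
        raise ValueError("ages must be >= 0")
    A, alpha = params.A, params.alpha
    edges = grid.edges
    n = grid.n_bins
    kernel = np.zeros(n)
    overflow = 0.0

    amounts = alpha * taus  # survivor-atom positions
    if A > 0:
        rate = A / alpha
        for start in range(0, taus.size, 1024):
            sl = slice(start, start + 1024)
            clipped = np.minimum(edges[None, :], amounts[sl, None])
            expo = np.exp(-rate * clipped)
            kernel += weights[sl] @ (expo[:, :-1] - expo[:, 1:])

    atom_mass = weights * np.exp(-A * taus)
    idx = np.minimum(np.floor(amounts / grid.bin_width).astype(int), n)
    inside = idx < n
    np.add.at(kernel, idx[inside], atom_mass[inside])
    overflow += atom_mass[~inside].sum()
    # continuous mass beyond z_max (only when alpha*tau > z_max)
    overflow += max(weights.sum() - kernel.sum() - overflow, 0.0)
    return MassVector(grid, kernel, overflow)


def narrow_age_distribution(tau: float, params: ModelParams, grid: ValueGrid) -> MassVector:
    """Distribution ``P(y, tau)`` of the amount synthesized by age ``tau``.

    Truncated exponential on [0, alpha*tau) plus the survivor atom
    ``exp(-A*tau)`` at ``y = alpha*tau``.  When the grid is too coarse to
    separate the atom from the origin (``alpha*tau < bin_width``) the two
    components share bin 0.
    """
    if tau < 0:
        raise ValueError(f"age must be >= 0, got {tau}")
    return _mixture_kernel(np.array([tau]), np.array([1.0]), params, grid)


def convolve_mass(f: MassVector, p: MassVector) -> MassVector:
    """Distribution of the sum of two independent amounts (discrete linear
    convolution of bin masses).  Mass landing beyond ``z_max``, plus any
    overflow carried by the inputs, accumulates in the result's overflow."""
    _require_same_grid(f, p)
    n = f.grid.n_bins
    full = np.convolve(f.mass, p.mass)
    mass = full[:n]
    overflow = max(1.0 - mass.sum(), 0.0)
    return MassVector(f.grid, mass, overflow)


def rescale_axis(phi: MassVector, s: float) -> MassVector:
    """Deterministic rescaling of the amount axis: mass at bin center ``z``
    moves to ``s * z``, split linearly between the two nearest bins.  Mass
    is conserved; the mean scales by ``s`` up to boundary clipping.  The
    input's overflow stays overflow (its position is unknown)."""
    if s < 0:
        raise ValueError(f"scale factor must be >= 0, got {s}")
    n = phi.grid.n_bins
    # target position in bin-center coordinates: s*(i+0.5) - 0.5
    pos = s * (np.arange(n) + 0.5) - 0.5
    lo = np.floor(pos).astype(int)
    frac = pos - lo
    out = np.zeros(n)
    for idx, part in ((lo, phi.mass * (1.0 - frac)), (lo + 1, phi.mass * frac)):
        below = idx < 0
        inside = (idx >= 0) & (idx < n)
        out[0] += part[below].sum()
        np.add.at(out, idx[inside], part[inside])
    overflow = phi.overflow + max(phi.mass.sum() - out.sum(), 0.0)
    return MassVector(phi.grid, out, overflow)


def apply_inactivation(phi: MassVector, k: float) -> MassVector:
    """Palliative enzyme inactivation: every amount shrinks toward 0 in
    proportion to its distance from the origin, ``z -> (1 - k) * z``.
    ``k = 0`` is the identity, ``k = 1`` collapses all mass into bin 0."""
    if not 0.0 <= k <= 1.0:
        raise ValueError(f"shrink fraction must lie in [0, 1], got {k}")
    if k == 0.0:
        return phi.copy()
    return rescale_axis(phi, 1.0 - k)


def rebin(phi: MassVector, new_grid: ValueGrid) -> MassVector:
    """Re-express a distribution on another uniform grid, treating the
    density as uniform within each source bin (exact interval-overlap
    apportioning via the cumulative mass)."""
    cum = np.concatenate(([0.0], np.cumsum(phi.mass)))
    new_cum = np.interp(new_grid.edges, phi.grid.edges, cum)
    mass = np.diff(new_cum)
    overflow = phi.overflow + max(phi.mass.sum() - mass.sum(), 0.0)
    return MassVector(new_grid, mass, overflow)
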