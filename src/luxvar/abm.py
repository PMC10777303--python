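"""Agent-based Monte-Carlo simulator of the same single-cell mechanism.

Each cell carries an inherited amount, a cycle length drawn as
``T = tau1 + Exp(C)`` and an operon shut-off time drawn as ``Exp(A)``
(infinite when A = 0).  At division both daughters receive half the
mother's content and draw fresh cycle and shut-off times.  The simulator
is the independent correctness oracle for the deterministic fixed-point
solver: it shares no code path with the convolution/quadrature machinery.

The population grows exponentially, so once it exceeds ``population_cap``
it is uniformly subsampled back to the cap; uniform subsampling is
unbiased for snapshot distributions in a branching population (every
lineage is equally likely to be retained), and the discarded growth factor
is retained in the bookkeeping so the growth rate remains measurable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model_core import MassVector, ModelParams, ValueGrid

__all__ = [
    "CellState",
    "AbmConfig",
    "AbmResult",
    "current_amount",
    "simulate_population",
    "snapshot_histogram",
    "compare_to_deterministic",
]


@dataclass
class CellState:
    """A single agent: inherited amount, current age, and the two draws
    that determine its fate (cycle length and operon shut-off time)."""

    inherited: float
    age: float
    cycle_length: float
    binding_time: float

    def __post_init__(self) -> None:
        if self.inherited < 0:
            raise ValueError("inherited amount must be >= 0")
        if not 0.0 <= self.age <= self.cycle_length:
            raise ValueError("age must lie in [0, cycle_length]")


@dataclass(frozen=True)
class AbmConfig:
    params: ModelParams
    n_initial: int = 50_000
    t_end: float = 12.0
    population_cap: int = 50_000
    seed: int = 0
    checkpoint_dt: float = 1.0

    def __post_init__(self) -> None:
        if self.n_initial < 1:
            raise ValueError("n_initial must be >= 1")
        if self.population_cap < max(2, self.n_initial):
            raise ValueError("population_cap must be >= max(2, n_initial)")
        if self.t_end <= 0 or self.checkpoint_dt <= 0:
            raise ValueError("t_end and checkpoint_dt must be > 0")


@dataclass
class AbmResult:
    """Snapshot of the population at ``t_end`` plus growth bookkeeping."""

    amounts: np.ndarray          # per-cell luciferase amount z at t_end
    ages: np.ndarray             # per-cell age at t_end
    checkpoint_times: np.ndarray
    log_population: np.ndarray   # log of (cells alive x discarded growth factor)
    division_ages: np.ndarray    # ages at division, events in the last 2 time units
    n_divisions: int
    config: AbmConfig = field(repr=False)

    def growth_rate(self, window: float | None = None) -> float:
        """Log-slope of the population-size trajectory (default: second half,
        after initial-condition transients)."""
        t, logn = self.checkpoint_times, self.log_population
        if window is None:
            window = self.config.t_end / 2.0
        sel = t >= self.config.t_end - window
        if sel.sum() < 2:
            raise ValueError("not enough checkpoints in the window")
        slope, _ = np.polyfit(t[sel], logn[sel], 1)
        return float(slope)


def current_amount(cell: CellState, alpha: float) -> float:
    """z = inherited + alpha * min(age, binding_time)."""
    if alpha <= 0:
        raise ValueError(f"synthesis rate must be > 0, got {alpha}")
    return cell.inherited + alpha * min(cell.age, cell.binding_time)


def _draw_binding(rng: np.random.Generator, A: float, size: int) -> np.ndarray:
    if A == 0.0:
        return np.full(size, np.inf)
    return rng.exponential(1.0 / A, size)


def simulate_population(cfg: AbmConfig) -> AbmResult:
    """Event-driven simulation, vectorized in rounds: all divisions due
    before the next checkpoint are processed together, in array order, so
    the run is bit-reproducible for a given seed."""
    p = cfg.params
    rng = np.random.default_rng(cfg.seed)

    n0 = cfg.n_initial
    inherited = np.zeros(n0)
    birth = np.zeros(n0)
    cycle = p.tau1 + rng.exponential(1.0 / p.C, n0)
    binding = _draw_binding(rng, p.A, n0)

    n_check = int(np.ceil(cfg.t_end / cfg.checkpoint_dt))
    checkpoints = np.minimum((np.arange(n_check) + 1) * cfg.checkpoint_dt, cfg.t_end)
    times = [0.0]
    log_pop = [np.log(n0)]
    log_factor = 0.0
    div_window_start = cfg.t_end - 2.0
    division_ages: list[np.ndarray] = []
    n_divisions = 0

    for tc in checkpoints:
        while True:
            t_div = birth + cycle
            due = t_div <= tc
            if not due.any():
                break
            n_divisions += int(due.sum())
            in_window = due & (t_div >= div_window_start)
            if in_window.any():
                division_ages.append(cycle[in_window].copy())

            z_mother = inherited[due] + p.alpha * np.minimum(cycle[due], binding[due])
            n_new = 2 * z_mother.size
            inherited = np.concatenate((inherited[~due], np.repeat(z_mother / 2.0, 2)))
            birth = np.concatenate((birth[~due], np.repeat(t_div[due], 2)))
            cycle = np.concatenate(
                (cycle[~due], p.tau1 + rng.exponential(1.0 / p.C, n_new))
            )
            binding = np.concatenate((binding[~due], _draw_binding(rng, p.A, n_new)))

            if inherited.size > cfg.population_cap:
                keep = np.sort(
                    rng.choice(inherited.size, cfg.population_cap, replace=False)
                )
                log_factor += np.log(inherited.size / cfg.population_cap)
                inherited, birth = inherited[keep], birth[keep]
                cycle, binding = cycle[keep], binding[keep]
        times.append(float(tc))
        log_pop.append(log_factor + np.log(inherited.size))

    ages = cfg.t_end - birth
    amounts = inherited + p.alpha * np.minimum(ages, binding)
    return AbmResult(
        amounts=amounts,
        ages=ages,
        checkpoint_times=np.array(times),
        log_population=np.array(log_pop),
        division_ages=(
            np.concatenate(division_ages) if division_ages else np.empty(0)
        ),
        n_divisions=n_divisions,
        config=cfg,
    )


def snapshot_histogram(amounts: np.ndarray, grid: ValueGrid) -> MassVector:
    """Normalized histogram of a per-cell amount sample on a value grid."""
    amounts = np.asarray(amounts, dtype=float)
    if amounts.size == 0:
        raise ValueError("empty sample")
    counts, _ = np.histogram(amounts, bins=grid.edges)
    overflow_count = int((amounts >= grid.z_max).sum())
    n = amounts.size
    return MassVector(grid, counts / n, overflow=overflow_count / n)


def compare_to_deterministic(
    abm_hist: MassVector, phi: MassVector
) -> tuple[float, float]:
    """L1 distance between an ABM snapshot histogram and the deterministic
    solution on the same grid, plus the difference in CV.  Returns
    ``(l1, cv_abm - cv_det)``."""
    from .steady_state import distribution_stats

    l1 = abm_hist.l1_distance(phi)
    dcv = distribution_stats(abm_hist).cv - distribution_stats(phi).cv
    return l1, dcv
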