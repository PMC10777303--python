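import numpy as np
import pytest

import luxvar as lv


@pytest.fixture(scope="session")
def calib_params() -> lv.ModelParams:
    """The calibration parameter set: constitutive synthesis, mean cycle = 1."""
    return lv.ModelParams(A=0.0, alpha=1.0, C=4.0, tau1=0.75)


@pytest.fixture(scope="session")
def fitted_params() -> lv.ModelParams:
    """The parameter set with the fitted binding intensity."""
    return lv.ModelParams(A=2.0, alpha=1.0, C=4.0, tau1=0.75)


@pytest.fixture(scope="session")
def calib_steady(calib_params) -> lv.SteadyState:
    state = lv.solve_fixed_point(calib_params)
    assert state.converged
    return state


@pytest.fixture(scope="session")
def fitted_steady(fitted_params) -> lv.SteadyState:
    state = lv.solve_fixed_point(fitted_params)
    assert state.converged
    return state


@pytest.fixture(scope="session")
def fitted_abm(fitted_params) -> lv.AbmResult:
    """One shared 50k-cell agent-based run at the fitted parameters."""
    cfg = lv.AbmConfig(
        params=fitted_params, n_initial=50_000, population_cap=50_000,
        t_end=12.0, seed=20240917,
    )
    return lv.simulate_population(cfg)


@pytest.fixture
def small_grid() -> lv.ValueGrid:
    return lv.ValueGrid(z_max=4.0, n_bins=64)


def coarsen(mv: lv.MassVector, n_bins: int = 256) -> lv.MassVector:
    return lv.rebin(mv, lv.ValueGrid(mv.grid.z_max, n_bins))


def make_mass(grid: lv.ValueGrid, rng: np.random.Generator) -> lv.MassVector:
    raw = rng.random(grid.n_bins)
    return lv.MassVector(grid, raw / raw.sum())
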