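"""Fixed point of the inheritance-synthesis loop and its moments."""

import numpy as np
import pytest

import luxvar as lv
from luxvar.model_core import _mixture_kernel
from luxvar.steady_state import age_conditional_distribution


def _point_mass_profile(params: lv.ModelParams, tau_star: float) -> lv.AgeProfile:
    """Age profile whose quadrature weights concentrate on one grid node."""
    profile = lv.age_profile(params)
    spike = np.zeros_like(profile.psi)
    idx = int(np.argmin(np.abs(profile.taus - tau_star)))
    spike[idx] = 1.0
    profile.psi = spike
    profile.omega_div = spike.copy()
    return profile


class TestAgeConditional:
    def test_newborn_with_nothing_inherited(self, small_grid):
        p = lv.ModelParams(A=2.0)
        f = lv.MassVector.point_mass(small_grid, 0.0)
        out = age_conditional_distribution(f, 0.0, p, small_grid)
        assert out.mass[0] == pytest.approx(1.0)

    def test_constitutive_is_deterministic_shift(self, small_grid):
        p = lv.ModelParams(A=0.0, alpha=1.0)
        f = lv.MassVector.point_mass(small_grid, 0.0)
        out = age_conditional_distribution(f, 1.0, p, small_grid)
        assert out.mass[small_grid.bin_index(1.0)] == pytest.approx(1.0)

    def test_inherited_atom_shifts_the_distribution(self, small_grid):
        p = lv.ModelParams(A=2.0, alpha=1.0)
        f0 = lv.MassVector.point_mass(small_grid, 0.0)
        base = age_conditional_distribution(f0, 1.0, p, small_grid)
        shift_bins = 8  # 0.5 amount units on this grid
        f = lv.MassVector(small_grid, np.roll(f0.mass, shift_bins))
        shifted = age_conditional_distribution(f, 1.0, p, small_grid)
        np.testing.assert_allclose(
            shifted.mass[shift_bins:], base.mass[:-shift_bins], atol=1e-12
        )


class TestCompose:
    def test_point_mass_age_structure_degenerates(self, small_grid):
        p = lv.ModelParams(A=2.0)
        profile = _point_mass_profile(p, 0.75)
        tau_star = profile.taus[int(np.argmax(profile.psi))]
        f = lv.MassVector.point_mass(small_grid, 0.5)
        composed = lv.compose_population(f, profile, p, small_grid)
        direct = age_conditional_distribution(f, float(tau_star), p, small_grid)
        np.testing.assert_allclose(composed.mass, direct.mass, atol=1e-12)

    def test_matches_explicit_age_quadrature(self):
        """Kernel composition equals the term-by-term quadrature of
        f * P(., tau) — the linearity identity behind the fast path."""
        p = lv.ModelParams(A=2.0)
        grid = lv.ValueGrid(z_max=4.0, n_bins=128)
        profile = lv.age_profile(p, lv.AgeGrid(tau_max=4.0, n_steps=64))
        rng = np.random.default_rng(11)
        raw = rng.random(grid.n_bins)
        f = lv.MassVector(grid, raw / raw.sum())
        composed = lv.compose_population(f, profile, p, grid)
        weights = profile.psi_weights
        explicit = sum(
            w * age_conditional_distribution(f, float(t), p, grid).mass
            for t, w in zip(profile.taus, weights)
        )
        np.testing.assert_allclose(composed.mass, explicit, atol=1e-10)

    def test_constitutive_composition_is_age_scaling(self, calib_params):
        """With A = 0 and an empty newborn, Phi is the distribution of
        alpha*tau with tau drawn from Psi — checked against sampled ages."""
        grid = lv.default_value_grid(calib_params)
        profile = lv.age_profile(calib_params)
        f = lv.MassVector.point_mass(grid, 0.0)
        composed = lv.compose_population(f, profile, calib_params, grid)
        rng = np.random.default_rng(12)
        taus = rng.choice(profile.taus, size=200_000, p=profile.psi_weights)
        sampled = np.histogram(calib_params.alpha * taus, bins=grid.edges)[0] / taus.size
        coarse = lv.ValueGrid(grid.z_max, 64)
        a = lv.rebin(composed, coarse)
        b = lv.rebin(lv.MassVector(grid, sampled, 1 - sampled.sum()), coarse)
        assert a.l1_distance(b) < 0.02

    def test_dividing_cells_are_older_on_average(self, calib_steady, calib_params):
        grid = calib_steady.phi_population.grid
        profile = lv.age_profile(calib_params)
        phi_div = lv.compose_dividing(
            calib_steady.f_newborn, profile, calib_params, grid
        )
        assert phi_div.mean() > calib_steady.phi_population.mean()

    def test_composition_is_normalized(self, calib_steady):
        assert calib_steady.phi_population.total == pytest.approx(1.0, abs=1e-8)
        assert calib_steady.phi_dividing.total == pytest.approx(1.0, abs=1e-8)


class TestHalveAtDivision:
    def test_atom_halves(self, small_grid):
        phi = lv.MassVector.point_mass(small_grid, 2.0)
        out = lv.halve_at_division(phi)
        assert out.mean() == pytest.approx(1.0, abs=small_grid.bin_width)

    def test_uniform_rescales(self, small_grid):
        uniform = lv.MassVector(small_grid, np.full(64, 1 / 64))
        out = lv.halve_at_division(uniform)
        # all mass below 2 afterwards, mean halved
        assert out.mass[small_grid.bin_index(2.0) + 1:].sum() < 1e-12
        assert out.mean() == pytest.approx(uniform.mean() / 2, abs=small_grid.bin_width)

    def test_mean_exactly_halved_by_interpolation(self, small_grid):
        rng = np.random.default_rng(13)
        raw = rng.random(64)
        phi = lv.MassVector(small_grid, raw / raw.sum())
        out = lv.halve_at_division(phi)
        assert out.total == pytest.approx(1.0, abs=1e-9)
        assert out.mean() == pytest.approx(phi.mean() / 2, abs=small_grid.bin_width)


class TestGenerationMap:
    def test_deterministic_recursion_with_point_masses(self, small_grid):
        """A = 0 with a degenerate dividing age T: x -> (x + alpha*T)/2,
        whose fixed point is alpha*T."""
        p = lv.ModelParams(A=0.0, alpha=1.0)
        profile = _point_mass_profile(p, 1.0)
        T = float(profile.taus[int(np.argmax(profile.omega_div))])
        f = lv.MassVector.point_mass(small_grid, 0.5)
        expected_mean = 0.5
        for _ in range(25):
            f = lv.generation_map(f, p, profile, small_grid)
            expected_mean = 0.5 * (expected_mean + p.alpha * T)
            assert f.mean() == pytest.approx(expected_mean, abs=3 * small_grid.bin_width)
        assert f.mean() == pytest.approx(p.alpha * T, abs=3 * small_grid.bin_width)

    def test_preserves_normalization(self, calib_params):
        grid = lv.default_value_grid(calib_params)
        profile = lv.age_profile(calib_params)
        f = lv.MassVector.point_mass(grid, 0.0)
        out = lv.generation_map(f, calib_params, profile, grid)
        assert out.total == pytest.approx(1.0, abs=1e-9)


class TestSolveFixedPoint:
    def test_constitutive_moment_identities(self, calib_steady, calib_params):
        """At A = 0: E[x] = alpha E_Omega[T], Var[x] = alpha^2 Var_Omega[T]/3,
        E[z] = E[x] + alpha E_Psi[tau]."""
        p = calib_params
        mu = calib_steady.mu
        dz = calib_steady.f_newborn.grid.bin_width
        e_T = p.tau1 + 1.0 / (mu + p.C)
        var_T = 1.0 / (mu + p.C) ** 2
        profile = lv.age_profile(p)

        f_stats = lv.distribution_stats(calib_steady.f_newborn)
        assert f_stats.mean == pytest.approx(p.alpha * e_T, abs=2 * dz)
        assert f_stats.sd**2 == pytest.approx(p.alpha**2 * var_T / 3.0, abs=2 * dz)

        z_stats = lv.distribution_stats(calib_steady.phi_population)
        assert z_stats.mean == pytest.approx(
            f_stats.mean + p.alpha * profile.mean_age(), abs=2 * dz
        )

    def test_residuals_contract_geometrically(self, calib_steady):
        hist = np.array(calib_steady.residual_history)
        assert (np.diff(hist[3:]) < 0).all()
        # asymptotic ratio ~0.5 (variance halves per generation)
        ratios = hist[10:20] / hist[9:19]
        assert ratios.max() < 0.75

    def test_fixed_point_is_initialization_independent(self, calib_params, calib_steady):
        grid = calib_steady.f_newborn.grid
        alt = lv.solve_fixed_point(
            calib_params,
            initial=lv.MassVector.point_mass(grid, 2.0 * calib_params.alpha),
        )
        assert alt.converged
        assert alt.f_newborn.l1_distance(calib_steady.f_newborn) < 1e-6

    def test_nonconvergence_is_explicit(self, calib_params):
        state = lv.solve_fixed_point(calib_params, max_iter=1)
        assert not state.converged
        assert state.final_residual > 1e-8
        assert state.n_iterations == 1

    def test_synthesis_increases_mean_over_inherited(self, fitted_steady):
        assert fitted_steady.phi_population.mean() > fitted_steady.f_newborn.mean()

    def test_large_binding_intensity_quenches_the_mean(self, calib_steady):
        """Synthesis window ~1/A: at A = 50 the steady mean collapses to
        under a tenth of the constitutive mean."""
        dim = lv.solve_fixed_point(lv.ModelParams(A=50.0))
        assert dim.converged
        assert dim.phi_population.mean() <= 0.1 * calib_steady.phi_population.mean()

    def test_cv_stable_under_grid_refinement(self, calib_params, calib_steady):
        cv_2048 = lv.distribution_stats(calib_steady.phi_population).cv
        fine = lv.solve_fixed_point(
            calib_params, value_grid=lv.ValueGrid(z_max=8.0, n_bins=4096)
        )
        cv_4096 = lv.distribution_stats(fine.phi_population).cv
        assert abs(cv_2048 - cv_4096) < 0.005


class TestDistributionStats:
    def test_two_atom_moments(self):
        grid = lv.ValueGrid(z_max=4.0, n_bins=8)  # centers 0.25, 0.75, ...
        mass = np.zeros(8)
        mass[grid.bin_index(1.0)] = 0.5
        mass[grid.bin_index(3.0)] = 0.5
        stats = lv.distribution_stats(lv.MassVector(grid, mass))
        assert stats.mean == pytest.approx(2.0, abs=grid.bin_width)
        assert stats.sd == pytest.approx(1.0, abs=grid.bin_width)
        assert stats.cv == pytest.approx(0.5, abs=0.1)

    def test_atom_has_zero_cv(self, small_grid):
        stats = lv.distribution_stats(lv.MassVector.point_mass(small_grid, 2.0))
        assert stats.cv == pytest.approx(0.0, abs=1e-12)

    def test_exponential_cv_is_one(self):
        grid = lv.ValueGrid(z_max=30.0, n_bins=8192)
        edges = grid.edges
        mass = np.exp(-edges[:-1]) - np.exp(-edges[1:])
        stats = lv.distribution_stats(lv.MassVector(grid, mass, 1 - mass.sum()))
        assert stats.cv == pytest.approx(1.0, abs=0.01)

    def test_zero_mean_rejected(self, small_grid):
        all_overflow = lv.MassVector(small_grid, np.zeros(64), overflow=1.0)
        with pytest.raises(ValueError):
            lv.distribution_stats(all_overflow)
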