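"""Deterministic and stochastic simulators of the two-site kinetics."""

import numpy as np
import pytest

from coopdiscern import (
    IBParams,
    NCParams,
    SimulationGrid,
    default_doses,
    default_times,
    simulate_gillespie,
    simulate_ode,
    smooth_dose_curve,
    theta_eq_ib,
    theta_eq_nc,
    nc_to_ib,
)


class TestOde:
    def test_empty_initial_condition(self):
        grid = SimulationGrid(np.array([0.1, 1.0, 10.0]), np.array([0.0, 1.0]))
        data = simulate_ode(NCParams(1, 1, 0.5), grid)
        assert np.all(data.theta[:, 0] == 0.0)

    def test_long_time_limit_matches_equilibrium(self):
        grid = SimulationGrid(default_doses(80), np.array([0.0, 1e3, 1e4]))
        nc = NCParams(k=1, l=1, omega=0.5)
        data = simulate_ode(nc, grid)
        assert np.max(np.abs(data.theta[:, -1] - theta_eq_nc(grid.doses, 1, 0.5))) < 1e-6
        ib = IBParams(k10=2, k01=0.5, l10=1, l01=1)
        datb = simulate_ode(ib, grid)
        eq = theta_eq_ib(grid.doses, ib.K10, ib.K01)
        assert np.max(np.abs(datb.theta[:, -1] - eq)) < 1e-6

    def test_single_site_relaxation_closed_form(self):
        # identical independent sites behave per-site as one Langmuir site:
        # theta(t) = (L/(K+L)) (1 - exp(-(kL+l) t)); at L=K=1 -> 0.5(1-e^-2t)
        grid = SimulationGrid(np.array([0.5, 1.0, 2.0]), default_times(40))
        data = simulate_ode(IBParams(1, 1, 1, 1), grid)
        expected = 0.5 * (1 - np.exp(-2.0 * grid.times))
        assert np.max(np.abs(data.theta[1] - expected)) < 1e-10

    def test_monotone_in_time_and_bounded(self):
        grid = SimulationGrid(default_doses(40), default_times(40))
        for model in (NCParams(3, 0.2, 0.07), IBParams(5, 0.1, 1, 0.3)):
            th = simulate_ode(model, grid).theta
            assert np.all((th >= 0) & (th <= 1))
            assert np.all(np.diff(th, axis=1) >= -1e-9)

    def test_manifold_pair_shares_equilibrium_curve(self):
        # paired NC/IB kinetics converge to the same dose-response for t > 1e3
        K10, K01 = nc_to_ib(1.0, 0.1)
        nc = NCParams(k=1, l=1, omega=0.1)
        ib = IBParams(k10=1 / K10, k01=1 / K01, l10=1, l01=1)
        grid = SimulationGrid(default_doses(60), np.array([0.0, 5e3]))
        a = simulate_ode(nc, grid).theta[:, -1]
        b = simulate_ode(ib, grid).theta[:, -1]
        assert np.max(np.abs(a - b)) < 1e-6


class TestGillespie:
    def test_requires_finite_r0(self):
        grid = SimulationGrid(np.array([1.0, 2.0]), np.array([0.0, 1.0]))
        with pytest.raises(ValueError):
            simulate_gillespie(NCParams(1, 1, 0.5), grid, seed=0)
        with pytest.raises(ValueError):
            SimulationGrid(np.array([1.0, 2.0]), np.array([0.0, 1.0]), r0=0)

    def test_single_receptor_occupancy_levels(self):
        grid = SimulationGrid(
            np.array([0.5, 5.0]), np.array([0.0, 0.1, 1.0, 10.0]), r0=1
        )
        data = simulate_gillespie(NCParams(1, 1, 0.5), grid, seed=11)
        assert set(np.unique(data.theta)) <= {0.0, 0.5, 1.0}

    def test_seed_determinism(self):
        grid = SimulationGrid(default_doses(8, 1e-2, 1e4), default_times(15), r0=50)
        a = simulate_gillespie(IBParams(1, 0.3, 2, 0.5), grid, seed=42)
        b = simulate_gillespie(IBParams(1, 0.3, 2, 0.5), grid, seed=42)
        c = simulate_gillespie(IBParams(1, 0.3, 2, 0.5), grid, seed=43)
        assert np.array_equal(a.theta, b.theta)
        assert not np.array_equal(a.theta, c.theta)

    def test_equilibrium_mean_within_binomial_error(self):
        # mean over seeds at t >> 1/l sits at the analytic equilibrium
        # within the binomial envelope of R0=1000 receptors
        grid = SimulationGrid(np.array([1.0, 2.0]), np.array([0.0, 1e3]), r0=1000)
        nc = NCParams(1, 1, 0.5)
        p = theta_eq_nc(1.0, 1.0, 0.5)
        vals = [
            simulate_gillespie(nc, grid, seed=s).theta[0, -1] for s in range(30)
        ]
        tol = 3 * np.sqrt(p * (1 - p) / 1000)
        assert abs(np.mean(vals) - p) < tol

    def test_mean_converges_to_ode(self):
        # weak convergence of the SSA average to the mass-action solution
        grid = SimulationGrid(
            np.array([0.3, 1.0, 3.0]), np.array([0.0, 0.3, 1.0, 3.0]), r0=200
        )
        model = NCParams(1, 1, 0.2)
        det = simulate_ode(model, SimulationGrid(grid.doses, grid.times))
        mean = np.mean(
            [simulate_gillespie(model, grid, seed=s).theta for s in range(60)],
            axis=0,
        )
        # MC error ~ sqrt(theta(1-theta)/(2 R0 n_rep)) ~ 2.5e-3
        assert np.max(np.abs(mean - det.theta)) < 0.012


class TestSmoothing:
    def test_window_one_is_identity(self, rng):
        y = rng.random(31)
        assert np.array_equal(smooth_dose_curve(y, 1), y)

    def test_constant_curve_fixed_point(self):
        y = np.full(21, 0.37)
        assert np.allclose(smooth_dose_curve(y, 5), y)

    def test_noiseless_curve_barely_changed_on_fine_grid(self):
        L = np.logspace(-3, 5, 1000)
        y = theta_eq_nc(L, 1.0, 0.5)
        assert np.max(np.abs(smooth_dose_curve(y, 5) - y)) < 1e-3

    def test_matches_direct_moving_average_interior(self, rng):
        y = rng.random(50)
        out = smooth_dose_curve(y, 5)
        direct = np.convolve(y, np.ones(5) / 5, mode="valid")
        assert np.allclose(out[2:-2], direct)

    @pytest.mark.parametrize("window", [0, 2, 4])
    def test_even_or_zero_window_rejected(self, window):
        with pytest.raises(ValueError):
            smooth_dose_curve(np.ones(9), window)

    def test_window_longer_than_curve_rejected(self):
        with pytest.raises(ValueError):
            smooth_dose_curve(np.ones(3), 5)
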