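"""EC levels, dynamic range, and target-curve feature extraction."""

import numpy as np
import pytest

from coopdiscern import (
    NCParams,
    SimulationGrid,
    SINGLE_SITE_DYNR,
    default_doses,
    default_times,
    dynr,
    ec_level,
    hill_from_dynr,
    occupancy,
    simulate_ode,
    target_curve,
    theta_eq_nc,
)
from coopdiscern.metrics import TargetCurve, classify_shape, dynr_initial, inflection_time

#: DynR(t->0) of identical independent sites: the early dose curve is
#: 1 - exp(-kLt), so EC10/EC90 solve exp(-x) = 0.9 / 0.1 and
#: DynR = log10(ln 10 / ln(10/9)).
EARLY_SINGLE_SITE_DYNR = float(np.log10(np.log(10.0) / np.log(10.0 / 9.0)))


class TestOccupancy:
    @pytest.mark.parametrize(
        "states, expected",
        [((0, 0, 0, 10), 0.0), ((0, 0, 100, 100), 1.0), ((10, 20, 35, 100), 0.5)],
    )
    def test_values(self, states, expected):
        R10, R01, R11, R0 = states
        assert occupancy(R10, R01, R11, R0) == expected

    def test_conservation_enforced(self):
        with pytest.raises(ValueError):
            occupancy(60, 50, 0, 100)
        with pytest.raises(ValueError):
            occupancy(-1, 0, 0, 10)


class TestEcLevel:
    def test_langmuir_inversion(self):
        L = np.logspace(-4, 4, 2000)
        y = L / (1 + L)
        assert ec_level(L, y, 0.5) == pytest.approx(1.0, rel=1e-3)
        assert ec_level(L, y, 0.1) == pytest.approx(1 / 9, rel=1e-3)
        assert ec_level(L, y, 0.9) == pytest.approx(9.0, rel=1e-3)

    def test_unreached_level_is_undefined_signal(self):
        L = np.logspace(-2, 2, 50)
        y = 0.6 * L / (1 + L)  # saturates at 0.6
        assert np.isnan(ec_level(L, y, 0.9))

    def test_crossing_below_grid_is_undefined(self):
        L = np.logspace(0, 4, 50)
        y = L / (0.001 + L)  # EC10 far below the bottom dose
        assert np.isnan(ec_level(L, y, 0.1))

    def test_invalid_level(self):
        with pytest.raises(ValueError):
            ec_level(np.array([1.0, 2.0]), np.array([0.1, 0.9]), 1.5)


class TestDynr:
    def test_single_site_reference(self):
        assert dynr(1 / 9, 9.0) == pytest.approx(SINGLE_SITE_DYNR)
        assert SINGLE_SITE_DYNR == pytest.approx(1.908, abs=5e-4)

    def test_equal_ecs(self):
        assert dynr(2.0, 2.0) == 0.0

    def test_nc_equilibrium_example(self):
        # quadratic inversion of the NC isotherm at K=1, omega=0.01:
        # theta = 0.1 -> L = 0.124831..., theta = 0.9 -> L = 801.123...
        L = np.logspace(-4, 5, 20000)
        y = theta_eq_nc(L, 1.0, 0.01)
        e10, e90 = ec_level(L, y, 0.1), ec_level(L, y, 0.9)
        assert e10 == pytest.approx(0.12483, rel=1e-3)
        assert e90 == pytest.approx(801.12, rel=1e-3)
        assert dynr(e10, e90) == pytest.approx(3.807, abs=2e-3)

    def test_nan_propagates(self):
        assert np.isnan(dynr(float("nan"), 9.0))

    def test_hill_correspondence(self):
        assert hill_from_dynr(SINGLE_SITE_DYNR) == pytest.approx(1.0)
        assert hill_from_dynr(3.8074) == pytest.approx(0.501, abs=2e-3)
        assert hill_from_dynr(SINGLE_SITE_DYNR / 2) == pytest.approx(2.0)
        with pytest.raises(ValueError):
            hill_from_dynr(0.0)


def _curve(times, values):
    times = np.asarray(times, float)
    values = np.asarray(values, float)
    return TargetCurve(times=times, dynr=values, valid=np.isfinite(values))


class TestShapeAndFeatures:
    def test_strictly_monotone_shapes(self):
        t = np.logspace(-3, 3, 40)
        up = _curve(t, np.linspace(1.5, 3.0, 40))
        down = _curve(t, np.linspace(3.0, 1.5, 40))
        assert classify_shape(up) == "increasing"
        assert classify_shape(down) == "decreasing"

    def test_biphasic_detected(self):
        t = np.logspace(-3, 3, 41)
        y = np.concatenate([np.linspace(1.5, 3.0, 21), np.linspace(2.95, 1.8, 20)])
        assert classify_shape(_curve(t, y)) == "biphasic"

    def test_flat_counts_as_increasing(self):
        t = np.logspace(-3, 3, 30)
        assert classify_shape(_curve(t, np.full(30, 1.9))) == "increasing"

    def test_too_few_points(self):
        with pytest.raises(ValueError):
            classify_shape(_curve([1, 2, 3], [1, 2, 3]))

    def test_dynr_initial_plateau_flag(self):
        t = np.logspace(-3, 3, 30)
        flat = _curve(t, np.full(30, SINGLE_SITE_DYNR))
        assert dynr_initial(flat) == (pytest.approx(1.908, abs=1e-3), True)
        steep = _curve(t, np.concatenate([[2.0, 2.5, 3.1], np.full(27, 3.2)]))
        value, reliable = dynr_initial(steep)
        assert value == 2.0 and not reliable

    def test_inflection_of_symmetric_sigmoid(self):
        # DynR(t) = a + b / (1 + (t/tau)^-c) has its log-time inflection at tau
        t = np.logspace(-4, 4, 120)
        tau, c = 3.7, 1.4
        y = 1.9 + 1.2 / (1 + (t / tau) ** (-c))
        curve = _curve(t, y)
        curve.shape = "increasing"
        assert inflection_time(curve) == pytest.approx(tau, rel=0.05)

    def test_inflection_time_rescaling_covariance(self):
        t = np.logspace(-4, 4, 120)
        y = 1.9 + 1.2 / (1 + (t / 2.0) ** (-1.1))
        for s in (1.0, 8.0):
            curve = _curve(t * s, y)
            curve.shape = "increasing"
            assert inflection_time(curve) == pytest.approx(2.0 * s, rel=0.05)

    def test_non_increasing_curve_has_no_inflection(self):
        t = np.logspace(-3, 3, 40)
        curve = _curve(t, np.linspace(3.0, 1.5, 40))
        curve.shape = classify_shape(curve)
        assert np.isnan(inflection_time(curve))


@pytest.fixture(scope="module")
def single_site():
    grid = SimulationGrid(default_doses(250), default_times(60))
    return target_curve(simulate_ode(NCParams(1, 1, 1.0), grid))


class TestTargetCurve:
    def test_single_site_limits(self, single_site):
        # rises from the early-kinetics value to log10(81) at equilibrium
        assert single_site.dynr_final == pytest.approx(1.908, abs=5e-3)
        assert single_site.dynr_initial == pytest.approx(
            EARLY_SINGLE_SITE_DYNR, abs=5e-3
        )
        assert single_site.shape == "increasing"
        assert single_site.dynr_initial_reliable

    def test_nc_final_value_and_shape(self):
        grid = SimulationGrid(default_doses(250), default_times(60))
        curve = target_curve(simulate_ode(NCParams(1, 1, 0.01), grid))
        assert curve.shape == "increasing"
        assert curve.dynr_final == pytest.approx(3.807, abs=5e-3)

    def test_inflection_ordered_by_unbinding_rate(self):
        grid = SimulationGrid(default_doses(200), default_times(60))
        tips = {
            l: target_curve(simulate_ode(NCParams(l, l, 0.05), grid)).t_ip
            for l in (1.0, 10.0)
        }  # k scaled with l so K stays 1
        assert tips[10.0] < tips[1.0]

    def test_requires_minimum_grid(self):
        grid = SimulationGrid(np.array([0.5, 1, 2, 4]), default_times(20))
        data = simulate_ode(NCParams(1, 1, 0.5), grid)
        with pytest.raises(ValueError):
            target_curve(data)

    def test_validity_mask_when_saturation_late(self):
        # early times cannot reach 90% on a narrow dose range -> masked
        grid = SimulationGrid(default_doses(40, 1e-3, 1e2), default_times(40))
        curve = target_curve(simulate_ode(NCParams(0.1, 0.1, 0.5), grid))
        assert not curve.valid.all()
        assert curve.valid.any()
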