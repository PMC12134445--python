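"""Closed-form mathematics: normalisation, budgets, prediction, inversion.

Independent oracles: scipy adaptive quadrature for the ramp integral and
scipy root-finding for the cross-acclimation predictor; the implementation
never calls either.
"""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import integrate, optimize

from thermoscale import (
    HeatingAssay,
    RescaledTolerance,
    TemperatureTrajectory,
    ThermalConstants,
    acclimation_response_ratio,
    compute_beta,
    from_normalized,
    heating_tolerance,
    invert_critical_temperature,
    normalize_temperature,
    predict_heating_tolerance,
    predict_tc_surface,
    rate_transfer,
    rescaled_tolerance,
    rescaled_tolerance_trajectory,
)

T_K = 273.15


def quad_budget(t_a, t_c, rate, beta):
    """Oracle: adaptive quadrature of e^{beta*tau(t)} over the linear ramp."""
    f = lambda t: math.exp(beta * (t_a + rate * t) / T_K)
    value, _ = integrate.quad(f, 0.0, (t_c - t_a) / rate, epsabs=0, epsrel=1e-12)
    return value


class TestNormalisation:
    @pytest.mark.parametrize("celsius, tau", [(0.0, 0.0), (273.15, 1.0), (27.315, 0.1)])
    def test_examples(self, celsius, tau, constants):
        assert normalize_temperature(celsius, constants) == pytest.approx(tau, abs=1e-15)

    @given(st.floats(-80, 200))
    @settings(max_examples=50, derandomize=True)
    def test_round_trip(self, celsius):
        constants = ThermalConstants()
        assert from_normalized(normalize_temperature(celsius, constants),
                               constants) == pytest.approx(celsius, rel=1e-14)


class TestBeta:
    def test_default_value(self):
        # 0.66 / (8.617333262e-5 * 273.15), confirmed by direct arithmetic
        assert compute_beta() == pytest.approx(28.039472671982747, rel=1e-12)

    def test_zero_activation_energy(self):
        assert compute_beta(0.0) == 0.0

    def test_linear_in_activation_energy(self):
        assert compute_beta(1.32) == pytest.approx(2 * compute_beta(0.66), rel=1e-14)

    @pytest.mark.parametrize("kwargs", [{"boltzmann": 0.0}, {"boltzmann": -1.0},
                                        {"reference_temp": 0.0},
                                        {"activation_energy": -0.1}])
    def test_invalid_inputs(self, kwargs):
        with pytest.raises(ValueError):
            compute_beta(**{"activation_energy": 0.66, "boltzmann": 8.617333262e-5,
                            "reference_temp": 273.15, **kwargs})

    def test_constants_hold_beta_invariant(self, constants):
        assert constants.beta == constants.activation_energy / (
            constants.boltzmann * constants.reference_temp)


class TestHeatingTolerance:
    @pytest.mark.parametrize("ta, tc, h", [(10, 30, 20), (25, 25, 0), (15.0, 38.5, 23.5)])
    def test_examples(self, ta, tc, h):
        assert heating_tolerance(ta, tc) == pytest.approx(h)

    def test_inverted_assay_rejected(self):
        with pytest.raises(ValueError, match="invalid assay"):
            heating_tolerance(30, 10)
        with pytest.raises(ValueError):
            HeatingAssay("x", 30.0, 10.0, 0.1)

    def test_nonpositive_rate_rejected(self):
        with pytest.raises(ValueError, match="heating rate"):
            HeatingAssay("x", 10.0, 30.0, 0.0)


class TestRescaledTolerance:
    def test_worked_example_matches_quadrature(self, constants):
        assay = HeatingAssay("x", 10.0, 30.0, 0.1)
        result = rescaled_tolerance(assay, constants)
        oracle = quad_budget(10.0, 30.0, 0.1, constants.beta)
        assert result.value == pytest.approx(oracle, rel=1e-9)
        assert result.value == pytest.approx(1.8468e3, rel=1e-4)

    def test_zero_beta_limit_is_duration(self):
        constants = ThermalConstants(activation_energy=0.0)
        assay = HeatingAssay("x", 10.0, 30.0, 0.1)
        assert rescaled_tolerance(assay, constants).value == pytest.approx(
            assay.duration, rel=1e-14)

    def test_additive_in_temperature_span(self, constants):
        whole = rescaled_tolerance(HeatingAssay("x", 10, 30, 0.2), constants).value
        first = rescaled_tolerance(HeatingAssay("x", 10, 20, 0.2), constants).value
        second = rescaled_tolerance(HeatingAssay("x", 20, 30, 0.2), constants).value
        assert whole == pytest.approx(first + second, rel=1e-12)

    def test_degenerate_assay_flagged_with_zero_budget(self, constants):
        assay = HeatingAssay("x", 20.0, 20.0, 0.5)
        assert assay.is_degenerate
        assert rescaled_tolerance(assay, constants).value == 0.0

    @given(beta=st.floats(0.0, 40.0),
           t_a=st.floats(-5.0, 40.0),
           h=st.floats(0.01, 50.0),
           rate=st.floats(1e-3, 10.0))
    @settings(max_examples=200, derandomize=True, deadline=None)
    def test_closed_form_matches_quadrature_everywhere(self, beta, t_a, h, rate):
        constants = ThermalConstants(activation_energy=beta * 8.617333262e-5 * T_K)
        value = rescaled_tolerance(HeatingAssay("x", t_a, t_a + h, rate),
                                   constants).value
        assert value == pytest.approx(quad_budget(t_a, t_a + h, rate, constants.beta),
                                      rel=1e-9)

    def test_negative_budget_rejected(self):
        with pytest.raises(ValueError):
            RescaledTolerance(value=-1.0, beta_used=28.0, lambda_used=1e-3)


class TestTrajectory:
    def test_constant_hold(self, constants):
        traj = TemperatureTrajectory([0.0, 7.0], [25.0, 25.0])
        expected = 7.0 * math.exp(constants.beta * 25.0 / T_K)
        assert rescaled_tolerance_trajectory(traj, constants).value == pytest.approx(
            expected, rel=1e-12)

    def test_two_sample_ramp_equals_closed_form(self, constants):
        assay = HeatingAssay("x", 10.0, 30.0, 0.1)
        traj = TemperatureTrajectory([0.0, assay.duration], [10.0, 30.0])
        assert rescaled_tolerance_trajectory(traj, constants).value == pytest.approx(
            rescaled_tolerance(assay, constants).value, rel=1e-12)

    def test_dense_sampling_of_linear_ramp_is_exact(self, constants):
        assay = HeatingAssay("x", 5.0, 35.0, 0.25)
        times = np.linspace(0.0, assay.duration, 57)
        traj = TemperatureTrajectory(times, 5.0 + 0.25 * times)
        assert rescaled_tolerance_trajectory(traj, constants).value == pytest.approx(
            rescaled_tolerance(assay, constants).value, rel=1e-12)

    def test_nonlinear_ramp_converges_to_quadrature(self, constants):
        # quadratic heating profile; piecewise-linear approx must converge
        profile = lambda t: 10.0 + 0.02 * t ** 2
        f = lambda t: math.exp(constants.beta * profile(t) / T_K)
        oracle, _ = integrate.quad(f, 0.0, 30.0, epsabs=0, epsrel=1e-12)
        times = np.linspace(0.0, 30.0, 3001)
        value = rescaled_tolerance_trajectory(
            TemperatureTrajectory(times, profile(times)), constants).value
        assert value == pytest.approx(oracle, rel=1e-6)

    @pytest.mark.parametrize("times, temps", [
        ([0.0], [10.0]),
        ([0.0, 1.0, 1.0], [10.0, 11.0, 12.0]),
        ([0.0, 2.0, 1.0], [10.0, 11.0, 12.0]),
    ])
    def test_invalid_trajectories_rejected(self, times, temps):
        with pytest.raises(ValueError):
            TemperatureTrajectory(times, temps)


class TestPredictHeatingTolerance:
    def test_identity_at_same_acclimation(self, constants):
        assert predict_heating_tolerance(20.0, 10.0, 10.0, constants) == pytest.approx(
            20.0, abs=1e-12)

    def test_worked_example_matches_root_finding_oracle(self, constants):
        # oracle: solve the budget-conservation equation numerically
        lam = 0.1 / T_K
        budget = lambda ta, h: (math.exp(constants.beta * (ta + h) / T_K)
                                - math.exp(constants.beta * ta / T_K)) / (constants.beta * lam)
        target = budget(10.0, 20.0)
        oracle = optimize.brentq(lambda h: budget(20.0, h) - target, 1e-9, 50.0,
                                 xtol=1e-13)
        predicted = predict_heating_tolerance(20.0, 10.0, 20.0, constants)
        assert predicted == pytest.approx(oracle, abs=1e-9)
        assert predicted == pytest.approx(12.016, abs=1e-3)

    @given(h1=st.floats(0.5, 40.0), t_a1=st.floats(0.0, 30.0),
           t_a2=st.floats(0.0, 30.0))
    @settings(max_examples=200, derandomize=True)
    def test_budget_conservation(self, h1, t_a1, t_a2):
        constants = ThermalConstants()
        h2 = predict_heating_tolerance(h1, t_a1, t_a2, constants)
        b1 = rescaled_tolerance(HeatingAssay("x", t_a1, t_a1 + h1, 0.1), constants)
        b2 = rescaled_tolerance(HeatingAssay("x", t_a2, t_a2 + h2, 0.1), constants)
        assert b2.value == pytest.approx(b1.value, rel=1e-9)

    @given(h1=st.floats(0.5, 40.0), t_a1=st.floats(0.0, 30.0),
           t_a2=st.floats(0.0, 30.0))
    @settings(max_examples=100, derandomize=True)
    def test_round_trip(self, h1, t_a1, t_a2):
        constants = ThermalConstants()
        h2 = predict_heating_tolerance(h1, t_a1, t_a2, constants)
        assert predict_heating_tolerance(h2, t_a2, t_a1, constants) == pytest.approx(
            h1, abs=1e-10)

    def test_strictly_decreasing_in_target_acclimation(self, constants):
        grid = np.linspace(0.0, 35.0, 36)
        values = [predict_heating_tolerance(20.0, 10.0, ta, constants) for ta in grid]
        assert all(a > b for a, b in zip(values, values[1:]))

    def test_zero_beta_limit(self):
        constants = ThermalConstants(activation_energy=0.0)
        assert predict_heating_tolerance(20.0, 10.0, 25.0, constants) == 20.0

    def test_small_beta_tends_to_identity(self):
        h_ref = 20.0
        for energy in (1e-3, 1e-5):
            constants = ThermalConstants(activation_energy=energy)
            h2 = predict_heating_tolerance(h_ref, 10.0, 25.0, constants)
            assert abs(h2 - h_ref) < 2 * abs(
                predict_heating_tolerance(h_ref, 10.0, 25.0,
                                          ThermalConstants(activation_energy=10 * energy))
                - h_ref)

    def test_large_beta_no_overflow(self):
        constants = ThermalConstants(activation_energy=50.0)  # beta ~ 2124
        h2 = predict_heating_tolerance(40.0, 0.0, 35.0, constants)
        assert np.isfinite(h2) and h2 > 0


class TestInversion:
    def test_zero_budget_returns_acclimation_temp(self, constants):
        budget = RescaledTolerance(0.0, constants.beta, 0.1 / T_K)
        assert invert_critical_temperature(12.0, 0.1, budget, constants) == 12.0

    @given(t_a=st.floats(-5.0, 40.0), h=st.floats(0.01, 50.0),
           rate=st.floats(1e-3, 10.0))
    @settings(max_examples=200, derandomize=True)
    def test_inverse_of_rescaling(self, t_a, h, rate):
        constants = ThermalConstants()
        budget = rescaled_tolerance(HeatingAssay("x", t_a, t_a + h, rate), constants)
        assert invert_critical_temperature(t_a, rate, budget, constants) == pytest.approx(
            t_a + h, abs=1e-10)

    def test_monotone_in_budget_and_rate(self, constants):
        budgets = [10.0, 100.0, 1000.0]
        tcs = [invert_critical_temperature(10.0, 0.1, b, constants) for b in budgets]
        assert tcs == sorted(tcs) and len(set(tcs)) == 3
        rates = [0.05, 0.1, 0.5]
        tcs = [invert_critical_temperature(10.0, v, 500.0, constants) for v in rates]
        assert tcs == sorted(tcs) and len(set(tcs)) == 3

    def test_nonpositive_rate_rejected(self, constants):
        with pytest.raises(ValueError):
            invert_critical_temperature(10.0, 0.0, 100.0, constants)


class TestRateTransfer:
    def test_identity_cases(self, constants):
        budget = RescaledTolerance(500.0, constants.beta, 0.1 / T_K)
        assert rate_transfer(budget, 0.1, 0.1, 0.76).value == pytest.approx(500.0)
        assert rate_transfer(budget, 0.1, 0.7, 0.0).value == pytest.approx(500.0)

    def test_doubling_rate(self, constants):
        # 2^{-0.76} = 0.59050, confirmed by direct arithmetic
        budget = RescaledTolerance(500.0, constants.beta, 0.1 / T_K)
        assert rate_transfer(budget, 0.1, 0.2, 0.76).value == pytest.approx(
            500.0 * 0.5904963307147651, rel=1e-12)

    def test_nonpositive_rates_rejected(self, constants):
        budget = RescaledTolerance(500.0, constants.beta, 0.1 / T_K)
        with pytest.raises(ValueError):
            rate_transfer(budget, 0.0, 0.1, 0.76)
        with pytest.raises(ValueError):
            rate_transfer(budget, 0.1, -0.5, 0.76)


class TestPredictionSurface:
    def test_anchor_reproduced(self, constants):
        anchor = HeatingAssay("x", 10.0, 30.0, 0.1)
        table = predict_tc_surface(anchor, [5.0, 10.0, 20.0], [0.05, 0.1, 1.0],
                                   0.76, constants)
        at_anchor = table[(table.acclimation_temp == 10.0)
                          & (table.heating_rate == 0.1)]
        assert at_anchor["predicted_tc"].iloc[0] == pytest.approx(30.0, abs=1e-10)

    def test_acclimation_slope_strictly_inside_unit_interval(self, constants):
        anchor = HeatingAssay("x", 10.0, 30.0, 0.1)
        grid = np.linspace(0.0, 35.0, 71)
        table = predict_tc_surface(anchor, grid, [0.1], 0.76, constants)
        tc = table["predicted_tc"].to_numpy()
        slopes = np.diff(tc) / np.diff(grid)
        assert np.all(slopes > 0.0) and np.all(slopes < 1.0)

    def test_local_slope_matches_analytic_response_ratio(self, constants):
        anchor = HeatingAssay("x", 10.0, 30.0, 0.1)
        eps = 1e-6
        table = predict_tc_surface(anchor, [15.0, 15.0 + eps], [0.1], 0.76, constants)
        tc = table["predicted_tc"].to_numpy()
        numeric = (tc[1] - tc[0]) / eps
        analytic = acclimation_response_ratio(15.0, tc[0], constants)
        assert numeric == pytest.approx(analytic, rel=1e-5)
        assert 0.0 < analytic < 1.0

    def test_tc_increases_with_rate_for_subunit_gamma(self, constants):
        anchor = HeatingAssay("x", 10.0, 30.0, 0.1)
        rates = [0.02, 0.1, 0.5, 2.0]
        table = predict_tc_surface(anchor, [15.0], rates, 0.76, constants)
        tc = table.sort_values("heating_rate")["predicted_tc"].to_numpy()
        assert np.all(np.diff(tc) > 0)

    def test_empty_grid_rejected(self, constants):
        anchor = HeatingAssay("x", 10.0, 30.0, 0.1)
        with pytest.raises(ValueError):
            predict_tc_surface(anchor, [], [0.1], 0.76, constants)
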