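"""Closed-form autocatalytic sigmoid vs independent numerical integration,
and the tangent-construction characteristic times."""

import math
import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

from amylokin import (
    KineticParameters,
    aggregated_fraction,
    characteristic_times,
    ode_oracle,
    time_at_fraction,
)

from conftest import A_UM10


def integrate_rate_law(k_n, k_e, a, grid):
    """Test-local oracle: integrate df/dt = k_n(1-f) + k_e*a*f*(1-f) directly
    from the raw rate constants, independent of the package's closed form."""
    sol = solve_ivp(
        lambda _t, f: k_n * (1.0 - f) + k_e * a * f * (1.0 - f),
        (0.0, grid[-1]),
        [0.0],
        t_eval=grid,
        method="LSODA",
        rtol=1e-12,
        atol=1e-14,
    )
    assert sol.success
    return sol.y[0]


class TestAggregatedFraction:
    def test_boundary_condition_zero(self, condition):
        _, params = condition
        assert aggregated_fraction(params, 0.0) == 0.0

    def test_asymptote_and_overflow_safety(self, condition):
        """f -> 1 at long times without overflow even for huge exponents."""
        _, params = condition
        with warnings.catch_warnings():
            warnings.simplefilter("error")
            f = aggregated_fraction(params, np.array([1e6, 1e9, 1e12]))
        assert np.all(f <= 1.0)
        assert f[-1] == pytest.approx(1.0, abs=1e-12)

    def test_negative_time_rejected(self, control_params):
        with pytest.raises(ValueError):
            aggregated_fraction(control_params, -1.0)

    def test_control_value_against_rate_law_integration(self, control_params):
        """At the printed half-time of the uninhibited condition (989 s) the
        model sits just below half-aggregation, f ~ 0.443."""
        f = aggregated_fraction(control_params, 989.0)
        oracle = integrate_rate_law(3.09e-5, 486.9, A_UM10, np.array([0.0, 989.0]))[-1]
        assert f == pytest.approx(oracle, abs=1e-8)
        assert f == pytest.approx(0.443, abs=1e-3)

    def test_strictly_increasing(self, control_params):
        t = np.linspace(0.0, 5000.0, 400)
        f = aggregated_fraction(control_params, t)
        assert np.all(np.diff(f) > 0)

    def test_scale_covariance(self):
        """Multiplying k by c and dividing times by c leaves f unchanged."""
        p1 = KineticParameters.from_rho_k(rho=0.01, k=1e-3, a=A_UM10)
        p2 = KineticParameters.from_rho_k(rho=0.01, k=1e-2, a=A_UM10)
        t = np.linspace(0.0, 8000.0, 50)
        np.testing.assert_allclose(
            aggregated_fraction(p1, t), aggregated_fraction(p2, t / 10.0), rtol=1e-12
        )


class TestOdeOracle:
    def test_matches_closed_form_on_study_conditions(self, condition):
        _, params = condition
        grid = np.arange(0.0, 5001.0, 300.0)
        dev = np.abs(ode_oracle(params, grid) - aggregated_fraction(params, grid))
        assert dev.max() < 1e-8

    def test_rho_of_one_edge(self):
        params = KineticParameters.from_rho_k(rho=1.0, k=1e-3, a=A_UM10)
        grid = np.linspace(0.0, 3000.0, 30)
        dev = np.abs(ode_oracle(params, grid) - aggregated_fraction(params, grid))
        assert dev.max() < 1e-8

    def test_initial_condition_only_grid(self, control_params):
        np.testing.assert_array_equal(ode_oracle(control_params, [0.0]), [0.0])

    def test_rejects_unsorted_grid(self, control_params):
        with pytest.raises(ValueError):
            ode_oracle(control_params, [300.0, 0.0])

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(
        log_rho=st.floats(min_value=math.log10(1e-8), max_value=0.0),
        log_k=st.floats(min_value=-5.0, max_value=-1.5),
    )
    def test_closed_form_equals_ode_over_random_parameters(self, log_rho, log_k):
        params = KineticParameters.from_rho_k(rho=10**log_rho, k=10**log_k, a=A_UM10)
        t1 = characteristic_times(params).t1
        grid = np.linspace(0.0, 10.0 * max(t1, 1.0), 40)
        dev = np.abs(ode_oracle(params, grid) - aggregated_fraction(params, grid))
        assert dev.max() < 1e-8


class TestTimeAtFraction:
    def test_zero_fraction_is_time_zero(self, condition):
        _, params = condition
        assert time_at_fraction(params, 0.0) == 0.0

    def test_fraction_one_rejected(self, control_params):
        with pytest.raises(ValueError):
            time_at_fraction(control_params, 1.0)

    @pytest.mark.parametrize("f_target", [0.05, 0.25, 0.5, 0.9, 0.999])
    def test_inverts_forward_model(self, condition, f_target):
        _, params = condition
        t = time_at_fraction(params, f_target)
        assert aggregated_fraction(params, t) == pytest.approx(f_target, rel=1e-10)

    def test_control_half_time_matches_bisection(self, control_params):
        """Analytic t_half agrees with a bisection root of f(t) = 1/2."""
        t_half = time_at_fraction(control_params, 0.5)
        root = brentq(
            lambda t: aggregated_fraction(control_params, t) - 0.5, 1.0, 1e5,
            xtol=1e-8,
        )
        assert t_half == pytest.approx(root, rel=1e-9)
        assert t_half == pytest.approx(1035.0, abs=1.0)

    def test_control_inflection_time(self, control_params):
        """f_i = (1-rho)/2 occurs at t_i = ln(1/rho)/((1+rho)k) ~ 1033 s."""
        rho, k = control_params.rho, control_params.k
        t_i = time_at_fraction(control_params, (1.0 - rho) / 2.0)
        assert t_i == pytest.approx(math.log(1.0 / rho) / ((1.0 + rho) * k), rel=1e-12)
        assert t_i == pytest.approx(1033.0, abs=1.0)


def tangent_times_numeric(params, n=200_001, span=6000.0):
    """Numeric tangent construction: steepest finite-difference slope on a
    dense curve, extrapolated to f = 0 and f = 1."""
    t = np.linspace(0.0, span, n)
    f = aggregated_fraction(params, t)
    slopes = np.diff(f) / np.diff(t)
    i = int(np.argmax(slopes))
    t_mid = 0.5 * (t[i] + t[i + 1])
    f_mid = 0.5 * (f[i] + f[i + 1])
    v = slopes[i]
    return t_mid - f_mid / v, t_mid + (1.0 - f_mid) / v


class TestCharacteristicTimes:
    def test_control_tangent_times(self, control_params):
        """Tangent at the inflection gives t0 ~ 630 s, t_i ~ 1033 s,
        t1 ~ 1441 s for the uninhibited condition."""
        ct = characteristic_times(control_params)
        t0_num, t1_num = tangent_times_numeric(control_params)
        assert ct.t0 == pytest.approx(t0_num, abs=0.5)
        assert ct.t1 == pytest.approx(t1_num, abs=0.5)
        assert ct.t0 == pytest.approx(630.0, abs=1.0)
        assert ct.t_inflection == pytest.approx(1033.0, abs=1.0)
        assert ct.t1 == pytest.approx(1441.0, abs=1.0)

    def test_ordering(self, condition):
        _, params = condition
        ct = characteristic_times(params)
        assert ct.t0 < ct.t_inflection < ct.t1
        assert ct.t0 < ct.t_half < ct.t1

    def test_tangent_midpoint_identity(self, condition):
        """(t0 + t1)/2 equals t_i + (1 - 2 f_i)/(2 v_max) to 1e-9 * t1."""
        _, params = condition
        ct = characteristic_times(params)
        f_i = (1.0 - params.rho) / 2.0
        expected = ct.t_inflection + (1.0 - 2.0 * f_i) / (2.0 * ct.v_max)
        assert abs(ct.t_half_tangent - expected) < 1e-9 * ct.t1
        assert abs(0.5 * (ct.t0 + ct.t1) - ct.t_half_tangent) < 1e-9 * ct.t1

    def test_symmetric_limit_small_rho(self):
        """As rho -> 0 the sigmoid becomes logistic and t_half -> t_i."""
        params = KineticParameters.from_rho_k(rho=1e-9, k=1e-3, a=A_UM10)
        ct = characteristic_times(params)
        assert abs(ct.t_half - ct.t_inflection) < 1e-3

    def test_logistic_limit(self):
        """For tiny rho, f matches 1/(1+exp(-(1+rho)k(t-t_i))) within 10*rho."""
        rho, k = 1e-7, 1e-3
        params = KineticParameters.from_rho_k(rho=rho, k=k, a=A_UM10)
        ct = characteristic_times(params)
        t = np.linspace(ct.t0, ct.t1, 500)
        logistic = 1.0 / (1.0 + np.exp(-(1.0 + rho) * k * (t - ct.t_inflection)))
        assert np.abs(aggregated_fraction(params, t) - logistic).max() < 10.0 * rho

    def test_monotonicity_in_rate_constants(self):
        """Faster nucleation shortens all times; faster elongation sharpens
        the transition (shrinks t1 - t0)."""
        base = KineticParameters(k_n=1e-5, k_e=400.0, a=A_UM10)
        more_nucleation = KineticParameters(k_n=3e-5, k_e=400.0, a=A_UM10)
        more_elongation = KineticParameters(k_n=1e-5, k_e=800.0, a=A_UM10)
        ct_b, ct_n, ct_e = map(characteristic_times, (base, more_nucleation, more_elongation))
        assert ct_n.t0 < ct_b.t0 and ct_n.t_half < ct_b.t_half and ct_n.t1 < ct_b.t1
        assert (ct_e.t1 - ct_e.t0) < (ct_b.t1 - ct_b.t0)

    def test_lagless_regime_flagged(self):
        """rho >= 1 puts the inflection at t <= 0: flagged, t0 clamped to 0."""
        params = KineticParameters.from_rho_k(rho=2.0, k=1e-3, a=A_UM10)
        assert params.is_lagless
        with pytest.warns(UserWarning, match="lag"):
            ct = characteristic_times(params)
        assert ct.lagless and ct.t0 == 0.0


class TestKineticParameters:
    def test_derived_quantities_round_trip(self, condition):
        _, p = condition
        assert p.k == pytest.approx(p.k_e * p.a, rel=1e-15)
        assert p.k_n == pytest.approx(p.rho * p.k, rel=1e-15)
        p2 = KineticParameters.from_rho_k(p.rho, p.k, p.a)
        assert p2.k_n == pytest.approx(p.k_n, rel=1e-14)
        assert p2.k_e == pytest.approx(p.k_e, rel=1e-14)

    @pytest.mark.parametrize("bad", [{"k_n": -1e-5}, {"k_e": 0.0}, {"a": -1e-6}])
    def test_nonpositive_rejected(self, bad):
        kwargs = {"k_n": 1e-5, "k_e": 400.0, "a": A_UM10, **bad}
        with pytest.raises(ValueError):
            KineticParameters(**kwargs)
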