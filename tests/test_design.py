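"""Unit and property tests for the sampling-design calculus."""

import math

import pytest
from hypothesis import given, settings, strategies as st

from fovcount.design import (
    DesignPoint,
    Method,
    allocation_for_error,
    choose_method,
    critical_density,
    effort_coefficient,
    effort_difference,
    effort_for_error_fovs,
    effort_for_error_linear,
    error_fovs_two_dim,
    error_ratio,
    error_vs_effort_fovs,
    error_vs_effort_linear,
    n3e_from_effort,
    optimal_allocation,
    reversed_role,
)
from conftest import DENSITY, OMEGA, SCENARIOS, integer_allocation_search

# moderately wide, numerically safe parameter ranges for property tests
u_st = st.floats(1.0, 80.0)
y_st = st.floats(0.2, 150.0)
w_st = st.floats(0.0, 10.0)
t_st = st.floats(0.0, 4e-4)
dp_st = st.builds(DesignPoint, u_hat=u_st, density=y_st, omega=w_st, dose_error=t_st)


class TestEffortCoefficient:
    def test_limits_and_values(self):
        assert effort_coefficient(DesignPoint(1e9, 27.0, 0.0)) == pytest.approx(1.0)
        assert effort_coefficient(DesignPoint(1.0, 27.0, 2.0)) == pytest.approx(
            2.07407, abs=5e-6
        )
        assert effort_coefficient(DesignPoint(60.0, 27.0, 2.0)) == pytest.approx(
            1.09074, abs=5e-6
        )

    def test_matches_common_effort_budget(self):
        # A * x reproduces the ~1000 effort unit design of the validation runs
        assert effort_coefficient(DesignPoint(1, 27, 2)) * 482 == pytest.approx(
            999.70, abs=0.005
        )
        assert effort_coefficient(DesignPoint(60, 27, 2)) * 917 == pytest.approx(
            1000.2, abs=0.05
        )


class TestErrorVsEffort:
    def test_linear_value(self):
        dp = DesignPoint(1.0, 27.0, 2.0)
        sig = error_vs_effort_linear(dp, 999.7)
        assert sig == pytest.approx(100 * math.sqrt(2 * 2.0740741 / 999.7), abs=1e-6)
        assert sig == pytest.approx(6.44, abs=5e-3)

    def test_inverse_square_root_law(self):
        dp = DesignPoint(5.0, 10.0, 2.0)
        assert error_vs_effort_linear(dp, 4000.0) == pytest.approx(
            error_vs_effort_linear(dp, 1000.0) / 2, rel=1e-12
        )
        assert error_vs_effort_fovs(dp, 4000.0) == pytest.approx(
            error_vs_effort_fovs(dp, 1000.0) / 2, rel=1e-12
        )

    def test_dose_error_floor(self):
        dp = DesignPoint(5.0, 10.0, 2.0, dose_error=1e-4)
        assert error_vs_effort_linear(dp, 1e12) == pytest.approx(
            100 * math.sqrt(1e-4), rel=1e-4
        )

    def test_two_dim_value_and_symmetry(self):
        dp = DesignPoint(1.0, 27.0, 2.0)
        assert error_fovs_two_dim(dp, 17, 17) == pytest.approx(
            100 * math.sqrt(2 / 459), rel=1e-9
        )
        # exchanging (N3C, N3E/u) leaves the error unchanged
        dp2 = DesignPoint(4.0, 20.0, 2.0)
        assert error_fovs_two_dim(dp2, 10, 4 * 25) == pytest.approx(
            error_fovs_two_dim(dp2, 25, 4 * 10), rel=1e-12
        )

    def test_fovs_effort_curve_equals_optimum(self):
        for dp in (DesignPoint(3.0, 10.0, 2.0), DesignPoint(20.0, 27.0, 1.0, 1e-4)):
            alloc = optimal_allocation(dp, 1500.0)
            assert error_vs_effort_fovs(dp, 1500.0) == pytest.approx(
                error_fovs_two_dim(dp, alloc.n3c_star, alloc.n3e_star), rel=1e-12
            )

    def test_rejects_nonpositive_effort(self):
        with pytest.raises(ValueError):
            error_vs_effort_linear(DesignPoint(2, 10, 2), 0.0)


class TestBudgetLine:
    def test_n3e_from_effort_value(self):
        dp = DesignPoint(1.0, 27.0, 2.0)
        assert n3e_from_effort(dp, 1000.0, 17) == pytest.approx(17.48, abs=5e-3)

    def test_boundary_and_error(self):
        dp = DesignPoint(2.0, 10.0, 2.0)
        with pytest.raises(ValueError, match="exhausts budget"):
            n3e_from_effort(dp, (dp.omega + dp.density) * 5, 5)

    @given(dp=dp_st, n3c=st.floats(1.0, 50.0), budget=st.floats(500.0, 5000.0))
    @settings(max_examples=100, deadline=None)
    def test_effort_conservation(self, dp, n3c, budget):
        """Substituting expected counts back into the effort model
        recovers the budget exactly."""
        if budget <= (dp.omega + dp.density) * n3c:
            return
        n3e = n3e_from_effort(dp, budget, n3c)
        spent = (
            dp.omega * n3c
            + n3c * dp.density
            + dp.omega * n3e
            + n3e * dp.density / dp.u_hat
        )
        assert spent == pytest.approx(budget, rel=1e-10)


class TestOptimalAllocation:
    def test_equal_abundance_splits_evenly(self):
        alloc = optimal_allocation(DesignPoint(1.0, 27.0, 2.0), 999.7)
        assert alloc.delta_star == pytest.approx(1.0, rel=1e-12)
        assert alloc.n3c == alloc.n3e == 17

    @pytest.mark.parametrize("sc", SCENARIOS, ids=lambda s: f"u={s.u}")
    def test_published_allocations(self, sc):
        dp = DesignPoint(sc.u, DENSITY, OMEGA)
        budget = effort_coefficient(dp) * sc.x_stop
        alloc = optimal_allocation(dp, budget)
        assert (alloc.n3c, alloc.n3e) == (sc.n3c, sc.n3e)

    @pytest.mark.parametrize("sc", SCENARIOS, ids=lambda s: f"u={s.u}")
    def test_integer_search_oracle_agrees(self, sc):
        """Exhaustive integer search at the rounded pair's realised
        expected effort confirms the rounding is integer-optimal."""
        dp = DesignPoint(sc.u, DENSITY, OMEGA)
        budget = effort_coefficient(dp) * sc.x_stop
        alloc = optimal_allocation(dp, budget)
        realised = (dp.omega + dp.density) * alloc.n3c + (
            dp.omega + dp.density / dp.u_hat
        ) * alloc.n3e
        best_err, best_pair = integer_allocation_search(dp, realised + 1e-9)
        assert best_pair == (alloc.n3c, alloc.n3e)
        assert error_fovs_two_dim(dp, alloc.n3c, alloc.n3e) == pytest.approx(
            best_err, rel=1e-6
        )

    @given(dp=dp_st, budget=st.floats(2000.0, 20_000.0))
    @settings(max_examples=100, deadline=None)
    def test_stationary_point_conserves_effort(self, dp, budget):
        alloc = optimal_allocation(dp, budget)
        spent = (dp.omega + dp.density) * alloc.n3c_star + (
            dp.omega + dp.density / dp.u_hat
        ) * alloc.n3e_star
        assert spent == pytest.approx(budget, rel=1e-10)
        assert alloc.delta_star == pytest.approx(
            alloc.n3e_star / alloc.n3c_star, rel=1e-10
        )

    def test_delta_grows_as_sqrt_u(self):
        dp_base = DesignPoint(100.0, 27.0, 2.0)
        dp_4x = DesignPoint(400.0, 27.0, 2.0)
        ratio = (
            optimal_allocation(dp_4x, 1e5).delta_star
            / optimal_allocation(dp_base, 1e5).delta_star
        )
        assert ratio == pytest.approx(2.0, rel=0.15)

    def test_budget_too_small(self):
        with pytest.raises(ValueError, match="minimum feasible effort"):
            optimal_allocation(DesignPoint(2.0, 27.0, 2.0), 5.0)


class TestCriticalDensityAndChoice:
    @pytest.mark.parametrize("sc", SCENARIOS, ids=lambda s: f"u={s.u}")
    def test_published_critical_densities(self, sc):
        got = critical_density(sc.u, OMEGA)
        if math.isinf(sc.critical_density):
            assert math.isinf(got)
        else:
            assert got == pytest.approx(sc.critical_density, rel=5e-4)

    @given(u=st.floats(1.01, 100.0), w=st.floats(0.05, 10.0))
    @settings(max_examples=200, deadline=None)
    def test_closed_form_is_root_of_dividing_line(self, u, w):
        y = critical_density(u, w)
        residual = (
            (u**2 - 1) ** 2 * y**2
            - 4 * w * u**2 * (1 + u) * y
            - 4 * w**2 * u**3
        )
        scale = (u**2 - 1) ** 2 * y**2 + 4 * w**2 * u**3
        assert abs(residual) / scale < 1e-6

    def test_decreasing_in_u(self):
        vals = [critical_density(u, 2.0) for u in [1.5, 2, 4, 8, 16, 32, 64]]
        assert all(b < a for a, b in zip(vals, vals[1:]))

    @given(u=st.floats(1.05, 60.0), w=st.floats(0.1, 8.0),
           e=st.floats(100.0, 1e5), t=t_st)
    @settings(max_examples=200, deadline=None)
    def test_error_ratio_is_one_at_critical_density(self, u, w, e, t):
        ystar = critical_density(u, w)
        dp = DesignPoint(u, ystar, w, t)
        assert error_ratio(dp, e) == pytest.approx(1.0, abs=1e-10)

    def test_ratio_direction(self):
        # near-equal abundances favour the linear method
        assert error_ratio(DesignPoint(1.0, 27.0, 2.0), 1000.0) < 1.0
        # strongly uneven abundances at density 27 favour the FOVS method
        assert error_ratio(DesignPoint(30.0, 27.0, 2.0), 1000.0) > 1.0

    def test_choose_method_decisions(self):
        assert choose_method(DesignPoint(2.0, 27.0, 2.0)).recommended is Method.fovs
        assert choose_method(DesignPoint(1.2, 27.0, 2.0)).recommended is Method.linear
        assert choose_method(DesignPoint(1.0, 1e6, 2.0)).recommended is Method.linear
        tie = choose_method(DesignPoint(2.0, critical_density(2.0, 2.0), 2.0))
        assert tie.recommended is Method.equivalent


class TestTargetedPrecision:
    def test_linear_effort_value(self):
        dp = DesignPoint(3.0, 10.0, 2.0)
        assert effort_for_error_linear(dp, 10.0) == pytest.approx(613.33, abs=0.01)

    def test_worked_example_with_calibrated_dose_error(self):
        # dose error chosen so the u=3 companion case costs 627 effort units
        dp3 = DesignPoint(3.0, 10.0, 2.0)
        t = (10.0 / 100) ** 2 - (
            effort_for_error_linear(dp3, 10.0) * (10.0 / 100) ** 2 / 627.0
        )
        dp20 = DesignPoint(20.0, 10.0, 2.0, dose_error=t)
        assert effort_for_error_linear(dp20, 10.0) == pytest.approx(2682, rel=1e-3)

    def test_fovs_effort_value(self):
        dp = DesignPoint(20.0, 10.0, 2.0)
        expect = (2 * 10 + 2 * 21 + 2 * math.sqrt(12 * 50)) / (10 * 0.01)
        assert effort_for_error_fovs(dp, 10.0) == pytest.approx(expect, rel=1e-12)
        assert expect == pytest.approx(1109.90, abs=0.01)

    def test_unreachable_error_raises(self):
        dp = DesignPoint(3.0, 10.0, 2.0, dose_error=(0.12) ** 2)
        with pytest.raises(ValueError, match="unattainable"):
            effort_for_error_linear(dp, 10.0)
        with pytest.raises(ValueError, match="unattainable"):
            effort_for_error_fovs(dp, 10.0)

    @given(dp=dp_st, sigma=st.floats(3.0, 40.0))
    @settings(max_examples=150, deadline=None)
    def test_round_trips_are_exact(self, dp, sigma):
        if (sigma / 100) ** 2 <= dp.dose_error:
            return
        e_lin = effort_for_error_linear(dp, sigma)
        assert error_vs_effort_linear(dp, e_lin) == pytest.approx(sigma, rel=1e-10)
        e_fov = effort_for_error_fovs(dp, sigma)
        assert error_vs_effort_fovs(dp, e_fov) == pytest.approx(sigma, rel=1e-10)
        alloc = allocation_for_error(dp, sigma)
        assert error_fovs_two_dim(dp, alloc.n3c_star, alloc.n3e_star) == pytest.approx(
            sigma, rel=1e-10
        )
        # delta* is budget independent; evaluate at a comfortable budget
        assert alloc.n3e_star / alloc.n3c_star == pytest.approx(
            optimal_allocation(dp, 1e6).delta_star, rel=1e-10
        )
        assert alloc.effort == pytest.approx(e_fov, rel=1e-10)

    def test_allocation_for_error_matches_budget_allocation(self):
        dp = DesignPoint(30.0, 27.0, 2.0)
        sigma = error_vs_effort_fovs(dp, 1000.0)
        alloc = allocation_for_error(dp, sigma)
        assert (alloc.n3c, alloc.n3e) == (13, 219)

    @given(dp=dp_st, sigma=st.floats(3.0, 40.0))
    @settings(max_examples=150, deadline=None)
    def test_effort_difference_sign_matches_method_choice(self, dp, sigma):
        if (sigma / 100) ** 2 <= dp.dose_error or dp.omega < 1e-6:
            return  # degenerate transition cost: difference underflows
        diff = effort_difference(dp, sigma)
        choice = choose_method(dp)
        if choice.recommended is Method.fovs:
            assert diff > 0
        elif choice.recommended is Method.linear:
            assert diff < 0

    def test_equal_abundance_always_favours_linear(self):
        for y in (0.5, 5.0, 50.0):
            assert effort_difference(DesignPoint(1.0, y, 2.0), 8.0) < 0
        assert effort_difference(DesignPoint(10.0, 10.0, 2.0), 10.0) > 0


class TestReversedRole:
    def test_double_swap_identity(self):
        dp = DesignPoint(0.5, 13.5, 2.0, 1e-4)
        assert reversed_role(reversed_role(dp)) == dp

    def test_swap_maps_density_to_markers(self):
        dp = DesignPoint(0.5, 10.0, 2.0)  # markers twice as common
        swapped = reversed_role(dp)
        assert swapped.u_hat == pytest.approx(2.0)
        assert swapped.density == pytest.approx(20.0)  # markers per FOV

    def test_primal_formulas_refuse_marker_common_input(self):
        dp = DesignPoint(0.5, 10.0, 2.0)
        with pytest.raises(ValueError, match="reversed_role"):
            error_vs_effort_linear(dp, 100.0)
        with pytest.raises(ValueError, match="reversed_role"):
            optimal_allocation(dp, 1000.0)
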