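"""Derringer-Suich desirability scores and the grid optimizer."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from chromaqbd.designs import DesignMatrix, Factor
from chromaqbd.desirability import (
    DesirabilityGoal,
    individual_desirability,
    optimize_desirability,
    overall_desirability,
)
from chromaqbd.rsm import ResponseTable, fit_response_model


class TestIndividual:
    def test_at_least_saturates_at_observed_max(self):
        # resolution floor 1.2 with the observed maximum 2.12 as ramp top
        goal = DesirabilityGoal(cma="RS1", goal="at_least", lower=1.2, upper=2.12)
        assert individual_desirability(2.12, goal) == 1.0
        assert individual_desirability(1.2, goal) == 0.0

    def test_linear_ramp_midpoint(self):
        goal = DesirabilityGoal(cma="Y", goal="maximize", lower=0.0, upper=2.0)
        assert individual_desirability(1.0, goal) == pytest.approx(0.5)

    def test_in_range_outside_is_zero(self):
        goal = DesirabilityGoal(cma="Y", goal="in_range", lower=2.0, upper=7.0)
        assert individual_desirability(1.5, goal) == 0.0
        assert individual_desirability(4.0, goal) == 1.0

    def test_minimize_mirrors_maximize(self):
        lo, hi = 1.0, 3.0
        mx = DesirabilityGoal(cma="Y", goal="maximize", lower=lo, upper=hi)
        mn = DesirabilityGoal(cma="Y", goal="minimize", lower=lo, upper=hi)
        y = np.linspace(0, 4, 17)
        np.testing.assert_allclose(
            individual_desirability(y, mx), individual_desirability(lo + hi - y, mn)
        )

    def test_target_peaks_at_target(self):
        goal = DesirabilityGoal(cma="Y", goal="target", lower=0, upper=10, target=4)
        assert individual_desirability(4, goal) == 1.0
        assert individual_desirability(2, goal) == pytest.approx(0.5)
        assert individual_desirability(7, goal) == pytest.approx(0.5)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        st.floats(-50, 50, allow_nan=False),
        st.sampled_from(["maximize", "minimize", "in_range", "at_least", "at_most"]),
        st.floats(0.25, 4.0),
    )
    def test_always_in_unit_interval(self, y, kind, weight):
        goal = DesirabilityGoal(cma="Y", goal=kind, lower=-1.0, upper=2.0, weight=weight)
        d = individual_desirability(y, goal)
        assert 0.0 <= d <= 1.0


class TestOverall:
    def test_all_ones(self):
        assert overall_desirability([1.0, 1.0, 1.0]) == 1.0

    def test_zero_vetoes(self):
        assert overall_desirability([0.0, 1.0, 0.9]) == 0.0

    def test_sqrt_identity(self):
        assert overall_desirability([0.25, 1.0]) == pytest.approx(0.5)

    def test_negative_importance_rejected(self):
        with pytest.raises(ValueError):
            overall_desirability([0.5, 0.5], importance=[1.0, -1.0])

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0.01, 1.0), min_size=2, max_size=6))
    def test_permutation_invariant_and_equals_geometric_mean(self, d):
        D = overall_desirability(d)
        assert D == pytest.approx(overall_desirability(d[::-1]), rel=1e-12)
        assert D == pytest.approx(float(np.exp(np.mean(np.log(d)))), rel=1e-12)


def _fit_surface(fun, factors, rng):
    """Fit an interaction model to a surface sampled on a 2^k + centers design."""
    from chromaqbd.designs import full_factorial

    d = full_factorial(factors, n_center=1, seed=0)
    nat = d.natural
    y = fun(*[nat[:, j] for j in range(nat.shape[1])])
    table = ResponseTable(design=d, responses=pd.DataFrame({"Y": y}))
    return fit_response_model(table, "Y")


class TestOptimizer:
    def test_monotone_single_factor_optimum_at_high_end(self):
        f = [Factor("X", 0.0, 10.0)]
        m = _fit_surface(lambda x: 2.0 * x + 1.0, f, None)
        goal = DesirabilityGoal(cma="Y", goal="maximize", lower=0.0, upper=30.0)
        res = optimize_desirability({"Y": m}, [goal], f, grid=11, polish=False)
        assert res.best["X"] == pytest.approx(10.0)

    def test_matches_exhaustive_grid_oracle(self, rng):
        f = [Factor("A", -1.0, 1.0), Factor("B", -1.0, 1.0)]
        # bilinear surface with a unique optimum at a corner region
        m = _fit_surface(lambda a, b: 3 - a - 0.5 * b + a * b, f, rng)
        goal = DesirabilityGoal(cma="Y", goal="maximize", lower=0.0, upper=6.0)
        grid = 21
        res = optimize_desirability({"Y": m}, [goal], f, grid=grid, polish=False)
        # independent exhaustive enumeration over the same grid
        axes = [np.linspace(-1, 1, grid)] * 2
        best_D, best_pt = -1.0, None
        from chromaqbd.rsm import predict

        for a, b in itertools.product(*axes):
            y = predict(m, {"A": [a], "B": [b]})[0]
            d = individual_desirability(y, goal)
            if d > best_D:
                best_D, best_pt = d, (a, b)
        assert res.grid_D == pytest.approx(best_D, abs=1e-6)
        step = 2.0 / (grid - 1)
        assert abs(res.grid_best["A"] - best_pt[0]) <= step + 1e-12
        assert abs(res.grid_best["B"] - best_pt[1]) <= step + 1e-12

    def test_polish_does_not_decrease_D(self, fitted_models):
        from chromaqbd.synthetic import optimization_goals, screening_factors

        goals = optimization_goals()
        res = optimize_desirability(fitted_models, goals, screening_factors(), grid=11, polish=True)
        assert res.D >= res.grid_D - 1e-12

    def test_doubled_importance_same_argmax(self, rng):
        f = [Factor("A", -1.0, 1.0), Factor("B", -1.0, 1.0)]
        m1 = _fit_surface(lambda a, b: 2 + a - 0.5 * b, f, rng)
        m2 = _fit_surface(lambda a, b: 1 - 0.3 * a + 0.8 * b, f, rng)
        g1 = DesirabilityGoal(cma="Y1", goal="maximize", lower=0.0, upper=4.0)
        g2 = DesirabilityGoal(cma="Y2", goal="maximize", lower=0.0, upper=3.0)
        r1 = optimize_desirability({"Y1": m1, "Y2": m2}, [g1, g2], f, grid=15, polish=False)
        g1d = DesirabilityGoal(cma="Y1", goal="maximize", lower=0.0, upper=4.0, importance=2.0)
        g2d = DesirabilityGoal(cma="Y2", goal="maximize", lower=0.0, upper=3.0, importance=2.0)
        r2 = optimize_desirability({"Y1": m1, "Y2": m2}, [g1d, g2d], f, grid=15, polish=False)
        assert r1.grid_best == r2.grid_best

    def test_grid_refinement_monotonicity(self, fitted_models):
        from chromaqbd.synthetic import optimization_goals, screening_factors

        goals = optimization_goals()
        coarse = optimize_desirability(fitted_models, goals, screening_factors(), grid=11, polish=False)
        fine = optimize_desirability(fitted_models, goals, screening_factors(), grid=21, polish=False)
        assert fine.grid_D >= coarse.grid_D - 1e-12

    def test_infeasible_everywhere_reports_zero(self):
        f = [Factor("X", 0.0, 1.0)]
        m = _fit_surface(lambda x: x, f, None)
        goal = DesirabilityGoal(cma="Y", goal="in_range", lower=100.0, upper=200.0)
        res = optimize_desirability({"Y": m}, [goal], f, grid=11)
        assert res.D == 0.0
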