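"""Fractional Adams-Bashforth-Moulton solver and Mittag-Leffler oracle."""

import math

import numpy as np
import pytest

from fracprey import CaputoProblem, SolverBlowUpError, abm_solve, mittag_leffler
from fracprey.caputo import convergence_order, mittag_leffler_grid

from conftest import SET1, SET2, SET3, simulate


def linear_problem(zeta: float, h: float, t_end: float = 5.0) -> CaputoProblem:
    return CaputoProblem(
        order=zeta,
        rhs=lambda t, y: -y,
        initial_state=np.array([1.0]),
        t_end=t_end,
        h=h,
    )


class TestMittagLeffler:
    @pytest.mark.parametrize("z", [-2.0, -1.0, -0.3, 0.5, 2.0])
    def test_order_one_is_exponential(self, z):
        assert mittag_leffler(1.0, z) == pytest.approx(math.exp(z), rel=1e-14)

    @pytest.mark.parametrize("zeta", [0.3, 0.6, 0.95, 1.0])
    def test_value_one_at_zero(self, zeta):
        assert mittag_leffler(zeta, 0.0) == 1.0

    def test_half_order_erfc_identity(self):
        # E_{1/2}(-x) = exp(x^2) erfc(x); frozen at x = 1 from 40-digit arithmetic
        assert mittag_leffler(0.5, -1.0) == pytest.approx(
            0.42758357615580700441, rel=1e-13
        )

    def test_extended_precision_branch_continuous(self):
        # values just below and above the precision switch agree smoothly
        lo = mittag_leffler(0.8, -9.99)
        hi = mittag_leffler(0.8, -10.01)
        assert abs(lo - hi) < 1e-3

    def test_guard_on_large_arguments(self):
        with pytest.raises(ValueError, match="guard"):
            mittag_leffler(0.8, -60.0)

    def test_invalid_order_rejected(self):
        with pytest.raises(ValueError):
            mittag_leffler(1.2, -1.0)


class TestABMSolver:
    @pytest.mark.parametrize("zeta", [0.6, 0.8, 0.95])
    def test_matches_mittag_leffler_reference(self, zeta):
        traj = abm_solve(linear_problem(zeta, h=2**-8))
        ref = mittag_leffler_grid(zeta, traj.times)
        assert np.max(np.abs(traj.states[:, 0] - ref)) <= 1e-3

    def test_integer_order_matches_exponential(self):
        traj = abm_solve(linear_problem(1.0, h=2**-8))
        assert np.max(np.abs(traj.states[:, 0] - np.exp(-traj.times))) <= 1e-4

    def test_error_decreases_under_step_halving(self):
        report = convergence_order(0.8, [2**-5, 2**-6, 2**-7, 2**-8])
        assert report.monotone
        # error at least halves per halving
        assert np.all(report.errors[:-1] / report.errors[1:] >= 2.0)

    def test_empirical_order_brackets_theory(self):
        # corrector order is 1 + zeta for smooth problems
        report = convergence_order(0.8, [2**-5, 2**-6, 2**-7, 2**-8, 2**-9])
        assert np.all((report.orders >= 1.0) & (report.orders <= 2.0))

    def test_integer_order_is_second_order(self):
        report = convergence_order(1.0, [2**-5, 2**-6, 2**-7, 2**-8])
        assert report.estimate == pytest.approx(2.0, abs=0.3)

    def test_convergence_needs_three_levels(self):
        with pytest.raises(ValueError):
            convergence_order(0.8, [0.1, 0.05])

    def test_memory_quadrature_is_causal(self):
        # extending the horizon must not change the shared interval
        short = abm_solve(linear_problem(0.7, h=2**-5, t_end=2.0))
        long = abm_solve(linear_problem(0.7, h=2**-5, t_end=4.0))
        n = len(short.times)
        assert np.allclose(short.states, long.states[:n], atol=1e-12, rtol=0)

    @pytest.mark.filterwarnings("ignore:overflow")
    def test_blowup_raises_with_last_valid_time(self):
        problem = CaputoProblem(
            order=0.9,
            rhs=lambda t, y: y**2,
            initial_state=np.array([2.0]),
            t_end=5.0,
            h=0.01,
        )
        with pytest.raises(SolverBlowUpError) as exc_info:
            abm_solve(problem)
        assert 0.0 < exc_info.value.t_last < 5.0

    def test_grid_must_divide_horizon(self):
        with pytest.raises(ValueError, match="multiple"):
            abm_solve(linear_problem(0.8, h=0.3, t_end=1.0))

    @pytest.mark.parametrize("bad", [{"order": 0.0}, {"order": 1.5}, {"h": -0.1}])
    def test_problem_validation(self, bad):
        kwargs = dict(
            order=0.8, rhs=lambda t, y: -y, initial_state=np.array([1.0]), t_end=1.0, h=0.1
        )
        kwargs.update(bad)
        with pytest.raises(ValueError):
            CaputoProblem(**kwargs)


class TestModelIntegration:
    def test_published_attractor_reached(self):
        # below the critical order the coexistence point attracts
        traj = simulate(SET1, 0.95, [1.5, 0.5], t_end=500.0)
        assert np.abs(traj.final_state - np.array([2.0543, 0.3970])).max() <= 1e-2

    @pytest.mark.parametrize("p", [SET1, SET2, SET3])
    def test_positive_quadrant_preserved(self, p):
        traj = simulate(p, 0.95, [1.5, 0.5], t_end=200.0)
        assert traj.states.min() >= -1e-8

    @pytest.mark.parametrize("p", [SET1, SET2, SET3])
    def test_integer_order_matches_adaptive_reference(self, p):
        # zeta = 1 must recover classical dynamics: compare against a
        # high-order adaptive integrator at tight tolerance
        from scipy.integrate import solve_ivp

        from fracprey import interior_equilibrium, vector_field

        y0 = interior_equilibrium(p).point * np.array([1.01, 1.0])
        traj = simulate(p, 1.0, y0, t_end=100.0, h=0.01)
        ref = solve_ivp(
            lambda t, y: vector_field(p, y),
            (0.0, 100.0),
            y0,
            t_eval=traj.times,
            rtol=1e-11,
            atol=1e-12,
            method="DOP853",
        )
        assert np.max(np.abs(traj.states - ref.y.T)) <= 1e-4

    def test_trajectory_csv_roundtrip(self, tmp_path):
        from fracprey import Trajectory

        traj = simulate(SET1, 0.9, [1.5, 0.5], t_end=5.0, h=0.05)
        path = tmp_path / "traj.csv"
        traj.to_csv(path)
        back = Trajectory.from_csv(path)
        assert np.allclose(back.times, traj.times)
        assert np.allclose(back.states, traj.states)
        assert path.with_suffix(".meta.json").exists()
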