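"""Model containers, dosing semantics and simulation accuracy."""

import numpy as np
import pytest
from scipy.linalg import expm

from qspreduce.core import (ControlAffineModel, DoseEvent, DoseRegimen,
                            LinearStateSpaceModel, default_time_grid,
                            is_asymptotically_stable, marginal_eigenvalues,
                            simulate)
from qspreduce.errors import ConfigurationError, ValidationError
from qspreduce.fixtures import random_stable_linear_system


def scalar_decay(x0=1.0):
    return LinearStateSpaceModel([[-1.0]], [[1.0]], [[1.0]],
                                 ["x"], ["u"], ["y"], initial_state=[x0])


class TestSimulateClosedForms:
    def test_scalar_exponential_decay(self):
        grid = np.linspace(0, 5, 200)
        traj = simulate(scalar_decay(), time_grid=grid)
        assert np.allclose(traj.outputs[:, 0], np.exp(-grid), atol=1e-10)

    def test_diagonal_two_state(self):
        m = LinearStateSpaceModel(np.diag([-1.0, -2.0]), np.zeros((2, 1)),
                                  np.eye(2), ["a", "b"], ["u"], ["ya", "yb"],
                                  initial_state=[1.0, 1.0])
        grid = np.linspace(0, 3, 100)
        traj = simulate(m, time_grid=grid)
        assert np.allclose(traj.states[:, 0], np.exp(-grid), atol=1e-10)
        assert np.allclose(traj.states[:, 1], np.exp(-2 * grid), atol=1e-10)

    def test_nonlinear_path_matches_closed_form(self):
        m = ControlAffineModel(["x"], lambda x: -x, [], lambda x: x.copy(),
                               np.array([1.0]), [], ["y"])
        grid = np.linspace(0, 5, 100)
        traj = simulate(m, time_grid=grid)
        assert np.allclose(traj.outputs[:, 0], np.exp(-grid), atol=1e-7)


class TestSimulateAgainstMatrixExponential:
    @pytest.mark.parametrize("n", [2, 5, 16])
    def test_linear_free_response(self, n):
        m = random_stable_linear_system(n, 1, 1, seed=100 + n)
        x0 = np.linspace(0.5, 1.5, n)
        m.initial_state = x0
        grid = np.linspace(0, 4, 50)
        traj = simulate(m, time_grid=grid)
        exact = np.array([expm(m.A * t) @ x0 for t in grid])
        assert np.abs(traj.states - exact).max() < 1e-7

    def test_nonlinear_solver_agrees_with_linear_path(self):
        m = random_stable_linear_system(6, 1, 2, seed=3)
        m.initial_state = np.ones(6)
        grid = np.linspace(0, 5, 80)
        dose = DoseRegimen([DoseEvent(0.0, "u1", 2.0),
                            DoseEvent(1.0, "u1", 1.0, "infusion", 2.0)])
        lin = simulate(m, dose, grid)
        aff = simulate(m.to_control_affine(), dose, grid)
        assert np.abs(lin.states - aff.states).max() < 1e-6

    def test_halving_tolerances_converged(self):
        m = random_stable_linear_system(5, 1, 1, seed=11).to_control_affine()
        m.initial_state[:] = 1.0
        grid = np.linspace(0, 5, 50)
        coarse = simulate(m, time_grid=grid, rtol=1e-8, atol=1e-10)
        fine = simulate(m, time_grid=grid, rtol=5e-9, atol=5e-11)
        assert np.abs(coarse.outputs - fine.outputs).max() < 1e-8


class TestDosing:
    def test_bolus_at_zero_equals_amended_x0(self):
        grid = np.linspace(0, 5, 60)
        dosed = simulate(scalar_decay(x0=0.0),
                         DoseRegimen([DoseEvent(0.0, "u", 2.0)]), grid)
        amended = simulate(scalar_decay(x0=2.0), time_grid=grid)
        assert np.array_equal(dosed.states, amended.states)

    def test_mid_run_bolus_jump(self):
        grid = np.linspace(0, 4, 401)
        dose = DoseRegimen([DoseEvent(2.0, "u", 1.0)])
        traj = simulate(scalar_decay(x0=1.0), dose, grid)
        i = np.searchsorted(grid, 2.0)
        assert traj.states[i, 0] == pytest.approx(np.exp(-2.0) + 1.0, abs=1e-9)

    def test_infusion_total_delivery(self):
        # pure integrator: state accumulates exactly the infused amount
        m = LinearStateSpaceModel([[0.0]], [[1.0]], [[1.0]], ["x"], ["u"], ["y"])
        grid = np.linspace(0, 10, 100)
        dose = DoseRegimen([DoseEvent(1.0, "u", 7.0, "infusion", 3.0)])
        traj = simulate(m, dose, grid)
        assert traj.states[-1, 0] == pytest.approx(7.0, rel=1e-10)

    def test_unknown_channel_rejected(self):
        with pytest.raises(ConfigurationError, match="unknown input channel"):
            simulate(scalar_decay(), DoseRegimen([DoseEvent(0.0, "iv", 1.0)]),
                     np.linspace(0, 1, 10))

    def test_invalid_events_rejected(self):
        with pytest.raises(ConfigurationError):
            DoseEvent(-1.0, "u", 1.0)
        with pytest.raises(ConfigurationError):
            DoseEvent(0.0, "u", -5.0)
        with pytest.raises(ConfigurationError):
            DoseEvent(0.0, "u", 1.0, "infusion", 0.0)

    def test_scaled_regimen(self):
        d = DoseRegimen.single_oral_bolus(100.0, channel="u").scaled(0.1)
        assert d.events[0].amount == pytest.approx(10.0)


class TestStability:
    def test_scalar_cases(self):
        stable = LinearStateSpaceModel([[-1.0]], [[1.0]], [[1.0]], ["x"], ["u"], ["y"])
        marginal = LinearStateSpaceModel([[0.0]], [[1.0]], [[1.0]], ["x"], ["u"], ["y"])
        assert is_asymptotically_stable(stable)
        assert not is_asymptotically_stable(marginal)
        assert len(marginal_eigenvalues(marginal)) == 1
        assert len(marginal_eigenvalues(stable)) == 0

    def test_random_systems_are_stable_by_construction(self):
        for seed in range(5):
            m = random_stable_linear_system(8, 2, 2, seed=seed)
            assert is_asymptotically_stable(m)


class TestValidation:
    def test_shape_mismatches_raise(self):
        with pytest.raises(ValidationError):
            LinearStateSpaceModel(np.zeros((2, 3)), np.zeros((2, 1)),
                                  np.zeros((1, 2)), ["a", "b"], ["u"], ["y"])
        with pytest.raises(ValidationError):
            ControlAffineModel(["a"], lambda x: np.zeros(2), [],
                               lambda x: x, np.zeros(1), [], ["y"])

    def test_trajectory_grid_must_increase(self):
        with pytest.raises(ConfigurationError):
            simulate(scalar_decay(), time_grid=np.array([0.0, 2.0, 1.0]))

    def test_trajectory_output_lookup_and_csv(self, tmp_path):
        traj = simulate(scalar_decay(), time_grid=default_time_grid(1.0, 20))
        assert traj.output("y").shape == (20,)
        out = tmp_path / "t.csv"
        traj.to_csv(out)
        header = out.read_text().splitlines()[0]
        assert header == "time,y"
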