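"""Gramians, square-root balancing and truncation."""

import numpy as np
import pytest
from scipy.linalg import expm

from qspreduce.balanced_truncation import (balance, gramians, reduce_linear,
                                           truncate)
from qspreduce.core import (DoseRegimen, LinearStateSpaceModel,
                            default_time_grid, is_asymptotically_stable,
                            simulate)
from qspreduce.errors import ConfigurationError, StabilityError
from qspreduce.fixtures import random_stable_linear_system


def scalar_system(a=1.0, b=1.0, c=1.0):
    return LinearStateSpaceModel([[-a]], [[b]], [[c]], ["x"], ["u"], ["y"])


class TestGramians:
    def test_scalar_controllability_closed_form(self):
        # -2aP + b^2 = 0 -> P = b^2 / (2a)
        pair = gramians(scalar_system(a=1.0, b=1.0))
        assert pair.P[0, 0] == pytest.approx(0.5)

    def test_scalar_observability_closed_form(self):
        pair = gramians(scalar_system(a=2.0, c=1.0))
        assert pair.Q[0, 0] == pytest.approx(1.0 / 4.0)

    def test_lyapunov_residuals_small(self):
        m = random_stable_linear_system(8, 2, 2, seed=5)
        pair = gramians(m)
        rp, rq = pair.residuals(m)
        assert rp < 1e-8 * np.linalg.norm(m.B @ m.B.T)
        assert rq < 1e-8 * np.linalg.norm(m.C.T @ m.C)

    def test_matches_quadrature_of_integral_definition(self):
        """P = int_0^inf e^{At} B B' e^{A't} dt, truncated at large T."""
        m = random_stable_linear_system(8, 2, 1, seed=42,
                                        spectral_range=(0.5, 5.0))
        pair = gramians(m)
        ts = np.linspace(0, 40, 40001)
        integrand = np.array([
            (E := expm(m.A * t)) @ m.B @ m.B.T @ E.T for t in ts])
        P_quad = np.trapezoid(integrand, ts, axis=0)
        assert np.abs(pair.P - P_quad).max() < 1e-5 * np.abs(pair.P).max()

    def test_unstable_system_rejected_with_eigenvalues(self):
        m = LinearStateSpaceModel([[0.5]], [[1.0]], [[1.0]], ["x"], ["u"], ["y"])
        with pytest.raises(StabilityError) as err:
            gramians(m)
        assert err.value.eigenvalues is not None


class TestBalancing:
    def test_scalar_hankel_value(self):
        bal = balance(scalar_system())
        assert bal.hankel_singular_values[0] == pytest.approx(0.5)

    def test_balanced_gramians_are_equal_and_diagonal(self):
        m = random_stable_linear_system(7, 2, 3, seed=9)
        bal = balance(m)
        s = bal.hankel_singular_values
        mb = LinearStateSpaceModel(bal.A, bal.B, bal.C,
                                   [f"z{i}" for i in range(len(s))],
                                   m.input_names, m.output_names)
        pair = gramians(mb)
        assert np.abs(pair.P - np.diag(s)).max() < 1e-7 * s[0]
        assert np.abs(pair.Q - np.diag(s)).max() < 1e-7 * s[0]

    def test_transformation_inverse_consistent(self):
        m = random_stable_linear_system(6, 1, 1, seed=2)
        bal = balance(m)
        n = len(bal.hankel_singular_values)
        assert np.abs(bal.T_inv @ bal.T - np.eye(n)).max() < 1e-7

    def test_already_balanced_fixed_point(self):
        # symmetric SISO system: P == Q, balancing is (close to) identity
        bal0 = balance(scalar_system(a=3.0, b=2.0, c=2.0))
        assert abs(abs(bal0.T[0, 0]) - 1.0) < 1e-9

    @pytest.mark.parametrize("seed", range(5))
    def test_hankel_values_similarity_invariant(self, seed):
        m = random_stable_linear_system(8, 2, 2, seed=seed)
        rng = np.random.default_rng(seed + 1000)
        Q, _ = np.linalg.qr(rng.standard_normal((8, 8)))
        T = Q + 0.05 * rng.standard_normal((8, 8))
        Ti = np.linalg.inv(T)
        m2 = LinearStateSpaceModel(Ti @ m.A @ T, Ti @ m.B, m.C @ T,
                                   m.state_names, m.input_names, m.output_names)
        s1 = balance(m).hankel_singular_values
        s2 = balance(m2).hankel_singular_values
        assert np.abs(s1 - s2).max() / s1[0] < 1e-8


class TestTruncation:
    def test_full_order_preserves_transfer_function(self):
        m = random_stable_linear_system(5, 1, 1, seed=4)
        bal = balance(m)
        red = truncate(bal, len(bal.hankel_singular_values))
        assert red.error_bound == 0.0
        grid = np.linspace(0, 20, 400)
        dose = DoseRegimen([],)
        m.initial_state = np.zeros(5)
        d = DoseRegimen.single_oral_bolus(1.0, channel="u1")
        t1 = simulate(m, d, grid)
        t2 = simulate(red.model, d, grid)
        assert np.abs(t1.outputs - t2.outputs).max() < 1e-8

    def test_error_bound_formula(self):
        m = random_stable_linear_system(6, 1, 1, seed=8)
        bal = balance(m)
        red = truncate(bal, 2)
        s = bal.hankel_singular_values
        assert red.error_bound == pytest.approx(2 * s[2:].sum())

    def test_invalid_order_rejected(self):
        bal = balance(random_stable_linear_system(4, 1, 1, seed=1))
        with pytest.raises(ConfigurationError):
            truncate(bal, 0)
        with pytest.raises(ConfigurationError):
            truncate(bal, 7)

    def test_truncation_inside_sigma_cluster_moves_cut(self):
        # two identical decoupled SISO subsystems -> equal Hankel pair
        A = np.diag([-1.0, -1.0])
        B = np.array([[1.0], [1.0]])
        C = np.array([[1.0, 1.0]])
        # make them exactly symmetric under swap but coupled to I/O equally
        m = LinearStateSpaceModel(A, B, C, ["a", "b"], ["u"], ["y"])
        bal = balance(m)
        s = bal.hankel_singular_values
        if len(s) == 2 and np.isclose(s[0], s[1], rtol=1e-9):
            with pytest.warns(UserWarning, match="equal-sigma"):
                red = truncate(bal, 1)
            assert red.order == 2

    @pytest.mark.parametrize("seed", range(8))
    def test_reduced_system_stays_hurwitz(self, seed):
        m = random_stable_linear_system(9, 2, 2, seed=seed)
        bal = balance(m)
        s = bal.hankel_singular_values
        for k in range(1, len(s)):
            if np.isclose(s[k - 1], s[k], rtol=1e-9):
                continue
            red = truncate(bal, k)
            assert is_asymptotically_stable(red.model), (seed, k)

    def test_state_recovery_shape_and_outputs(self):
        m = random_stable_linear_system(6, 1, 2, seed=3)
        bal = balance(m)
        red = truncate(bal, 3)
        assert red.state_recovery.shape == (6, 3)
        # recovered outputs equal the reduced model's outputs: C @ T_k == C~
        assert np.allclose(m.C @ red.state_recovery, red.model.C)


class TestReduceLinear:
    def test_convenience_composition(self):
        m = random_stable_linear_system(8, 1, 1, seed=21)
        d = DoseRegimen.single_oral_bolus(1.0, channel="u1")
        grid = default_time_grid(20.0, 500)
        red, rep = reduce_linear(m, 8, d, grid)
        assert rep.epsilon < 1e-8
        red3, rep3 = reduce_linear(m, 3, d, grid)
        assert rep3.epsilon >= 0.0
        assert red3.model.n_states == 3
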