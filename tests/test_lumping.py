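"""Proper lumping and the forward-selection search."""

import itertools

import numpy as np
import pytest

from qspreduce.core import (DoseRegimen, LinearStateSpaceModel,
                            default_time_grid, simulate)
from qspreduce.errors import ConfigurationError, ValidationError
from qspreduce.fixtures import parallel_compartments, random_stable_linear_system
from qspreduce.lumping import (LumpingMatrix, apply_lumping, forward_selection,
                               moore_penrose_partition_inverse,
                               weighted_partition_inverse)
from qspreduce.metrics import maximal_relative_error


class TestPartitionInverse:
    def test_two_into_one_closed_form(self):
        L = np.array([[1.0, 1.0]])
        assert np.allclose(moore_penrose_partition_inverse(L),
                           np.array([[0.5], [0.5]]))

    def test_identity(self):
        L = np.eye(4)
        assert np.allclose(moore_penrose_partition_inverse(L), np.eye(4))

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_generic_pseudoinverse(self, seed, rng):
        r = np.random.default_rng(seed)
        n = int(r.integers(2, 9))
        nhat = int(r.integers(1, n + 1))
        assignment = r.integers(0, nhat, size=n)
        assignment[:nhat] = np.arange(nhat)  # no empty lump
        L = np.zeros((nhat, n))
        L[assignment, np.arange(n)] = 1.0
        assert np.allclose(moore_penrose_partition_inverse(L),
                           np.linalg.pinv(L), atol=1e-12)

    def test_weighted_inverse_distributes_by_weight(self):
        L = np.array([[1.0, 1.0, 0.0], [0.0, 0.0, 1.0]])
        w = np.array([1.0, 3.0, 2.0])
        Lbar = weighted_partition_inverse(L, w)
        assert np.allclose(Lbar[:, 0], [0.25, 0.75, 0.0])
        assert np.allclose(L @ Lbar, np.eye(2))

    def test_improper_matrices_rejected(self):
        with pytest.raises(ValidationError):
            moore_penrose_partition_inverse(np.array([[1.0, 1.0], [0.0, 1.0]]))
        with pytest.raises(ValidationError):
            moore_penrose_partition_inverse(np.array([[1.0, 0.0], [0.0, 0.0]]))
        with pytest.raises(ValidationError):
            weighted_partition_inverse(np.array([[1.0, 1.0]]),
                                       np.array([1.0, -1.0]))


class TestApplyLumping:
    def test_identity_lumping_is_identity(self):
        m = random_stable_linear_system(5, 1, 1, seed=0)
        m.initial_state = np.ones(5)
        lm = LumpingMatrix.from_groups([[i] for i in range(5)], 5)
        red = apply_lumping(m, lm)
        grid = np.linspace(0, 5, 100)
        t1 = simulate(m, time_grid=grid)
        t2 = simulate(red, time_grid=grid)
        assert np.array_equal(t1.outputs, t2.outputs)

    def test_identical_parallel_compartments_lump_exactly(self):
        m = parallel_compartments(n_parallel=3)
        lm = LumpingMatrix.from_groups([[0], [1, 2, 3]], 4)
        red = apply_lumping(m, lm)
        grid = default_time_grid(20.0, 400)
        dose = DoseRegimen.single_oral_bolus(1.0, channel="inflow")
        rep = maximal_relative_error(simulate(m, dose, grid),
                                     simulate(red, dose, grid))
        assert rep.epsilon < 1e-8

    def test_nonlinear_model_lumps_through_inverse_image(self):
        from qspreduce.fixtures import receptor_cascade
        m = receptor_cascade()
        lm = LumpingMatrix.from_groups([[0], [1], [2, 4], [3], [5]], 6)
        red = apply_lumping(m, lm)
        assert red.n_states == 5
        # outputs remain evaluable and start from the same value
        assert np.allclose(red.output_map(red.initial_state),
                           m.output_map(m.initial_state))

    def test_dimension_mismatch_rejected(self):
        m = random_stable_linear_system(5, 1, 1, seed=0)
        lm = LumpingMatrix.from_groups([[0, 1], [2]], 3)
        with pytest.raises(ValidationError):
            apply_lumping(m, lm)

    def test_lumped_totals_conserved(self):
        """For a closed mass-conserving system, lump sums track state sums."""
        A = np.array([[-1.0, 0.5], [1.0, -0.5]])  # columns sum to 0
        m = LinearStateSpaceModel(A, np.zeros((2, 1)), np.eye(2),
                                  ["a", "b"], ["u"], ["ya", "yb"],
                                  initial_state=[1.0, 0.0])
        lm = LumpingMatrix.from_groups([[0, 1]], 2)
        red = apply_lumping(m, lm)
        grid = np.linspace(0, 10, 200)
        t_full = simulate(m, time_grid=grid)
        t_red = simulate(red, time_grid=grid)
        assert np.allclose(t_red.states[:, 0], t_full.states.sum(axis=1),
                           atol=1e-9)


class TestForwardSelection:
    def test_target_n_returns_identity(self):
        m = random_stable_linear_system(4, 1, 1, seed=7)
        d = DoseRegimen.single_oral_bolus(1.0, channel="u1")
        lm, trace = forward_selection(m, 4, [d], np.linspace(0, 5, 50))
        assert lm.n_lumps == 4
        assert trace.steps == []

    def test_parallel_fixture_found_first_and_exact(self):
        m = parallel_compartments(n_parallel=2)
        d = DoseRegimen.single_oral_bolus(1.0, channel="inflow")
        lm, trace = forward_selection(m, 2, [d], np.linspace(0, 20, 200))
        groups = sorted(map(sorted, lm.groups()))
        assert [1, 2] in groups          # the identical pair merged
        assert trace.steps[-1]["epsilon"] < 1e-8

    def test_greedy_at_least_as_bad_as_exhaustive(self):
        """On a 4-state chain, greedy epsilon >= the best over all proper
        2-partitions (and both are finite)."""
        A = np.array([[-2.0, 0.0, 0.0, 0.0],
                      [2.0, -1.0, 0.0, 0.0],
                      [0.0, 1.0, -0.5, 0.0],
                      [0.0, 0.0, 0.5, -0.25]])
        m = LinearStateSpaceModel(A, np.array([[1.0], [0], [0], [0]]),
                                  np.array([[0.0, 0, 0, 1.0]]),
                                  list("abcd"), ["u"], ["y"])
        d = DoseRegimen.single_oral_bolus(1.0, channel="u")
        grid = np.linspace(0, 30, 300)
        lm, trace = forward_selection(m, 2, [d], grid)
        greedy_eps = trace.steps[-1]["epsilon"]

        ref = simulate(m, d, grid)
        best = np.inf
        for part in _two_partitions(4):
            cand = apply_lumping(m, LumpingMatrix.from_groups(part, 4))
            rep = maximal_relative_error(ref, simulate(cand, d, grid))
            best = min(best, rep.epsilon)
        assert greedy_eps >= best - 1e-12
        assert np.isfinite(greedy_eps)

    def test_trace_dimensions_strictly_decreasing(self):
        m = random_stable_linear_system(6, 1, 1, seed=12)
        d = DoseRegimen.single_oral_bolus(1.0, channel="u1")
        _, trace = forward_selection(m, 2, [d], np.linspace(0, 10, 80))
        dims = [s["dimension"] for s in trace.steps]
        assert dims == list(range(5, 1, -1))

    def test_invalid_target_rejected(self):
        m = random_stable_linear_system(3, 1, 1, seed=0)
        d = DoseRegimen.single_oral_bolus(1.0, channel="u1")
        with pytest.raises(ConfigurationError):
            forward_selection(m, 0, [d], np.linspace(0, 1, 10))
        with pytest.raises(ConfigurationError):
            forward_selection(m, 2, [], np.linspace(0, 1, 10))

    def test_deterministic_rerun(self):
        m = random_stable_linear_system(6, 1, 1, seed=19)
        d = DoseRegimen.single_oral_bolus(1.0, channel="u1")
        grid = np.linspace(0, 10, 60)
        lm1, _ = forward_selection(m, 3, [d], grid)
        lm2, _ = forward_selection(m, 3, [d], grid)
        assert np.array_equal(lm1.L, lm2.L)


def _two_partitions(n):
    """All partitions of range(n) into exactly 2 non-empty groups."""
    items = list(range(n))
    for mask in range(1, 2 ** (n - 1)):
        g1 = [items[i] for i in range(n) if mask >> i & 1]
        g2 = [i for i in items if i not in g1]
        if g2:
            yield [g1, g2]
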