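"""Whole-body PBPK model construction."""

import numpy as np
import pytest

from qspreduce.core import (DoseRegimen, default_time_grid,
                            is_asymptotically_stable, simulate)
from qspreduce.errors import ConfigurationError, ValidationError
from qspreduce.pbpk import (amount_coordinates, build_pbpk, compound_fixture,
                            default_outputs, lumping_weights,
                            physiological_fixture, split_oral_depot,
                            tissue_volumes, STATE_NAMES)

COMPOUNDS = ["pindolol", "midazolam", "thiopental"]


class TestParameterArithmetic:
    def test_flows_and_volumes_from_table(self, phys):
        assert phys.flow("ad") == pytest.approx(0.05 * 390)        # 19.5 L/h
        assert phys.volume("li") == pytest.approx(0.021 * 70)      # 1.47 L
        assert phys.flow("lu") == pytest.approx(390.0)

    def test_hepatic_clearance_conversion(self):
        mid = compound_fixture("midazolam")
        assert mid.hepatic_clearance(70.0) == pytest.approx(36.54)

    def test_residual_flow_split_balances_cardiac_output(self, phys):
        systemic = sum(phys.flow(t) for t in
                       ["ad", "bo", "br", "he", "ki", "mu", "sk", "te", "re"])
        splanchnic = phys.FQ["h"] * phys.QC
        assert systemic + splanchnic == pytest.approx(phys.QC)

    def test_residual_kp_is_mean_of_printed(self):
        c = compound_fixture("pindolol")
        assert c.kp("te") == pytest.approx(np.mean(list(c.Kp.values())))
        assert c.kp("re") == c.kp("te")

    def test_parameter_validation(self, phys):
        bad = compound_fixture("midazolam")
        bad.fu_p = 1.5
        with pytest.raises(ValidationError):
            bad.__post_init__()


class TestModelStructure:
    @pytest.mark.parametrize("kp_reference", ["blood", "plasma"])
    @pytest.mark.parametrize("name", COMPOUNDS)
    def test_hurwitz_for_all_compounds(self, phys, name, kp_reference):
        m = build_pbpk(phys, compound_fixture(name), kp_reference=kp_reference)
        assert is_asymptotically_stable(m)

    def test_compartmental_sign_structure(self, pbpk_model):
        A = pbpk_model.A
        off = A - np.diag(np.diag(A))
        assert np.all(off >= 0)
        assert np.all(np.diag(A) < 0)

    def test_single_mass_sink_is_hepatic(self, phys):
        """Column sums of the mass-flow matrix vanish except for the liver."""
        comp = compound_fixture("midazolam")
        m = build_pbpk(phys, comp)
        vols = tissue_volumes(phys)
        v = np.array([vols[s] for s in m.state_names])
        # mass-flow matrix: d(mass)/dt = diag(v) A diag(1/v) @ mass
        M = (v[:, None] * m.A) / v[None, :]
        col = M.sum(axis=0)
        i_li = m.state_names.index("liver")
        for i, s in enumerate(m.state_names):
            if i == i_li:
                assert col[i] < -1e-9
            else:
                assert abs(col[i]) < 1e-9, s

    def test_state_naming(self, pbpk_model):
        assert pbpk_model.state_names == STATE_NAMES
        assert pbpk_model.input_names == ["oral", "IV"]

    def test_hepatic_flow_inconsistency_rejected(self, phys):
        phys.FQ["gu"] = 0.20
        phys.FQ["sp"] = 0.10   # gut+spleen > FQh = 0.215
        with pytest.raises(ConfigurationError, match="hepatic arterial"):
            build_pbpk(phys, compound_fixture("midazolam"))

    def test_clearance_above_hepatic_flow_warns(self, phys):
        fast = compound_fixture("midazolam")
        fast.CL_bl = 25.0   # 105 L/h > Q_h = 83.85 L/h
        with pytest.warns(UserWarning, match="hepatic clearance"):
            build_pbpk(phys, fast)


class TestOutputs:
    def test_single_output_selector(self, pbpk_model):
        m = default_outputs(pbpk_model, ["venous"])
        assert m.C.shape == (1, 16)
        assert m.C.sum() == 1.0
        assert m.C[0, m.state_names.index("venous")] == 1.0

    def test_two_output_rows_orthonormal(self, pbpk_model):
        m = default_outputs(pbpk_model, ["venous", "liver"])
        assert np.allclose(m.C @ m.C.T, np.eye(2))

    def test_identity_output_allowed(self, pbpk_model):
        m = default_outputs(pbpk_model, list(pbpk_model.state_names))
        assert np.allclose(m.C, np.eye(16))

    def test_empty_or_unknown_selection_rejected(self, pbpk_model):
        with pytest.raises(ConfigurationError):
            default_outputs(pbpk_model, [])
        with pytest.raises(ConfigurationError):
            default_outputs(pbpk_model, ["pancreas"])


class TestDynamics:
    def test_oral_profile_single_peak_then_decline(self, phys):
        m = build_pbpk(phys, compound_fixture("midazolam"))
        traj = simulate(m, DoseRegimen.single_oral_bolus(500.0),
                        default_time_grid(48.0, 1000))
        y = traj.output("venous")
        ipk = int(np.argmax(y))
        assert 0 < ipk < len(y) - 1
        assert np.all(np.diff(y[:ipk + 1]) > -1e-12)   # rise
        assert np.all(np.diff(y[ipk:]) < 1e-12)        # monotone decline

    def test_mass_conserved_without_clearance(self, phys):
        comp = compound_fixture("thiopental")
        comp.CL_bl = 0.0
        m = build_pbpk(phys, comp)
        traj = simulate(m, DoseRegimen.single_oral_bolus(500.0),
                        default_time_grid(48.0, 500))
        vols = tissue_volumes(phys)
        v = np.array([vols[s] for s in m.state_names])
        mass = traj.states @ v
        assert np.abs(mass - 500.0).max() / 500.0 < 1e-8

    def test_mass_decreases_with_clearance(self, phys):
        m = build_pbpk(phys, compound_fixture("midazolam"))
        traj = simulate(m, DoseRegimen.single_oral_bolus(500.0),
                        default_time_grid(96.0, 500))
        vols = tissue_volumes(phys)
        v = np.array([vols[s] for s in m.state_names])
        mass = traj.states @ v
        assert np.all(np.diff(mass) <= 1e-9)
        assert mass[-1] < 0.05 * 500.0

    def test_states_stay_nonnegative(self, pbpk_model):
        traj = simulate(pbpk_model, DoseRegimen.single_oral_bolus(500.0),
                        default_time_grid(48.0, 500))
        assert traj.states.min() > -1e-9

    def test_iv_dose_enters_venous(self, phys):
        m = build_pbpk(phys, compound_fixture("pindolol"))
        traj = simulate(m, DoseRegimen.single_iv_bolus(100.0),
                        default_time_grid(1.0, 50))
        v_ve = tissue_volumes(phys)["venous"]
        assert traj.output("venous")[0] == pytest.approx(100.0 / v_ve)


class TestCoordinateHelpers:
    def test_amount_coordinates_preserve_outputs(self, phys):
        m = build_pbpk(phys, compound_fixture("pindolol"))
        ma = amount_coordinates(m, phys)
        grid = default_time_grid(24.0, 200)
        dose = DoseRegimen.single_oral_bolus(100.0)
        t1 = simulate(m, dose, grid)
        t2 = simulate(ma, dose, grid)
        assert np.abs(t1.outputs - t2.outputs).max() < 1e-9

    def test_lumping_weights_positive_and_named(self, phys):
        comp = compound_fixture("midazolam")
        m = build_pbpk(phys, comp)
        w = lumping_weights(phys, comp, m.state_names)
        assert w.shape == (16,)
        assert np.all(w > 0)
        assert w[m.state_names.index("oral_depot")] == 1.0

    def test_split_oral_depot_roundtrip(self, phys):
        from qspreduce.workflows import attach_oral_depot
        comp = compound_fixture("thiopental")
        m = build_pbpk(phys, comp)
        m1 = m.with_outputs(m.C, m.output_names)
        m1.B = m.B[:, [0]]
        m1.input_names = ["oral"]
        block, _ = split_oral_depot(m1, comp.Ka)
        assert block.n_states == 15
        rebuilt = attach_oral_depot(block, comp.Ka)
        grid = default_time_grid(24.0, 300)
        dose = DoseRegimen.single_oral_bolus(200.0)
        t1 = simulate(m1, dose, grid)
        t2 = simulate(rebuilt, dose, grid)
        assert np.abs(t1.outputs - t2.outputs).max() < 1e-9
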