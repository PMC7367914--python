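"""mPBPK model: volume derivation, clearances, integration, endpoints."""

import math

import numpy as np
import pytest

from pbpkgsa.drugs import EnzymePathway, SubPathway, load_drug
from pbpkgsa.mpbpk import (
    InfeasibleSubjectError,
    PBPKModel,
    PKEndpoints,
    Trajectory,
    auc_infinity_oracle,
    derive_vsys,
    endpoints,
    evaluate_endpoints,
    hepatic_clint,
    simulate,
)
from pbpkgsa.population import sample_copula


class TestDeriveVsys:
    def test_central_quinidine_values(self):
        # V_ss, Kp, V_liver, BW at their table medians
        v = derive_vsys(1.878, 4.37, 1.48, 0.0, 73.7, 0.89)
        assert v == pytest.approx(148.3, abs=0.1)

    def test_identity_case(self):
        assert derive_vsys(2.0, 0.0, 1.0, 0.0, 70.0, 1.0) == pytest.approx(140.0)

    def test_boundary_rejection(self):
        # V_ss*BW == Kp*V_liver makes the systemic volume vanish
        v = derive_vsys(0.02, 1.0, 1.4, 0.0, 70.0, 1.0)
        assert v == pytest.approx(0.0)
        drug = load_drug("quinidine")
        vals = {m.name: m.quantile(0.5) for m in drug.varying}
        vals.update(V_ss=0.019, Kp_liver=1.0, V_liver=1.4, BW=70.0, BP=1.0)
        with pytest.raises(InfeasibleSubjectError):
            simulate(drug, vals)


class TestHepaticClint:
    def test_direct_sum_of_table_medians(self):
        drug = load_drug("quinidine")
        vals = {"CLint_CYP2E1": math.exp(0.47), "CLint_CYP2C9": math.exp(0.18),
                "CLint_CYP3A4": math.exp(4.35)}
        assert hepatic_clint(drug.pathways, 0.0, vals) == pytest.approx(80.28, abs=0.01)

    def test_michaelis_menten_single_pathway(self):
        pw = (EnzymePathway("CYP3A4", abundance_param="A",
                            subpathways=(SubPathway("1-OH", "Vm", "Km"),)),)
        vals = {"A": 7.6e6, "Vm": 5.23, "Km": 2.16}
        # pmol/min/uM -> L/h conversion: x 60e-6
        assert hepatic_clint(pw, 0.0, vals) == pytest.approx(1104.0, rel=1e-3)

    def test_saturation_limit(self):
        pw = (EnzymePathway("CYP3A4", abundance_param="A",
                            subpathways=(SubPathway("1-OH", "Vm", "Km"),)),)
        vals = {"A": 7.6e6, "Vm": 5.23, "Km": 2.16}
        assert hepatic_clint(pw, 1e12, vals) == pytest.approx(0.0, abs=1e-6)

    def test_negative_inputs_rejected(self):
        drug = load_drug("quinidine")
        with pytest.raises(ValueError):
            hepatic_clint(drug.pathways, -1.0, {})


class TestSimulate:
    def test_zero_dose_gives_flat_zero(self, quinidine_model):
        drug = quinidine_model.drug.replace(dose_mg=0.0)
        vals = quinidine_model.median_subject()
        traj = simulate(drug, vals)
        assert np.allclose(traj.C_sys, 0.0, atol=1e-12)
        ep = endpoints(traj, vals["BP"])
        assert ep == PKEndpoints(0.0, 0.0, 0.0, 0.0)

    def test_mass_conservation_without_elimination(self, quinidine_model):
        # zero all clearances: absorbed amount must be conserved
        vals = dict(quinidine_model.median_subject())
        vals.update(CLint_CYP2E1=0.0, CLint_CYP2C9=0.0, CLint_CYP3A4=0.0, CL_R=0.0)
        drug = quinidine_model.drug
        traj = simulate(drug, vals, t_end=48.0)
        from pbpkgsa.mpbpk import assemble_parameters

        p = assemble_parameters(drug, vals)
        total = (p["V_sys"] * traj.C_sys + p["V_pv"] * traj.C_pv
                 + p["V_liver"] * traj.C_liver)
        absorbed = vals["fa"] * vals["Fg"] * drug.dose_mg
        expected = absorbed * (1 - np.exp(-vals["ka"] * traj.t))
        late = traj.t > 5.0  # absorption essentially complete
        drift = np.abs(total[late] - absorbed) / absorbed
        assert drift.max() < 1e-4
        assert np.allclose(total[1:], expected[1:], rtol=2e-4)

    def test_dose_linearity_direct_clearance(self, quinidine_model):
        vals = quinidine_model.median_subject()
        drug = quinidine_model.drug
        e1 = endpoints(simulate(drug, vals), vals["BP"])
        e2 = endpoints(simulate(drug.replace(dose_mg=2 * drug.dose_mg), vals),
                       vals["BP"])
        assert e2.C_max == pytest.approx(2 * e1.C_max, rel=1e-3)
        assert e2.AUC_48h == pytest.approx(2 * e1.AUC_48h, rel=1e-3)
        assert e2.T_max == pytest.approx(e1.T_max, rel=1e-3)

    def test_auc_ordering_and_negativity(self, midazolam_model):
        vals = midazolam_model.median_subject()
        traj = simulate(midazolam_model.drug, vals)
        assert np.all(traj.C_sys >= -1e-9)
        ep = endpoints(traj, vals["BP"])
        assert ep.AUC_24h <= ep.AUC_48h
        assert 0 <= ep.T_max <= 48
        # midazolam's short half-life: nearly all exposure within 24 h
        assert ep.AUC_24h / ep.AUC_48h > 0.98


class TestAUCOracle:
    def test_matrix_solution_matches_long_integration(self, quinidine_model):
        # 100 random subjects: stationary linear-system AUC vs integration
        model = quinidine_model
        pop = sample_copula(list(model.drug.marginals), model.corr, 100, seed=99)
        worst = 0.0
        for _, row in pop.iterrows():
            vals = {k: float(row[k]) for k in model.labels}
            oracle = auc_infinity_oracle(model.drug, vals)
            traj = simulate(model.drug, vals, t_end=400.0, grid=0.1)
            worst = max(worst, abs(traj.auc_plasma[-1] / oracle - 1.0))
        assert worst < 1e-3


class TestEndpoints:
    def _curve_traj(self, bp=1.0):
        t = np.arange(0, 48.0 + 1e-9, 0.01)
        c = t * np.exp(-t) * bp  # blood concentration, plasma = c/bp
        auc = 1 - (t + 1) * np.exp(-t)  # exact integral of t e^-t
        z = np.zeros_like(t)
        return Trajectory(t, c, z, z, z, auc)

    def test_closed_form_peak(self):
        ep = endpoints(self._curve_traj(), BP=1.0)
        assert ep.C_max == pytest.approx(math.exp(-1), rel=1e-6)
        assert ep.T_max == pytest.approx(1.0, abs=1e-4)
        assert ep.AUC_24h == pytest.approx(1 - 25 * math.exp(-24), rel=1e-9)

    def test_blood_plasma_scaling(self):
        # same blood curve at BP=2 halves the plasma-scale endpoints
        e1 = endpoints(self._curve_traj(), BP=1.0)
        e2 = endpoints(self._curve_traj(), BP=2.0)
        assert e2.C_max == pytest.approx(e1.C_max / 2, rel=1e-9)


class TestBatchPaths:
    @pytest.mark.parametrize("name", ["quinidine", "alprazolam", "midazolam"])
    def test_batch_matches_reference_integrator(self, name):
        model = PBPKModel.from_drug(name)
        pop = sample_copula(list(model.drug.marginals), model.corr, 12, seed=42)
        batch, nbad = evaluate_endpoints(model.drug, pop[list(model.labels)])
        assert nbad == 0
        for i, (_, row) in enumerate(pop.iterrows()):
            vals = {k: float(row[k]) for k in model.labels}
            ref = endpoints(simulate(model.drug, vals), vals["BP"]).as_array()
            assert batch[i] == pytest.approx(ref, rel=2e-3)

    def test_infeasible_rows_are_nan_and_counted(self, quinidine_model):
        model = quinidine_model
        vals = model.median_subject()
        X = np.array([[vals[k] for k in model.labels]] * 3)
        bad = dict(zip(model.labels, X[1]))
        X[1, list(model.labels).index("V_ss")] = 1e-6  # forces V_sys < 0
        out, nbad = evaluate_endpoints(
            model.drug, {k: X[:, j] for j, k in enumerate(model.labels)})
        assert nbad == 1
        assert np.isnan(out[1]).all()
        assert np.isfinite(out[0]).all() and np.isfinite(out[2]).all()
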