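"""Gaussian-copula population sampling, correlation estimation/screening."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from pbpkgsa.drugs import default_fixture
from pbpkgsa.marginals import MarginalSpec
from pbpkgsa.population import (
    CorrelationRepairError,
    CorrelationSpec,
    adjust_correlation,
    estimate_correlation,
    nearest_psd,
    sample_copula,
)
from pbpkgsa.testfunctions import wide_normal_marginal


def _lognormals(k):
    return [MarginalSpec(f"x{i+1}", "lognormal", 0.0, 0.1, 1e-6, 50) for i in range(k)]


class TestSampleCopula:
    def test_independent_columns_nearly_uncorrelated(self):
        pop = sample_copula(_lognormals(2), CorrelationSpec.identity(["x1", "x2"]),
                            5000, seed=0)
        r = np.corrcoef(pop.x1, pop.x2)[0, 1]
        assert abs(r) < 0.05

    def test_strong_latent_correlation_recovered(self):
        # the 0.9 value used for the Kp_liver-fu link
        margs = [wide_normal_marginal("x1"), wide_normal_marginal("x2")]
        corr = CorrelationSpec(("x1", "x2"), np.array([[1, 0.9], [0.9, 1]]))
        pop = sample_copula(margs, corr, 5000, seed=1)
        r = np.corrcoef(pop.x1, pop.x2)[0, 1]
        assert 0.87 <= r <= 0.93

    def test_single_subject_within_bounds(self, quinidine):
        drug, corr = quinidine
        pop = sample_copula(list(drug.marginals), corr, 1, seed=3)
        assert len(pop) == 1
        for m in drug.varying:
            assert m.lower <= float(pop[m.name].iloc[0]) <= m.upper

    def test_fixed_marginals_are_constant(self):
        margs = _lognormals(1) + [
            MarginalSpec("c", "fixed", value=2.5, lower=0, upper=10)]
        pop = sample_copula(margs, None, 100, seed=0)
        assert (pop.c == 2.5).all()

    def test_copula_roundtrip_recovers_target_matrix(self):
        # untruncated normal marginals: latent correlation == value correlation
        labels = ("a", "b", "c")
        target = np.array([[1.0, 0.5, 0.2], [0.5, 1.0, -0.3], [0.2, -0.3, 1.0]])
        margs = [wide_normal_marginal(l) for l in labels]
        pop = sample_copula(margs, CorrelationSpec(labels, target), 5000, seed=5)
        est, _ = estimate_correlation(pop)
        assert np.abs(est.matrix - target).max() < 0.04

    def test_marginals_preserved_under_correlation(self, quinidine):
        # K-S test of each column against its truncated marginal at alpha=0.01
        drug, corr = quinidine
        pop = sample_copula(list(drug.marginals), corr, 2000, seed=11)
        for m in drug.varying:
            d, p = stats.kstest(pop[m.name], m.cdf)
            assert p > 0.01, f"{m.name}: KS p={p:.4f}"
            assert pop[m.name].between(m.lower, m.upper).all()


class TestEstimateCorrelation:
    def test_duplicated_column_r_one(self, rng):
        x = rng.uniform(size=500)
        est, p = estimate_correlation(pd.DataFrame({"a": x, "b": x}))
        assert est.entry("a", "b") == pytest.approx(1.0)
        assert p.loc["a", "b"] == pytest.approx(0.0, abs=1e-12)

    def test_negated_column_r_minus_one(self, rng):
        x = rng.uniform(size=500)
        est, _ = estimate_correlation(pd.DataFrame({"a": x, "b": -x}))
        assert est.entry("a", "b") == pytest.approx(-1.0)

    def test_independent_columns_small_r(self, rng):
        df = pd.DataFrame(rng.uniform(size=(2000, 2)), columns=["a", "b"])
        est, p = estimate_correlation(df)
        assert abs(est.entry("a", "b")) < 0.05
        assert p.loc["a", "b"] > 0.0

    def test_constant_column_warns_and_zeroes(self, rng):
        df = pd.DataFrame({"a": rng.uniform(size=100), "b": np.ones(100)})
        with pytest.warns(UserWarning, match="constant"):
            est, p = estimate_correlation(df)
        assert est.entry("a", "b") == 0.0
        assert p.loc["a", "b"] == 1.0


class TestAdjustCorrelation:
    def _spec(self, r):
        return CorrelationSpec(("a", "b"), np.array([[1.0, r], [r, 1.0]]))

    @pytest.mark.parametrize(
        "r, p, expected",
        [
            (0.08, 0.001, 0.0),  # weak although significant
            (0.5, 0.20, 0.0),    # strong but not significant
            (0.6, 0.001, 0.6),   # passes both screens
        ],
    )
    def test_screening_rules(self, r, p, expected):
        pmat = np.array([[0.0, p], [p, 0.0]])
        out = adjust_correlation(self._spec(r), pmat)
        assert out.entry("a", "b") == pytest.approx(expected)
        assert np.allclose(np.diag(out.matrix), 1.0)

    def test_idempotent(self, quinidine):
        drug, corr = quinidine
        pop = sample_copula(list(drug.marginals), corr, 1000, seed=21)
        est, p = estimate_correlation(pop[list(drug.varying_labels)])
        once = adjust_correlation(est, p)
        twice = adjust_correlation(once, p)
        assert np.allclose(once.matrix, twice.matrix)


class TestPSD:
    def test_nearest_psd_projects_and_keeps_unit_diagonal(self):
        bad = np.array([[1.0, 0.9, -0.9], [0.9, 1.0, 0.9], [-0.9, 0.9, 1.0]])
        fixed = nearest_psd(bad)
        assert np.linalg.eigvalsh(fixed).min() >= -1e-10
        assert np.allclose(np.diag(fixed), 1.0)

    def test_repair_beyond_tolerance_rejected(self):
        bad = CorrelationSpec(
            ("a", "b", "c"),
            np.array([[1.0, 0.9, -0.9], [0.9, 1.0, 0.9], [-0.9, 0.9, 1.0]]))
        with pytest.raises(CorrelationRepairError):
            sample_copula(_lognormals(3), CorrelationSpec(
                ("x1", "x2", "x3"), bad.matrix), 10, seed=0)

    def test_mild_violation_repaired_with_warning(self):
        m = np.array([[1.0, 0.7, 0.7], [0.7, 1.0, -0.1], [0.7, -0.1, 1.0]])
        spec = CorrelationSpec(("x1", "x2", "x3"), m)
        assert not spec.is_psd()
        with pytest.warns(UserWarning, match="repaired"):
            pop = sample_copula(_lognormals(3), spec, 100, seed=0)
        assert len(pop) == 100


class TestDefaultFixture:
    @pytest.mark.parametrize(
        "name, n_varying, dose",
        [("quinidine", 16, 200.0), ("alprazolam", 15, 0.5), ("midazolam", 16, 5.0)],
    )
    def test_fixture_shape(self, name, n_varying, dose):
        drug, corr = default_fixture(name)
        assert len(drug.varying) == n_varying
        assert drug.dose_mg == dose
        assert corr.labels == drug.varying_labels
        assert corr.is_psd()
        assert corr.entry("Kp_liver", "fu") == pytest.approx(0.9)
        assert "non-published" in corr.meta["source"]

    def test_midazolam_fixed_constants(self):
        drug, _ = default_fixture("midazolam")
        assert drug.sac_enabled and drug.clearance_mode == "michaelis_menten"
        fixed = drug.fixed_values
        assert fixed["Vm_CYP3A4_1OH"] == 5.23
        assert fixed["K_out"] == 0.25
        assert fixed["V_sac"] == 0.23

    def test_overrides_respected(self):
        drug, corr = default_fixture(
            "quinidine", correlation_overrides={("BW", "Q_HA"): 0.2})
        assert corr.entry("BW", "Q_HA") == pytest.approx(0.2)

    def test_unknown_drug_rejected(self):
        with pytest.raises(ValueError):
            default_fixture("aspirin")
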