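"""Truncated marginal distributions: quantile/CDF correctness and AIC fits."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from pbpkgsa.drugs import load_drug
from pbpkgsa.marginals import (
    DegenerateSupportError,
    DomainError,
    FitError,
    MarginalSpec,
    SpecError,
    fit_best,
)


@pytest.mark.parametrize(
    "spec, u, expected, tol",
    [
        # portal-vein volume: symmetric truncation, median = mean
        (MarginalSpec("V_pv", "normal", 0.008, 6.4e-7, 1e-6, 0.15), 0.5, 0.008, 1e-6),
        # fixed constant ignores u
        (MarginalSpec("Vm", "fixed", value=5.23, lower=0, upper=10), 0.3, 5.23, 0),
        (MarginalSpec("Vm", "fixed", value=5.23, lower=0, upper=10), 0.9, 5.23, 0),
    ],
)
def test_quantile_point_values(spec, u, expected, tol):
    assert spec.quantile(u) == pytest.approx(expected, abs=tol)


def test_lognormal_untruncated_median_body_weight():
    # body weight lognormal(4.30, 0.038): untruncated median exp(4.30) = 73.70 kg
    bw = MarginalSpec("BW", "lognormal", 4.30, 3.8e-2, 30, 200)
    dist = stats.lognorm(s=math.sqrt(3.8e-2), scale=math.exp(4.30))
    lo, hi = dist.cdf([30, 200])
    u_star = (0.5 - lo) / (hi - lo)  # u mapping to the untruncated median
    assert bw.quantile(u_star) == pytest.approx(math.exp(4.30), rel=1e-6)
    assert bw.quantile(u_star) == pytest.approx(73.70, abs=0.005)


def test_weibull_untruncated_median_fraction_absorbed():
    # f_a Weibull(8.86, 0.94): untruncated median = scale * (ln 2)^(1/shape)
    fa = MarginalSpec("fa", "weibull", 8.86, 0.94, 1e-6, 1.0)
    med = 0.94 * math.log(2) ** (1 / 8.86)
    dist = stats.weibull_min(c=8.86, scale=0.94)
    lo, hi = dist.cdf([1e-6, 1.0])
    u_star = (0.5 - lo) / (hi - lo)
    assert fa.quantile(u_star) == pytest.approx(med, rel=1e-9)
    assert med == pytest.approx(0.902, abs=5e-4)


@pytest.mark.parametrize("drug_name", ["quinidine", "alprazolam", "midazolam"])
def test_cdf_quantile_roundtrip_and_bounds(drug_name):
    drug = load_drug(drug_name)
    for m in drug.varying:
        assert m.cdf(m.lower) == pytest.approx(0.0, abs=1e-12)
        assert m.cdf(m.upper) == pytest.approx(1.0, abs=1e-12)
        for u in (0.1, 0.5, 0.9):
            assert m.cdf(m.quantile(u)) == pytest.approx(u, rel=1e-9, abs=1e-9)


@pytest.mark.parametrize("drug_name", ["quinidine", "alprazolam", "midazolam"])
def test_quantile_monotone_on_grid(drug_name):
    drug = load_drug(drug_name)
    u = np.linspace(0, 1, 101)
    for m in drug.varying:
        q = m.quantile(u)
        assert np.all(np.diff(q) >= 0)
        assert q[0] >= m.lower - 1e-12 and q[-1] <= m.upper + 1e-12


def test_truncated_normal_moments_match_analytic(rng):
    # sharply truncated normal: sample moments vs scipy.truncnorm analytics
    spec = MarginalSpec("x", "normal", 1.0, 4.0, 0.0, 2.5)
    a, b = (0.0 - 1.0) / 2.0, (2.5 - 1.0) / 2.0
    dist = stats.truncnorm(a, b, loc=1.0, scale=2.0)
    n = 100_000
    x = spec.sample(n, rng)
    se_mean = dist.std() / math.sqrt(n)
    assert x.mean() == pytest.approx(dist.mean(), abs=3 * se_mean)
    mu4 = dist.moment(4) - 4 * dist.mean() * dist.moment(3) \
        + 6 * dist.mean() ** 2 * dist.moment(2) - 3 * dist.mean() ** 4
    se_var = math.sqrt((mu4 - dist.var() ** 2) / n)
    assert x.var() == pytest.approx(dist.var(), abs=3 * se_var)


_family = st.sampled_from(["normal", "lognormal", "weibull"])


@st.composite
def _valid_specs(draw):
    family = draw(_family)
    if family == "normal":
        p1 = draw(st.floats(-5, 5))
        p2 = draw(st.floats(0.01, 4))
        center, spread = p1, math.sqrt(p2)
    elif family == "lognormal":
        p1 = draw(st.floats(-2, 2))
        p2 = draw(st.floats(0.01, 1))
        center, spread = math.exp(p1), math.exp(p1)
    else:
        p1 = draw(st.floats(0.5, 10))
        p2 = draw(st.floats(0.1, 5))
        center, spread = p2, p2
    lo = center - draw(st.floats(0.5, 3)) * spread
    hi = center + draw(st.floats(0.5, 3)) * spread
    if family in ("lognormal", "weibull"):
        lo = max(lo, 1e-9)
    return MarginalSpec("x", family, p1, p2, lo, hi)


class TestPropertyBased:
    @settings(max_examples=50, derandomize=True)
    @given(_valid_specs(), st.floats(0, 1))
    def test_quantile_in_bounds_and_roundtrip(self, spec, u):
        q = float(spec.quantile(u))
        assert spec.lower - 1e-9 <= q <= spec.upper + 1e-9
        assert float(spec.cdf(q)) == pytest.approx(u, abs=1e-7)

    @settings(max_examples=25, derandomize=True)
    @given(_valid_specs())
    def test_quantile_monotone(self, spec):
        u = np.linspace(0, 1, 101)
        assert np.all(np.diff(spec.quantile(u)) >= -1e-12)


class TestFitBest:
    def test_recovers_lognormal(self, rng):
        x = rng.lognormal(0.5, 0.2, size=2000)
        spec = fit_best(x)
        assert spec.family == "lognormal"
        assert spec.p1 == pytest.approx(0.5, abs=0.02)

    def test_recovers_normal(self, rng):
        x = rng.normal(10.0, 1.0, size=2000)
        assert fit_best(x).family == "normal"

    def test_recovers_weibull(self, rng):
        x = stats.weibull_min(c=8.86, scale=0.94).rvs(2000, random_state=rng)
        assert fit_best(x).family == "weibull"

    def test_constant_data_rejected(self):
        with pytest.raises(FitError):
            fit_best(np.full(100, 3.0))

    def test_negative_data_excludes_positive_families(self, rng):
        x = rng.normal(0.0, 1.0, size=500)  # straddles zero
        assert fit_best(x).family == "normal"

    def test_family_recovery_rate_well_separated(self):
        # lognormal with log-sd 0.5 vs normal: >= 95% of 100 replicates
        hits = 0
        for rep in range(100):
            r = np.random.default_rng(10_000 + rep)
            x = r.lognormal(0.0, 0.5, size=2000)
            hits += fit_best(x).family == "lognormal"
        assert hits >= 95


class TestValidation:
    def test_invalid_specs_raise(self):
        with pytest.raises(SpecError):
            MarginalSpec("x", "normal", 0.0, -1.0, 0, 1)
        with pytest.raises(SpecError):
            MarginalSpec("x", "weibull", -1.0, 1.0, 0, 1)
        with pytest.raises(SpecError):
            MarginalSpec("x", "normal", 0.0, 1.0, 2.0, 1.0)  # lower >= upper
        with pytest.raises(SpecError):
            MarginalSpec("x", "fixed", value=5.0, lower=0.0, upper=1.0)

    def test_degenerate_support_raises(self):
        with pytest.raises(DegenerateSupportError):
            MarginalSpec("x", "normal", 0.0, 1.0, 50.0, 60.0)

    def test_domain_errors(self):
        spec = MarginalSpec("x", "normal", 0.0, 1.0, -1.0, 1.0)
        with pytest.raises(DomainError):
            spec.quantile(1.5)
        with pytest.raises(DomainError):
            spec.cdf(2.0)
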