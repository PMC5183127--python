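import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from sadcompare import distributions as d

# frozen with mpmath (40 significant digits)
LS_PMF1_P05 = 0.72134752044448170368          # -0.5 / log(0.5)
ZT_POISSON1_PMF1 = 0.58197670686932642439     # e^-1 / (1 - e^-1)
# untruncated Poisson-lognormal, mu=1, sigma=1.5 (mpmath adaptive quadrature)
PLN_UNTRUNC = {0: 0.211514512459698423,
               1: 0.159315166593610455,
               5: 0.0481145362239901306,
               100: 0.000150850607777991735}
PLN_UNTRUNC_HEAVY = 0.027039480740095544      # n=3, mu=-2, sigma=2.5


PARAM_GRID = {
    "logseries": [{"p": p} for p in np.linspace(0.05, 0.999, 20)],
    "zipf": [{"s": s} for s in np.linspace(1.05, 10.0, 20)],
    "neg_binom": [{"k": k, "q": q}
                  for k in np.logspace(-2, 2, 5)
                  for q in (0.1, 0.35, 0.6, 0.9)],
    "poisson_lognormal": [{"mu": m, "sigma": s}
                          for m in np.linspace(-2, 3, 5)
                          for s in (0.1, 0.7, 1.5, 2.5)],
}


class TestClosedForms:
    def test_zipf_s2_pmf1_is_6_over_pi_squared(self):
        assert d.Zipf(2.0).pmf(1) == pytest.approx(6 / np.pi**2, rel=1e-12)

    def test_zipf_s2_cdf2(self):
        assert d.Zipf(2.0).cdf(2) == pytest.approx(1.25 * 6 / np.pi**2, rel=1e-12)

    def test_ztnb_k1_is_geometric(self):
        # k=1 truncated NB reduces to geometric q(1-q)^(n-1) on n >= 1
        for q in (0.2, 0.5, 0.8):
            nb = d.NegativeBinomial(k=1.0, q=q)
            for n in range(1, 21):
                assert nb.pmf(n) == pytest.approx(q * (1 - q) ** (n - 1),
                                                  rel=1e-12)

    def test_ztnb_k1_q05_examples(self):
        nb = d.NegativeBinomial(k=1.0, q=0.5)
        assert nb.pmf(2) == pytest.approx(0.25, rel=1e-12)
        assert nb.cdf(3) == pytest.approx(0.875, rel=1e-12)

    def test_logseries_pmf1(self):
        assert d.LogSeries(0.5).pmf(1) == pytest.approx(LS_PMF1_P05, rel=1e-12)
        assert d.LogSeries(0.5).logpmf(1) == pytest.approx(
            np.log(LS_PMF1_P05), abs=1e-12)

    def test_pln_sigma_to_zero_is_zt_poisson(self):
        # sigma=1e-4: matches zero-truncated Poisson(e^mu) to 1e-4
        for mu in (0.0, 1.0):
            pln = d.PoissonLognormal(mu, 1e-4)
            lam = np.exp(mu)
            p0 = np.exp(-lam)
            for n in range(1, 21):
                expected = stats.poisson.pmf(n, lam) / (1 - p0)
                assert pln.pmf(n) == pytest.approx(expected, abs=1e-4)

    def test_pln_sigma_to_zero_pmf1_value(self):
        assert d.PoissonLognormal(0.0, 1e-4).pmf(1) == pytest.approx(
            ZT_POISSON1_PMF1, abs=1e-4)


class TestPlnQuadrature:
    def test_untruncated_matches_mpmath(self):
        lp = d.pln_logpmf_untruncated(np.array(sorted(PLN_UNTRUNC)), 1.0, 1.5)
        for logp, (n, expected) in zip(lp, sorted(PLN_UNTRUNC.items())):
            assert np.exp(logp) == pytest.approx(expected, rel=1e-9)

    def test_untruncated_heavy_tail_matches_mpmath(self):
        lp = d.pln_logpmf_untruncated(np.array([3.0]), -2.0, 2.5)
        assert np.exp(lp[0]) == pytest.approx(PLN_UNTRUNC_HEAVY, rel=1e-9)

    def test_truncation_constant_consistent(self):
        # log(1 - P(0)) computed two ways agrees when P(0) is moderate
        logp0 = d.pln_logpmf_untruncated(np.array([0.0]), 2.0, 1.0)[0]
        assert d.pln_log_trunc_norm(2.0, 1.0) == pytest.approx(
            np.log1p(-np.exp(logp0)), abs=1e-10)

    def test_trunc_norm_extreme_regime(self):
        # P(0) -> 1: log(1 - P(0)) ~ log(E[lam]) = mu + sigma^2/2
        assert d.pln_log_trunc_norm(-50.0, 1e-3) == pytest.approx(-50.0, abs=1e-4)

    @pytest.mark.parametrize("mu,sigma", [(1.0, 1.5), (0.0, 0.5), (-1.0, 2.0)])
    def test_untruncated_matches_trapezoid(self, mu, sigma):
        # independent brute-force reference at well-resolved settings
        from oracles import pln_pmf_trapezoid
        n = np.arange(1, 51)
        ours = np.exp(d.pln_logpmf_untruncated(n.astype(float), mu, sigma))
        ref = pln_pmf_trapezoid(n, mu, sigma)
        np.testing.assert_allclose(ours, ref, rtol=1e-6)

    def test_logpmf_large_n_finite(self):
        val = d.PoissonLognormal(2.0, 1.0).logpmf(10_000)
        assert np.isfinite(val)


@pytest.mark.parametrize("family,params",
                         [(fam, p) for fam, ps in PARAM_GRID.items()
                          for p in ps[:4]])
def test_logpmf_pmf_consistency(family, params):
    dist = d.make_distribution(family, **params)
    n = np.arange(1, 200)
    pmf = dist.pmf(n)
    logpmf = dist.logpmf(n)
    mask = pmf > 1e-200
    np.testing.assert_allclose(np.exp(logpmf[mask]), pmf[mask], rtol=1e-12)


@pytest.mark.parametrize("family", d.FAMILY_ORDER)
def test_cdf_monotone_and_tail(family):
    params = PARAM_GRID[family][3]
    dist = d.make_distribution(family, **params)
    n = np.arange(1, 500)
    cdf = dist.cdf(n)
    assert np.all(np.diff(cdf) >= 0)
    assert np.all((cdf >= 0) & (cdf <= 1 + 1e-12))
    # limit 1 as n -> infinity: cdf(N) + tail_mass(N) ~ 1
    assert cdf[-1] + dist.tail_mass(499) == pytest.approx(1.0, abs=1e-6)


class TestValidation:
    @pytest.mark.parametrize("family,params", [
        ("logseries", {"p": 0.0}), ("logseries", {"p": 1.0}),
        ("logseries", {"p": -0.5}),
        ("zipf", {"s": 1.0}), ("zipf", {"s": 0.5}),
        ("neg_binom", {"k": 0.0, "q": 0.5}),
        ("neg_binom", {"k": 1.0, "q": 1.0}),
        ("neg_binom", {"k": -1.0, "q": 0.5}),
        ("poisson_lognormal", {"mu": 0.0, "sigma": 0.0}),
        ("poisson_lognormal", {"mu": 0.0, "sigma": -1.0}),
    ])
    def test_invalid_params_raise(self, family, params):
        with pytest.raises(d.ParameterError):
            d.make_distribution(family, **params)

    def test_unknown_family_raises(self):
        with pytest.raises(d.ParameterError, match="unknown family"):
            d.make_distribution("lognormal", mu=0, sigma=1)

    @pytest.mark.parametrize("bad_n", [0, -3, 1.5, np.nan])
    def test_invalid_abundance_raises(self, bad_n):
        dist = d.LogSeries(0.5)
        with pytest.raises(ValueError):
            dist.pmf(bad_n)

    def test_dispatch_by_name(self):
        assert d.pmf("zipf", {"s": 2.0}, 1) == pytest.approx(6 / np.pi**2)
        assert d.logpmf("logseries", {"p": 0.5}, 1) == pytest.approx(
            np.log(LS_PMF1_P05))
        assert d.cdf("neg_binom", {"k": 1.0, "q": 0.5}, 3) == pytest.approx(0.875)


class TestSampling:
    @pytest.mark.parametrize("family", d.FAMILY_ORDER)
    def test_deterministic_given_seed(self, family):
        params = PARAM_GRID[family][2]
        a = d.sample(family, params, 500, seed=7)
        b = d.sample(family, params, 500, seed=7)
        np.testing.assert_array_equal(a, b)

    @pytest.mark.parametrize("family", d.FAMILY_ORDER)
    def test_support_is_positive(self, family):
        params = PARAM_GRID[family][2]
        x = d.sample(family, params, 2000, seed=11)
        assert x.min() >= 1
        assert x.dtype == np.int64

    def test_logseries_singleton_frequency(self):
        # empirical P(1) within 3 Monte-Carlo standard errors of pmf(1)
        dist = d.LogSeries(0.9)
        n = 100_000
        x = dist.sample(n, seed=5)
        p1 = dist.pmf(1)
        se = np.sqrt(p1 * (1 - p1) / n)
        assert abs(np.mean(x == 1) - p1) < 3 * se

    @pytest.mark.parametrize("family", d.FAMILY_ORDER)
    def test_chisquare_goodness_of_fit(self, family):
        params = PARAM_GRID[family][2]
        dist = d.make_distribution(family, **params)
        n_draws = 100_000
        x = dist.sample(n_draws, seed=21)
        # bins 1..9 plus a lumped tail
        edges = np.arange(1, 10)
        observed = np.array([(x == e).sum() for e in edges]
                            + [(x >= 10).sum()], dtype=float)
        expected = np.append(dist.pmf(edges), dist.tail_mass(9)) * n_draws
        keep = expected >= 5
        obs, exp = observed[keep], expected[keep]
        exp *= obs.sum() / exp.sum()
        stat, pval = stats.chisquare(obs, exp)
        assert pval > 0.001


@settings(max_examples=30, deadline=None)
@given(p=st.floats(0.01, 0.995), n=st.integers(1, 300))
def test_logseries_pmf_formula_property(p, n):
    # matches the defining formula -p^n / (n log(1-p)) evaluated in log space
    expected = n * np.log(p) - np.log(n) - np.log(-np.log1p(-p))
    assert d.LogSeries(p).logpmf(n) == pytest.approx(expected, abs=1e-10)


@settings(max_examples=20, deadline=None)
@given(s=st.floats(1.05, 20.0), n=st.integers(1, 1000))
def test_zipf_pmf_formula_property(s, n):
    from scipy.special import zeta
    assert d.Zipf(s).pmf(n) == pytest.approx(n ** -s / zeta(s), rel=1e-10)
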