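import math

import numpy as np
import pytest
from scipy import stats as spstats
from scipy.special import logsumexp

from mbttest import PriorSettings, SummaryStats, TwoSampleData, fit_model, bayes_factor
from mbttest.marglik_normal import conditional_logml, logml_normal, nct_logpdf
from mbttest.models import ModelSpec


class TestNoncentralT:
    """The in-house noncentral-t log density behind the conditional
    marginal likelihood."""

    def test_agrees_with_scipy_where_scipy_is_finite(self):
        rng = np.random.default_rng(0)
        for _ in range(150):
            x = rng.uniform(-6, 6)
            df = int(rng.integers(3, 120))
            nc = rng.uniform(-10, 10)
            ref = spstats.nct.logpdf(x, df, nc)
            if np.isfinite(ref):
                assert nct_logpdf(x, df, nc) == pytest.approx(ref, abs=1e-8)

    @pytest.mark.parametrize(
        "x,df,nc", [(1.4544, 198, -8.385), (2.0, 400, 15.0), (0.3, 198, -12.0)]
    )
    def test_large_df_region_against_direct_integration(self, x, df, nc):
        """Large-df / large-|ncp| values where scipy's nct underflows to NaN,
        checked against a high-resolution integral of the definition."""
        u = np.linspace(1e-12, 6.0, 400001)
        lg = (
            math.log(2) + (df / 2) * math.log(df / 2)
            + (df - 1) * np.log(u) - df * u * u / 2 - math.lgamma(df / 2)
            + spstats.norm.logpdf(x * u - nc) + np.log(u)
        )
        m = lg.max()
        direct = m + math.log(np.trapezoid(np.exp(lg - m), u))
        assert nct_logpdf(x, df, nc) == pytest.approx(direct, abs=1e-9)

    def test_central_case_matches_t(self):
        assert nct_logpdf(1.3, 198, 0.0) == pytest.approx(
            spstats.t.logpdf(1.3, 198), abs=1e-12
        )

EQ_ALT = ModelSpec("alternative", "equal", "normal")
EQ_NULL = ModelSpec("null", "equal", "normal")
UN_ALT = ModelSpec("alternative", "unequal", "normal")
UN_NULL = ModelSpec("null", "unequal", "normal")


@pytest.fixture(scope="module")
def bench_stats():
    return SummaryStats(10, 0.5, 1.0, 10, 0.0, 1.0)


def _dense_grid_bf10(s, priors, n_nodes=10**6, half_width=50.0):
    """Independent 1-D oracle: dense-trapezoid integration over delta."""
    d = np.linspace(-half_width, half_width, n_nodes + 1)
    lf = conditional_logml(s, d, 0.5) + priors.delta_logpdf(d)
    log_ml1 = logsumexp(lf) + math.log(d[1] - d[0])
    return math.exp(log_ml1 - conditional_logml(s, 0.0, 0.5))


class TestEqualVarianceBayesFactor:
    def test_matches_dense_grid_oracle_to_6_digits(self, bench_stats, priors):
        bf_prod = math.exp(
            logml_normal(bench_stats, EQ_ALT, priors)
            - logml_normal(bench_stats, EQ_NULL, priors)
        )
        bf_oracle = _dense_grid_bf10(bench_stats, priors)
        assert bf_prod == pytest.approx(bf_oracle, rel=1e-6)

    def test_default_prior_is_cauchy_root_half(self, bench_stats):
        # the equal-variance alternative integrates the noncentral-t
        # conditional against Cauchy(0, 1/sqrt 2); a different scale
        # must move the Bayes factor
        wide = PriorSettings(delta_scale=1.0)
        bf_default = math.exp(
            logml_normal(bench_stats, EQ_ALT, PriorSettings())
            - logml_normal(bench_stats, EQ_NULL, PriorSettings())
        )
        bf_wide = math.exp(
            logml_normal(bench_stats, EQ_ALT, wide)
            - logml_normal(bench_stats, EQ_NULL, wide)
        )
        assert bf_default != pytest.approx(bf_wide, rel=1e-3)


class TestInvariances:
    @pytest.mark.parametrize("spec", [EQ_ALT, EQ_NULL, UN_ALT, UN_NULL])
    @pytest.mark.parametrize("scale,shift", [(3.7, 0.0), (1.0, 12.0), (0.2, -4.5)])
    def test_bf_invariant_to_affine_transforms(self, priors, spec, scale, shift):
        base = SummaryStats(8, 0.9, 1.2, 12, 0.1, 2.0)
        moved = SummaryStats(
            8, scale * 0.9 + shift, scale * 1.2, 12, scale * 0.1 + shift, scale * 2.0
        )
        null = EQ_NULL if spec.variances == "equal" else UN_NULL
        bf0 = logml_normal(base, spec, priors) - logml_normal(base, null, priors)
        bf1 = logml_normal(moved, spec, priors) - logml_normal(moved, null, priors)
        assert bf1 == pytest.approx(bf0, abs=1e-8)

    def test_rho_point_mass_reduction(self, toy_stats, priors):
        """Unequal-variance model with rho pinned at 1/2 = equal-variance model."""
        for spec, eq in [(UN_ALT, EQ_ALT), (UN_NULL, EQ_NULL)]:
            reduced = logml_normal(toy_stats, spec, priors, fix_rho=0.5)
            assert reduced == pytest.approx(
                logml_normal(toy_stats, eq, priors), abs=1e-6
            )

    def test_unequal_conditional_nests_equal_at_half(self, toy_stats):
        delta = np.linspace(-2, 2, 9)
        a = conditional_logml(toy_stats, delta, 0.5)
        b = conditional_logml(toy_stats, delta, np.full_like(delta, 0.5))
        np.testing.assert_allclose(a, b, rtol=1e-12)


class TestConditionalLogml:
    def test_closed_form_null_against_direct_integration(self, toy_stats):
        """Independent check of the (mu, sigma) closed form at delta=0."""
        s = toy_stats

        def integrand(sigma, mu, rho=0.5):
            v = 2 * rho
            lp = 0.0
            for n, mean, sd, vg in (
                (s.n1, s.mean1, s.sd1, 2 * (1 - rho)),
                (s.n2, s.mean2, s.sd2, v),
            ):
                sg = sigma * math.sqrt(vg)
                ss = (n - 1) * sd**2 + n * (mean - mu) ** 2
                lp += -n / 2 * math.log(2 * math.pi * sg**2) - ss / (2 * sg**2)
            return math.exp(lp) / sigma  # Jeffreys 1/sigma

        from scipy.integrate import dblquad

        val, err = dblquad(
            integrand, -40, 40, lambda mu: 1e-3, lambda mu: 60, epsabs=1e-12
        )
        assert math.log(val) == pytest.approx(
            conditional_logml(s, 0.0, 0.5), abs=1e-6
        )

    def test_noncentrality_direction(self, priors):
        """Data with group 2 larger favor positive delta."""
        s = SummaryStats(20, 0.0, 1.0, 20, 1.0, 1.0)
        up = conditional_logml(s, 0.8, 0.5)
        down = conditional_logml(s, -0.8, 0.5)
        assert up > down


class TestBayesFactorInterface:
    def test_identity_and_inversion(self, toy_data, priors):
        f1 = fit_model(toy_data, EQ_ALT, priors, include_draws=False)
        f0 = fit_model(toy_data, EQ_NULL, priors, include_draws=False)
        assert bayes_factor(f1, f1).value == pytest.approx(1.0)
        assert bayes_factor(f1, f0).value == pytest.approx(
            1.0 / bayes_factor(f0, f1).value
        )

    def test_mismatched_data_rejected(self, toy_data, priors):
        other = TwoSampleData([0.0, 1.0, 2.0], [3.0, 4.0, 5.5])
        f1 = fit_model(toy_data, EQ_ALT, priors, include_draws=False)
        f0 = fit_model(other, EQ_NULL, priors, include_draws=False)
        with pytest.raises(ValueError, match="different datasets"):
            bayes_factor(f1, f0)


class TestConsistency:
    def test_log_bf_grows_with_n_under_the_generating_model(self, priors):
        """Evidence for the correct effect indicator accumulates with n:
        BF10 grows under a true effect, BF01 under a true null.  Growth
        is stochastic per dataset, so a clear majority of seed x
        direction checks must succeed."""

        def log_bf10(a, b, n):
            s = SummaryStats(n, a[:n].mean(), a[:n].std(ddof=1),
                             n, b[:n].mean(), b[:n].std(ddof=1))
            return (logml_normal(s, EQ_ALT, PriorSettings())
                    - logml_normal(s, EQ_NULL, PriorSettings()))

        wins = 0
        for seed in (0, 1, 2):
            rng = np.random.default_rng(seed)
            g1 = rng.normal(-0.25, 1.0, 500)
            g2 = rng.normal(0.25, 1.0, 500)
            null1 = rng.normal(0.0, 1.0, 500)
            null2 = rng.normal(0.0, 1.0, 500)
            wins += log_bf10(g1, g2, 500) > log_bf10(g1, g2, 20)
            wins += log_bf10(null1, null2, 500) < log_bf10(null1, null2, 20)
        assert wins >= 5


class TestPosteriorDraws:
    def test_draw_moments_match_grid_posterior(self, priors):
        """Sampled delta draws reproduce the quadrature posterior mean."""
        s = SummaryStats(25, 0.0, 1.0, 25, 0.8, 1.0)
        fit = fit_model(s, EQ_ALT, priors, n_normal_draws=20000)
        d = np.linspace(-4, 6, 20001)
        lw = conditional_logml(s, d, 0.5) + priors.delta_logpdf(d)
        w = np.exp(lw - lw.max())
        mean_grid = float(np.sum(d * w) / np.sum(w))
        assert fit.draws["delta"].mean() == pytest.approx(mean_grid, abs=0.02)
        assert np.all(fit.draws["rho"] == 0.5)
        assert np.all(np.isinf(fit.draws["nu"]))
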