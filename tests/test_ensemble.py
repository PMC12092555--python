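import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mbttest import (
    fit_ensemble,
    inclusion_bf,
    model_averaged_posterior,
    posterior_model_probs,
)
from mbttest.ensemble import inclusion_bf_log_se
from mbttest.marglik import ModelFit
from mbttest.models import ModelSpec


class TestPosteriorModelProbs:
    def test_printed_worked_examples(self):
        # two models at unit prior odds: BF = 37.2 -> P(H1) = 37.2/38.2
        p = posterior_model_probs([math.log(37.2), 0.0], [0.5, 0.5])
        assert p[0] == pytest.approx(37.2 / 38.2)
        p = posterior_model_probs([math.log(67.4), 0.0], [0.5, 0.5])
        assert p[0] == pytest.approx(67.4 / 68.4)

    @given(k=st.integers(2, 12), base=st.floats(-500, 500))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_identical_models_share_probability(self, k, base):
        p = posterior_model_probs(np.full(k, base), np.full(k, 1 / k))
        np.testing.assert_allclose(p, 1 / k, rtol=1e-12)

    @given(
        lmls=st.lists(st.floats(-900, 900), min_size=2, max_size=6),
        shift=st.floats(-100, 100),
    )
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_shift_invariance_and_normalization(self, lmls, shift):
        k = len(lmls)
        prior = np.full(k, 1 / k)
        p0 = posterior_model_probs(lmls, prior)
        p1 = posterior_model_probs(np.asarray(lmls) + shift, prior)
        assert p0.sum() == pytest.approx(1.0, abs=1e-12)
        np.testing.assert_allclose(p0, p1, atol=1e-12)

    def test_length_mismatch(self):
        with pytest.raises(ValueError, match="mismatch"):
            posterior_model_probs([0.0, 1.0], [1.0])


class TestInclusionBf:
    def test_two_models_reduces_to_pairwise_bf(self):
        bf = 5.7
        probs = posterior_model_probs([math.log(bf), 0.0], [0.5, 0.5])
        assert inclusion_bf(probs, [0.5, 0.5], [0]) == pytest.approx(bf)

    def test_four_model_arithmetic(self):
        post = [0.4, 0.4, 0.1, 0.1]
        prior = [0.25] * 4
        assert inclusion_bf(post, prior, [0, 1]) == pytest.approx(4.0)

    def test_empty_or_full_indicator_rejected(self):
        with pytest.raises(ValueError):
            inclusion_bf([0.5, 0.5], [0.5, 0.5], [])
        with pytest.raises(ValueError):
            inclusion_bf([0.5, 0.5], [0.5, 0.5], [0, 1])

    def test_prior_odds_identity(self):
        """Doubling a set's prior odds doubles its posterior odds but
        leaves the inclusion BF unchanged."""
        lmls = [1.2, -0.3, 0.8, 0.1]
        prior_a = np.array([0.25, 0.25, 0.25, 0.25])
        prior_b = np.array([0.4, 0.4, 0.1, 0.1])  # prior odds of {0,1}: 1 -> 4
        post_a = posterior_model_probs(lmls, prior_a)
        post_b = posterior_model_probs(lmls, prior_b)
        bf_a = inclusion_bf(post_a, prior_a, [0, 1])
        bf_b = inclusion_bf(post_b, prior_b, [0, 1])
        assert bf_b == pytest.approx(bf_a, rel=1e-12)

    def test_log_se_propagation(self):
        se = inclusion_bf_log_se([0.0, 0.0], [0.1, 0.2], [0.5, 0.5], [0])
        assert se == pytest.approx(math.hypot(0.1, 0.2))


def _const_fit(spec_args, log_ml, draws=None):
    spec = ModelSpec(*spec_args)
    return ModelFit(spec=spec, log_ml=log_ml, log_ml_se=0.0, draws=draws,
                    data_hash="x")


class TestModelAveragedPosterior:
    def test_single_model_degenerate_mixture(self):
        rng = np.random.default_rng(0)
        draws = {"delta": rng.normal(1.0, 0.3, 5000)}
        fit = _const_fit(("alternative", "equal", "normal"), 0.0, draws)
        mixed, summary = model_averaged_posterior([fit], [1.0], "delta", 20000, seed=1)
        assert summary.center == pytest.approx(draws["delta"].mean(), abs=0.02)

    def test_point_mass_mixture(self):
        rng = np.random.default_rng(0)
        alt = _const_fit(("alternative", "equal", "normal"), 0.0,
                         {"delta": rng.normal(1.0, 0.2, 5000)})
        null = _const_fit(("null", "equal", "normal"), 0.0, None)
        mixed, _ = model_averaged_posterior(
            [alt, null], [0.5, 0.5], "delta", 40000, seed=2
        )
        assert np.mean(mixed == 0.0) == pytest.approx(0.5, abs=0.02)

    def test_nu_median_infinite_when_normal_models_dominate(self):
        rng = np.random.default_rng(3)
        tfit = _const_fit(("alternative", "equal", "t"), 0.0,
                          {"nu": 2 + rng.exponential(1.0, 5000)})
        nfit = _const_fit(("alternative", "equal", "normal"), 0.0, None)
        _, summary = model_averaged_posterior(
            [tfit, nfit], [0.4, 0.6], "nu", 20000, seed=3
        )
        assert math.isinf(summary.center)
        assert math.isfinite(summary.ci_low)  # style: median inf, finite lower bound
        assert summary.statistic == "median"

    def test_conditional_requires_mass_on_free_models(self):
        null = _const_fit(("null", "equal", "normal"), 0.0, None)
        alt = _const_fit(("alternative", "equal", "normal"), 0.0,
                         {"delta": np.array([1.0])})
        with pytest.raises(ValueError, match="conditional"):
            model_averaged_posterior([null, alt], [1.0, 0.0], "delta",
                                     2000, conditional=True)

    def test_small_draw_count_warns(self):
        alt = _const_fit(("alternative", "equal", "normal"), 0.0,
                         {"delta": np.array([1.0, 2.0])})
        with pytest.warns(UserWarning, match="small"):
            model_averaged_posterior([alt], [1.0], "delta", 500, seed=0)


class TestFitEnsemble:
    def test_mb4_on_replication_fixture(self, replication_stats, priors):
        """Means 12.35/3.65, SDs 12.18/3.94 (d ~ 1.0, SD ratio ~ 3.1):
        strong evidence for both an effect and unequal variances."""
        res = fit_ensemble(replication_stats, priors, ensemble="mb4", seed=1)
        assert res.incl_bf_effect > 10
        assert res.incl_bf_variances > 10
        assert res.model_probs.sum() == pytest.approx(1.0, abs=1e-12)
        assert res.incl_bf_outliers is None

    def test_student_ensemble_is_pairwise_bf(self, replication_stats, priors):
        from mbttest.marglik import bayes_factor, fit_model

        res = fit_ensemble(replication_stats, priors, ensemble="student", seed=1)
        f1 = fit_model(replication_stats,
                       ModelSpec("alternative", "equal", "normal"), priors,
                       include_draws=False)
        f0 = fit_model(replication_stats, ModelSpec("null", "equal", "normal"),
                       priors, include_draws=False)
        assert res.incl_bf_effect == pytest.approx(bayes_factor(f1, f0).value,
                                                   rel=1e-9)

    def test_romb8_requires_raw_data(self, replication_stats):
        with pytest.raises(TypeError, match="raw data"):
            fit_ensemble(replication_stats, ensemble="romb8")

    def test_report_serializes(self, replication_stats, priors):
        res = fit_ensemble(replication_stats, priors, ensemble="welch", seed=1)
        payload = res.to_json()
        assert "inclusion_bf" in payload
        from mbttest.reporting import text_report

        text = text_report(res)
        assert "BF[effect]" in text


class TestEnsembleCoherence:
    def test_romb8_with_mass_only_on_normal_models_reproduces_mb4(
        self, toy_data, priors, sweep_settings
    ):
        """Zeroing the t-likelihood models' prior probability makes the
        robust ensemble's effect/variance inclusion BFs collapse to the
        4-model ensemble's values."""
        import dataclasses
        import warnings as _w

        from mbttest.models import ROMB8

        probs = tuple(0.25 if s.likelihood == "normal" else 0.0 for s in ROMB8)
        pr8 = dataclasses.replace(priors, prior_model_probs=probs)
        with _w.catch_warnings():
            _w.simplefilter("ignore")  # outlier inclusion BF is infinite here
            res8 = fit_ensemble(toy_data, pr8, ensemble="romb8",
                                settings=sweep_settings, seed=3,
                                include_draws=False)
        res4 = fit_ensemble(toy_data, priors, ensemble="mb4", seed=3,
                            include_draws=False)
        assert res8.incl_bf_effect == pytest.approx(res4.incl_bf_effect, rel=1e-6)
        assert res8.incl_bf_variances == pytest.approx(res4.incl_bf_variances,
                                                       rel=1e-6)


class TestJointNullDirection:
    def test_all_inclusion_bfs_below_one_under_joint_null(self, priors,
                                                          sweep_settings):
        """Simulated null data (no effect, equal variances, normal) should
        mostly yield evidence against every ensemble component."""
        import dataclasses

        from mbttest.simulate import SimulationCondition, simulate_condition

        cond = SimulationCondition(delta=0.0, sdr=1.0, nu=math.inf,
                                   total_n=200, allocation=1.0)
        wins = 0
        n_seeds = 10
        for rep in range(n_seeds):
            data = simulate_condition(cond, rep, seed=123)
            res = fit_ensemble(
                data, priors, ensemble="romb8",
                settings=dataclasses.replace(sweep_settings, seed=rep),
                seed=rep, include_draws=False,
            )
            ok = (res.incl_bf_effect < 1 and res.incl_bf_variances < 1
                  and res.incl_bf_outliers < 1)
            wins += ok
        assert wins >= 8
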