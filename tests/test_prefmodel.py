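"""Dirichlet-multinomial preference model, Bayesian ANOVA, ETPIs, letters."""

import numpy as np
import pytest
from scipy.stats import gamma as gamma_dist

from hostvar import prefmodel, synthdata
from hostvar.prefmodel import _sample_dirichlet_rows
from hostvar.types import EtpiSummary, HostvarError, PreferenceCounts


def _counts(Y, substrates=None):
    Y = np.asarray(Y)
    return PreferenceCounts(
        female_id=[f"F{i}" for i in range(Y.shape[0])],
        source_population=["X"] * Y.shape[0],
        counts=Y,
        substrate_labels=substrates or [f"s{j}" for j in range(Y.shape[1])],
    )


class TestFitPreference:
    def test_symmetric_data_gives_uniform_preference(self):
        Y = np.full((20, 3), 10)
        fit = prefmodel.fit_preference(_counts(Y), n_iter=2000, burn_in=500,
                                       seed=1, store_individual=False)
        summaries = [prefmodel.etpi(fit, "Pi", index=h) for h in range(3)]
        for s in summaries:
            assert abs(s.point_estimate - 1 / 3) < 0.03
        for a in summaries:
            for b in summaries:
                assert a.overlaps(b)

    def test_gibbs_conditional_matches_conjugate_posterior(self, rng):
        """With (Pi, kappa) fixed, pi_i | y_i is Dirichlet(kappa*Pi + y_i);
        the sampler's conditional draw must match its moments."""
        Pi = np.array([0.6, 0.3, 0.1])
        kappa = 20.0
        y = np.array([25.0, 10.0, 5.0])
        alpha = kappa * Pi + y
        draws = np.vstack([
            _sample_dirichlet_rows(rng, alpha[None, :])[0] for _ in range(20000)
        ])
        a0 = alpha.sum()
        mean = alpha / a0
        var = alpha * (a0 - alpha) / (a0 ** 2 * (a0 + 1))
        assert np.allclose(draws.mean(axis=0), mean, atol=4 * np.sqrt(var / 20000).max())
        assert np.allclose(draws.var(axis=0), var, rtol=0.1)

    def test_posterior_matches_exact_marginal(self):
        """Sampler posterior of kappa agrees with a grid evaluation of the
        exact Dirichlet-multinomial marginal likelihood."""
        from scipy.special import gammaln
        sc = synthdata.PreferenceScenario(
            n_females=50, population_preference=(0.6, 0.3, 0.1),
            concentration=20.0, eggs_per_female_mean=40, seed=7)
        counts, truth = synthdata.generate_preference_counts(sc)
        fit = prefmodel.fit_preference(counts, n_iter=8000, burn_in=2000, seed=3,
                                       store_individual=False)
        Y = counts.counts.astype(float)
        n = Y.sum(axis=1)
        Pi = truth["Pi"]

        def dm_loglik(k):
            a = k * Pi
            return (np.sum(gammaln(k) - gammaln(k + n))
                    + np.sum(gammaln(a[None, :] + Y) - gammaln(a[None, :])))

        ks = np.linspace(5, 150, 400)
        lp = np.array([dm_loglik(k) for k in ks]) - np.log1p((ks / 25) ** 2)
        w = np.exp(lp - lp.max())
        w /= w.sum()
        exact_mean = float((w * ks).sum())
        sampled = prefmodel.etpi(fit, "kappa").point_estimate
        assert abs(sampled - exact_mean) / exact_mean < 0.25

    def test_recovery_of_population_preference(self):
        sc = synthdata.PreferenceScenario(
            n_females=50, population_preference=(0.6, 0.3, 0.1),
            concentration=20.0, eggs_per_female_mean=40, seed=11)
        counts, truth = synthdata.generate_preference_counts(sc)
        fit = prefmodel.fit_preference(counts, n_iter=2000, burn_in=500, seed=2,
                                       store_individual=False)
        for h in range(3):
            s = prefmodel.etpi(fit, "Pi", index=h)
            assert abs(s.point_estimate - truth["Pi"][h]) < 0.05

    def test_simplex_invariant_of_draws(self):
        Y = np.array([[5, 3, 2], [1, 8, 1]])
        fit = prefmodel.fit_preference(_counts(Y), n_iter=500, burn_in=100,
                                       seed=4)
        assert np.allclose(fit.get("Pi").sum(axis=1), 1.0, atol=1e-12)
        assert np.allclose(fit.get("pi").sum(axis=2), 1.0, atol=1e-12)
        assert (fit.get("kappa") > 0).all()

    def test_zero_egg_female_dropped(self):
        Y = np.array([[5, 5, 0], [0, 0, 0]])
        with pytest.warns(UserWarning, match="zero eggs"):
            fit = prefmodel.fit_preference(_counts(Y), n_iter=300, burn_in=100,
                                           seed=1)
        assert fit.get("pi").shape[1] == 1

    def test_deterministic_rerun(self):
        Y = np.array([[5, 3, 2], [1, 8, 1]])
        a = prefmodel.fit_preference(_counts(Y), n_iter=400, burn_in=100, seed=9)
        b = prefmodel.fit_preference(_counts(Y), n_iter=400, burn_in=100, seed=9)
        assert np.array_equal(a.get("Pi"), b.get("Pi"))


class TestFitSurvival:
    def test_beta_binomial_flat_prior_mean(self):
        fit = prefmodel.fit_survival(
            [30, 48], ["a", "b"], n_started=[60, 60],
            n_iter=60000, burn_in=0, seed=1)
        s = prefmodel.etpi(fit, "survival_rate", index=0)
        assert s.point_estimate == pytest.approx(31 / 62, abs=0.004)

    def test_zero_survivors_posterior_mean(self):
        fit = prefmodel.fit_survival(
            [0, 30], ["a", "b"], n_started=[60, 60],
            n_iter=60000, burn_in=0, seed=2)
        s = prefmodel.etpi(fit, "survival_rate", index=0)
        assert s.point_estimate == pytest.approx(1 / 62, abs=0.002)

    def test_equal_counts_give_equal_support(self):
        fit = prefmodel.fit_survival([40, 40, 40], ["a", "b", "c"],
                                     n_iter=5000, burn_in=1000, seed=3)
        means = fit.get("support").mean(axis=0)
        assert np.allclose(means, 1 / 3, atol=0.04)

    def test_all_zero_counts_error(self):
        with pytest.raises(HostvarError, match="zero total"):
            prefmodel.fit_survival([0, 0], ["a", "b"])


class TestBanova:
    def test_identical_groups_deflections_cover_zero(self, rng):
        y = np.tile(rng.normal(10, 1, 40), 2)
        g = np.repeat(["a", "b"], 40)
        fit = prefmodel.fit_banova(y, g, n_iter=6000, chains=2, burn_in=500,
                                   thin=2, seed=5)
        for i in range(2):
            s = prefmodel.etpi(fit, "delta", index=i)
            assert s.lower <= 0.0 <= s.upper

    def test_near_degenerate_likelihood_recovers_means(self, rng):
        y = np.concatenate([rng.normal(10, 0.1, 50), rng.normal(20, 0.1, 50)])
        g = np.repeat(["lo", "hi"], 50)
        fit = prefmodel.fit_banova(y, g, n_iter=12000, chains=3, burn_in=500,
                                   thin=2, seed=6)
        for i, target in enumerate([20.0, 10.0]):  # labels sort hi < lo
            s = prefmodel.etpi(fit, "group_mean", index=i)
            assert abs(s.point_estimate - target) < 0.1

    def test_chain_length_robustness(self, rng):
        y = np.concatenate([rng.normal(5, 1, 30), rng.normal(7, 1, 30)])
        g = np.repeat(["a", "b"], 30)
        short = prefmodel.fit_banova(y, g, n_iter=3000, chains=2, burn_in=300,
                                     thin=1, seed=7)
        long = prefmodel.fit_banova(y, g, n_iter=15000, chains=2, burn_in=300,
                                    thin=1, seed=8)
        for i in range(2):
            a = prefmodel.etpi(short, "group_mean", index=i)
            b = prefmodel.etpi(long, "group_mean", index=i)
            mcse = short.get("group_mean")[:, i].std(ddof=1) / np.sqrt(200)
            assert abs(a.point_estimate - b.point_estimate) < max(6 * mcse, 0.08)

    def test_single_group_matches_normal_gamma_closed_form(self, rng):
        """One group reduces to a conjugate-style mean estimate: with a flat
        mean prior and Gamma(1,1) precision prior, the marginal posterior of
        the mean is a scaled t around ybar."""
        y = rng.normal(3.0, 1.0, 80)
        with pytest.warns(UserWarning, match="single group"):
            fit = prefmodel.fit_banova(y, ["g"] * len(y), n_iter=30000, chains=2,
                                       burn_in=1000, thin=2, seed=9)
        s = prefmodel.etpi(fit, "group_mean", index=0)
        n = len(y)
        ybar = y.mean()
        # normal-gamma posterior with prior a=1, b=1, flat mean:
        a_post = 1.0 + (n - 1) / 2.0
        b_post = 1.0 + 0.5 * np.sum((y - ybar) ** 2)
        scale = np.sqrt(b_post / (a_post * n))
        from scipy.stats import t as t_dist
        lo, hi = t_dist.ppf([0.025, 0.975], df=2 * a_post, loc=ybar, scale=scale)
        assert s.point_estimate == pytest.approx(ybar, abs=0.05)
        assert s.lower == pytest.approx(lo, abs=0.07)
        assert s.upper == pytest.approx(hi, abs=0.07)

    def test_singleton_group_excluded(self, rng):
        y = np.array([1.0, 2.0, 3.0, 4.0, 10.0])
        g = np.array(["a", "a", "b", "b", "solo"])
        with pytest.warns(UserWarning, match="single observation"):
            fit = prefmodel.fit_banova(y, g, n_iter=600, chains=1, burn_in=100,
                                       thin=1, seed=1)
        assert fit.meta["groups"] == ["a", "b"]

    def test_nonpositive_mass_error(self):
        with pytest.raises(HostvarError, match="positive"):
            prefmodel.fit_banova([1.0, -2.0], ["a", "a"])


class TestEtpi:
    def test_constant_draws(self):
        from hostvar.types import McmcSamples
        s = McmcSamples({"x": np.full((1, 500), 7.0)}, burn_in=0)
        out = prefmodel.etpi(s, "x")
        assert (out.point_estimate, out.lower, out.upper) == (7.0, 7.0, 7.0)

    def test_linear_interpolation_convention(self):
        from hostvar.types import McmcSamples
        s = McmcSamples({"x": np.arange(1.0, 1001.0)[None, :]}, burn_in=0)
        out = prefmodel.etpi(s, "x")
        assert out.lower == pytest.approx(25.975)
        assert out.upper == pytest.approx(975.025)

    def test_normal_draws_recover_quantiles(self, rng):
        from hostvar.types import McmcSamples
        s = McmcSamples({"x": rng.standard_normal((1, 100000))}, burn_in=0)
        out = prefmodel.etpi(s, "x")
        assert out.lower == pytest.approx(-1.96, abs=0.02)
        assert out.upper == pytest.approx(1.96, abs=0.02)

    def test_missing_parameter_and_short_chain(self):
        from hostvar.types import McmcSamples
        s = McmcSamples({"x": np.ones((1, 50))}, burn_in=0)
        with pytest.raises(HostvarError, match="not found"):
            prefmodel.etpi(s, "y")
        with pytest.raises(HostvarError, match="need >= 100"):
            prefmodel.etpi(s, "x")


class TestLetterGroups:
    def test_disjoint_intervals(self):
        a = EtpiSummary("a", 0.5, 0.0, 1.0)
        b = EtpiSummary("b", 2.5, 2.0, 3.0)
        labels = prefmodel.letter_groups([a, b])
        assert labels["a"] != labels["b"]
        assert set(labels.values()) == {"a", "b"}

    def test_identical_intervals_share_letter(self):
        a = EtpiSummary("a", 0.5, 0.0, 1.0)
        b = EtpiSummary("b", 0.5, 0.0, 1.0)
        labels = prefmodel.letter_groups([a, b])
        assert labels["a"] == labels["b"] == "a"

    def test_overlap_chain(self):
        a = EtpiSummary("A", 1.0, 0.0, 2.0)
        b = EtpiSummary("B", 2.0, 1.5, 3.0)
        c = EtpiSummary("C", 3.5, 2.5, 4.0)
        labels = prefmodel.letter_groups([a, b, c])
        assert labels == {"A": "a", "B": "ab", "C": "b"}
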