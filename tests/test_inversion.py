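"""Likelihood caching, the marginalised mixture, and exceedance classification."""

import numpy as np
import pytest
from hypothesis import given, settings as hsettings, strategies as st
from scipy import stats

from temporev import (
    AgentConfig,
    Preferences,
    action_probabilities,
    build_likelihood_cache,
    classify,
    exceedance,
    expected_free_energy,
    fit_hierarchical,
    init_beliefs,
    numax_posterior,
    predict,
    preference_transform,
    response_loglik,
    run_agent,
    update_dirichlet,
    update_state_beliefs,
)
from temporev.inversion import SamplerSettings, _loglik_all_nu


@pytest.fixture(scope="module")
def short_cache(short_schedule, std_prefs):
    sched, table = short_schedule
    cfg = AgentConfig(nu_max=5, gamma=5.0, preferences=std_prefs)
    res = run_agent(cfg, sched, table, seed=77, subject="s0")
    cache = build_likelihood_cache(res.records, condition="regular", from_trial=300)
    return cache, res.records


class TestPreferenceTransform:
    def test_boundary_equality(self):
        prefs = preference_transform([1.0, 0.0, 0.0])
        assert np.allclose(prefs.vector, [0.5, 0.5, 0.0, 0.0])

    def test_simulation_standard_vector(self):
        prefs = preference_transform([0.2, 0.5, 0.3])
        assert np.allclose(prefs.vector, [0.1, 0.6, 0.15, 0.15])

    @given(
        st.lists(st.floats(0.01, 1.0), min_size=3, max_size=3).map(
            lambda v: np.array(v) / np.sum(v)
        )
    )
    @hsettings(max_examples=25, deadline=None, derandomize=True)
    def test_algebraic_properties(self, p):
        prefs = preference_transform(p)
        assert np.isclose(prefs.vector.sum(), 1.0)
        assert np.isclose(prefs.p_plus - prefs.p_minus, p[1], atol=1e-12)

    def test_off_simplex_rejected(self):
        with pytest.raises(ValueError):
            preference_transform([0.5, 0.5, 0.5])


class TestLikelihoodCache:
    def test_deterministic(self, short_schedule, std_prefs):
        sched, table = short_schedule
        cfg = AgentConfig(nu_max=3, gamma=5.0, preferences=std_prefs)
        res = run_agent(cfg, sched, table, seed=5)
        c1 = build_likelihood_cache(res.records, from_trial=300)
        c2 = build_likelihood_cache(res.records, from_trial=300)
        assert np.array_equal(c1.mu_bar, c2.mu_bar)
        assert np.array_equal(c1.base, c2.base)

    def test_two_option_subject_has_no_explore(self, short_schedule, std_prefs):
        sched, table = short_schedule
        cfg = AgentConfig(nu_max=2, gamma=5.0, preferences=std_prefs, n_options=2)
        res = run_agent(cfg, sched, table, seed=6)
        cache = build_likelihood_cache(res.records, n_options=2, from_trial=300)
        assert cache.actions == (1, 3)
        assert cache.mu_bar.shape[2] == 2

    def test_inconsistent_record_names_trial(self, short_cache):
        _, records = short_cache
        bad = records.copy()
        bad.loc[bad["trial"] == 310, "outcome"] = 3  # cue outcome for a card
        bad.loc[bad["trial"] == 310, "choice"] = 1
        with pytest.raises(ValueError, match="trial 310"):
            build_likelihood_cache(bad, from_trial=300)

    def test_gamma_zero_uniform_likelihood(self, short_cache, std_prefs):
        cache, _ = short_cache
        ll = response_loglik(cache, 1, 0.0, std_prefs)
        assert np.isclose(ll, cache.n_included * np.log(1.0 / 3.0))

    def test_missing_responses_excluded(self, short_schedule, std_prefs):
        sched, table = short_schedule
        cfg = AgentConfig(nu_max=2, gamma=5.0, preferences=std_prefs)
        res = run_agent(cfg, sched, table, seed=8)
        rec = res.records.astype({"choice": float, "outcome": float})
        rec.loc[rec["trial"].isin([320, 321, 400]), ["choice", "outcome"]] = np.nan
        cache = build_likelihood_cache(rec, from_trial=300)
        full = build_likelihood_cache(res.records, from_trial=300)
        assert cache.n_included == full.n_included - 3
        ll = response_loglik(cache, 4, 0.0, std_prefs)
        assert np.isclose(ll, cache.n_included * np.log(1.0 / 3.0))

    def test_cache_matches_slow_end_to_end_likelihood(self, short_cache, std_prefs):
        """The cached reconstruction G = base - mu_bar @ ln P_o must equal a
        from-scratch replay computing expected free energy trial by trial."""
        cache, records = short_cache
        gamma, nu_max = 3.7, 4
        cfg = AgentConfig(nu_max=nu_max, gamma=gamma, preferences=std_prefs)
        belief = init_beliefs(cfg)
        slow_ll = 0.0
        k = nu_max - 1
        for _, row in records.sort_values("trial").iterrows():
            t, a, o = int(row["trial"]), int(row["choice"]), int(row["outcome"])
            if t >= 300:
                efe = expected_free_energy(belief, std_prefs)
                i = t - 300
                G_cache = cache.base[k, i] - cache.mu_bar[k, i] @ std_prefs.log_vector
                assert np.max(np.abs(G_cache - efe.G)) < 1e-10
                probs = action_probabilities(efe, gamma)
                slow_ll += np.log(probs[efe.actions.index(a)])
            belief, _ = update_state_beliefs(belief, a, o)
            belief.counts = update_dirichlet(belief, a, o)
            belief = predict(belief)
        fast_ll = response_loglik(cache, nu_max, gamma, std_prefs)
        assert abs(fast_ll - slow_ll) < 1e-8

    def test_loglik_finite_and_nonpositive(self, short_cache, rng):
        cache, _ = short_cache
        for _ in range(20):
            gamma = rng.uniform(0.0, 10.0)
            p = rng.dirichlet(np.ones(3))
            ll = _loglik_all_nu(cache, gamma, preference_transform(p))
            assert np.all(np.isfinite(ll)) and np.all(ll <= 0.0)


class TestNumaxPosterior:
    def test_equal_likelihoods_return_weights(self, rng):
        r = rng.dirichlet(np.ones(10))
        post = numax_posterior(np.full(10, -123.4), r)
        assert np.allclose(post, r, atol=1e-12)

    def test_dominant_component(self):
        ll = np.full(10, -500.0)
        ll[3] = -500.0 + np.log(1e6)
        post = numax_posterior(ll, np.full(10, 0.1))
        assert post[3] > 0.999

    def test_matches_extended_precision_bayes(self, rng):
        ll = rng.normal(-400, 5, size=10)
        r = rng.dirichlet(np.ones(10))
        post = numax_posterior(ll, r)
        hi = np.longdouble(r) * np.exp(np.longdouble(ll - ll.max()))
        hi = hi / hi.sum()
        assert np.max(np.abs(post - hi.astype(float))) < 1e-12

    def test_mixture_identity_two_components(self):
        # marginal mixture log-likelihood = logsumexp(log w + component ll)
        from scipy.special import logsumexp

        ll = np.array([-10.0, -12.0])
        w = np.array([0.3, 0.7])
        mix = logsumexp(np.log(w) + ll)
        direct = np.log(w[0] * np.exp(ll[0]) + w[1] * np.exp(ll[1]))
        assert np.isclose(mix, direct, atol=1e-12)


class TestExceedance:
    def test_unanimous(self):
        resp = np.zeros((50, 10))
        resp[:, 0] = 1.0
        X = exceedance(resp)
        assert X[0] == 1.0 and classify(X) == "numax=1"

    def test_split_samples(self):
        resp = np.zeros((10, 10))
        resp[:6, 3] = 1.0  # nu = 4 wins in 60% of samples
        resp[6:, 0] = 1.0
        X = exceedance(resp)
        assert np.isclose(X[3], 0.6) and classify(X) == "numax>1"

    def test_sums_to_one(self, rng):
        resp = rng.dirichlet(np.ones(10), size=200)
        assert np.isclose(exceedance(resp).sum(), 1.0)

    def test_tie_breaks_toward_smaller_nu(self):
        resp = np.full((4, 10), 0.1)  # exact ties every sample
        X = exceedance(resp)
        assert X[0] == 1.0 and classify(X) == "numax=1"


class TestHierarchicalSampler:
    def test_prior_recovery(self, short_cache):
        """With the likelihood disabled the sampler must reproduce the
        Inverse-Gamma(2,2) prior on gamma and the flat Dirichlet on p."""
        cache, _ = short_cache
        fit = fit_hierarchical(
            [cache],
            settings=SamplerSettings(n_chains=2, n_warmup=300, n_samples=700, mh_steps=2),
            seed=42,
            prior_only=True,
        )
        g = fit.gamma[:, 0]
        med_true = stats.invgamma(2, scale=2).median()
        assert abs(np.median(g) - med_true) < 0.25
        assert np.allclose(fit.p.mean(axis=0)[0], 1.0 / 3.0, atol=0.05)

    def test_tau_limit_forces_uniform_weights(self, short_cache):
        cache, _ = short_cache
        fit = fit_hierarchical(
            [cache],
            settings=SamplerSettings(n_chains=1, n_warmup=100, n_samples=300),
            seed=3,
            prior_only=True,
            fix_tau=1e-3,
        )
        assert np.max(np.abs(fit.r.mean(axis=0) - 0.1)) < 0.02
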