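"""SIR posterior estimation, Gamma summaries, marginal-likelihood estimator."""

import numpy as np
import pytest
from scipy import special, stats

from jointpsych import (
    DegenerateFitWarning,
    GammaSummary,
    SamplingError,
    fit_gamma_summary,
    generate_dataset,
    marginal_loglik,
    sir,
    sir_sample,
)


def uniform_proposer(rng, size):
    return {"p": rng.uniform(0.0, 1.0, size)}


class TestSIRCore:
    def test_prior_recovery_under_constant_likelihood(self):
        """With a flat likelihood the resampled draws are prior draws."""
        rng = np.random.default_rng(42)
        res = sir(
            propose=uniform_proposer,
            log_likelihood_fn=lambda d: np.zeros(d["p"].size),
            n_proposals=25_000,
            n_final=2_000,
            rng=rng,
        )
        fresh = np.random.default_rng(43).uniform(0, 1, 2_000)
        assert stats.ks_2samp(res.draws["p"], fresh).pvalue > 0.01

    def test_beta_binomial_posterior_mean(self):
        """Conjugate oracle: Beta(1,1) prior + Binomial(k=7, n=10) data has
        posterior Beta(8, 4) with mean 8/12."""
        rng = np.random.default_rng(7)
        res = sir(
            propose=uniform_proposer,
            log_likelihood_fn=lambda d: stats.binom.logpmf(7, 10, d["p"]),
            n_proposals=25_000,
            n_final=2_000,
            rng=rng,
        )
        post_sd = np.sqrt(8 * 4 / (12.0**2 * 13.0))
        # resampled mean carries both importance-weighting and resampling noise
        mc_se = post_sd * np.sqrt(1.0 / res.ess + 1.0 / res.draws["p"].size)
        assert res.draws["p"].mean() == pytest.approx(8 / 12, abs=3 * mc_se)

    def test_beta_binomial_marginal_likelihood(self):
        """Closed form: integral of Binomial(7|10, p) over p ~ U(0,1) is
        C(10,7) * B(8,4) = 1/11."""
        rng = np.random.default_rng(8)
        res = sir(
            propose=uniform_proposer,
            log_likelihood_fn=lambda d: stats.binom.logpmf(7, 10, d["p"]),
            n_proposals=25_000,
            n_final=2_000,
            rng=rng,
        )
        w = np.exp(res.proposal_log_weights)
        mc_se = w.std() / (w.mean() * np.sqrt(w.size))  # delta method on log Z
        assert res.marginal_loglik == pytest.approx(np.log(1 / 11), abs=3 * mc_se)

    def test_resampling_preserves_support_and_weights(self):
        rng = np.random.default_rng(5)
        loglik = lambda d: stats.binom.logpmf(3, 5, d["p"])
        proposals_seen = {}

        def proposer(rng_, size):
            out = uniform_proposer(rng_, size)
            proposals_seen.update(out)
            return out

        res = sir(proposer, loglik, 2_000, 500, rng)
        assert np.all(np.isin(res.draws["p"], proposals_seen["p"]))
        # prior proposals: importance weight proportional to likelihood
        logw = res.proposal_log_weights
        np.testing.assert_allclose(
            logw, stats.binom.logpmf(3, 5, proposals_seen["p"]), rtol=1e-12
        )
        norm = np.exp(logw - special.logsumexp(logw))
        assert norm.sum() == pytest.approx(1.0, abs=1e-9)

    def test_all_zero_weights_error(self):
        rng = np.random.default_rng(0)
        with pytest.raises(SamplingError):
            sir(uniform_proposer, lambda d: np.full(d["p"].size, -np.inf), 100, 10, rng)

    def test_invalid_sizes_error(self):
        rng = np.random.default_rng(0)
        with pytest.raises(SamplingError):
            sir(uniform_proposer, lambda d: np.zeros(d["p"].size), 10, 20, rng)


class TestSirSample:
    def test_coverage_of_generating_parameters(self, default_params, fixed_scheme):
        """Central 95% credible intervals for m and w cover the generator in
        at least 90 of 100 seeded replicates."""
        hits = {"m": 0, "w": 0}
        for rep in range(100):
            data = generate_dataset(default_params, fixed_scheme, seed=1000 + rep)
            post = sir_sample(data, seed=2000 + rep, n_proposals=5_000, n_final=500)
            for name in hits:
                lo, hi = np.quantile(post.draws[name], [0.025, 0.975])
                hits[name] += lo <= getattr(default_params, name) <= hi
        assert hits["m"] >= 90
        assert hits["w"] >= 90

    def test_posterior_concentrates_with_more_trials(self, default_params, fixed_scheme):
        """Doubling every block's trial count does not increase the posterior
        IQR of w on average over seeds."""
        from jointpsych import SamplingScheme

        double = SamplingScheme(
            intensities=fixed_scheme.intensities,
            trials_per_block=tuple(2 * t for t in fixed_scheme.trials_per_block),
        )
        iqrs = {"base": [], "double": []}
        for rep in range(20):
            for tag, scheme in (("base", fixed_scheme), ("double", double)):
                d = generate_dataset(default_params, scheme, seed=500 + rep)
                post = sir_sample(d, seed=900 + rep, n_proposals=5_000, n_final=500)
                q1, q3 = np.quantile(post.draws["w"], [0.25, 0.75])
                iqrs[tag].append(q3 - q1)
        assert np.mean(iqrs["double"]) <= np.mean(iqrs["base"])

    def test_low_ess_warns_and_flags_degenerate(self, default_params, fixed_scheme):
        data = generate_dataset(default_params, fixed_scheme, seed=3)
        with pytest.warns(DegenerateFitWarning):
            post = sir_sample(
                data, seed=4, n_proposals=2_000, n_final=200, ess_floor=1e6
            )
        assert post.degenerate

    def test_determinism(self, default_params, fixed_scheme):
        data = generate_dataset(default_params, fixed_scheme, seed=3)
        a = sir_sample(data, seed=4, n_proposals=2_000, n_final=200)
        b = sir_sample(data, seed=4, n_proposals=2_000, n_final=200)
        assert a.draws.equals(b.draws)
        assert a.marginal_loglik_estimate == b.marginal_loglik_estimate


class TestGammaSummary:
    def test_recovers_known_gamma(self):
        rng = np.random.default_rng(11)
        x = rng.gamma(3.0, 1 / 2.0, 2_000)
        s = fit_gamma_summary(x)
        assert 2.7 <= s.shape <= 3.3
        assert 1.8 <= s.rate <= 2.2

    def test_exponential_is_gamma_shape_one(self):
        rng = np.random.default_rng(12)
        s = fit_gamma_summary(rng.exponential(1.0, 2_000))
        assert s.shape == pytest.approx(1.0, rel=0.1)

    def test_fitted_mean_matches_sample_mean(self):
        rng = np.random.default_rng(13)
        x = rng.gamma(5.0, 2.0, 500)
        s = fit_gamma_summary(x)
        assert s.mean == pytest.approx(x.mean(), rel=0.01)

    def test_agrees_with_reference_mle(self):
        """Independent cross-check against scipy's Gamma MLE (floc=0)."""
        rng = np.random.default_rng(14)
        x = rng.gamma(2.5, 1 / 1.5, 1_000)
        ours = fit_gamma_summary(x)
        shape_ref, _, scale_ref = stats.gamma.fit(x, floc=0)
        assert ours.shape == pytest.approx(shape_ref, rel=1e-4)
        assert ours.rate == pytest.approx(1 / scale_ref, rel=1e-4)

    @pytest.mark.parametrize(
        "samples",
        [
            np.full(100, 2.0),  # degenerate variance
            np.linspace(-1, 1, 100),  # non-positive values
            np.array([1.0, 2.0, 3.0]),  # too few
        ],
    )
    def test_invalid_inputs_error(self, samples):
        with pytest.raises(SamplingError):
            fit_gamma_summary(samples)

    def test_invalid_summary_parameters_error(self):
        with pytest.raises(SamplingError):
            GammaSummary(shape=-1.0, rate=2.0)


class TestMarginalLoglik:
    def test_constant_likelihood_is_exact(self):
        rng = np.random.default_rng(21)
        c = -3.7
        res = sir(uniform_proposer, lambda d: np.full(d["p"].size, c), 1_000, 100, rng)
        assert res.marginal_loglik == pytest.approx(c, abs=1e-12)

    def test_variance_halves_when_proposals_double(self):
        """Monte Carlo scaling: doubling n_proposals halves the variance of
        the marginal-likelihood estimate (ratio within [0.3, 0.8])."""
        loglik = lambda d: stats.binom.logpmf(7, 10, d["p"])
        est = {1_000: [], 2_000: []}
        for s in range(50):
            for n_prop in est:
                rng = np.random.default_rng(10_000 + s + 31 * n_prop)
                res = sir(uniform_proposer, loglik, n_prop, 100, rng)
                est[n_prop].append(np.exp(res.marginal_loglik))
        ratio = np.var(est[2_000]) / np.var(est[1_000])
        assert 0.3 <= ratio <= 0.8

    def test_requires_prior_proposals(self, default_params, fixed_scheme):
        data = generate_dataset(default_params, fixed_scheme, seed=3)
        post = sir_sample(data, seed=4, n_proposals=2_000, n_final=200)
        assert marginal_loglik(post) == post.marginal_loglik_estimate
        post.proposal_is_prior = False
        with pytest.raises(SamplingError):
            marginal_loglik(post)
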