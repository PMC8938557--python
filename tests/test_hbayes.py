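import numpy as np
import pytest
from scipy.special import expit

from affectbandit.errors import ConfigurationError, DataError, DomainError
from affectbandit.hbayes import (
    HAVE_NUMBA,
    HierarchicalPriors,
    McmcConfig,
    PosteriorSamples,
    SubjectDataset,
    _loglik_numpy,
    fast_mcmc_config,
    fit_hierarchical,
    log_likelihood,
    paper_mcmc_config,
    per_subject_log_likelihood,
    posterior_summary,
    rhat,
)


def make_dataset(rng, n_subjects=2, n_trials=30):
    seqs = {
        f"s{i}": (rng.integers(0, 2, n_trials), rng.integers(0, 2, n_trials))
        for i in range(n_subjects)
    }
    return SubjectDataset.from_sequences(seqs)


class TestConfigAccounting:
    def test_paper_protocol_retains_six_thousand(self):
        config = paper_mcmc_config()
        assert config.retained_per_chain == 2000
        assert config.retained_total == 6000

    def test_fast_protocol_accounting(self):
        config = fast_mcmc_config()
        assert config.retained_total == 3 * (4000 - 1000) // 2

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(burn_in=16_000),  # burn_in >= iterations
            dict(thin=0),
            dict(n_chains=0),
        ],
    )
    def test_invalid_config_rejected(self, kwargs):
        with pytest.raises(ConfigurationError):
            McmcConfig(**kwargs)

    def test_priors_require_ordered_bounds(self):
        with pytest.raises(ConfigurationError):
            HierarchicalPriors(mu_beta_bounds=(10.0, 10.0))


class TestLogLikelihood:
    def test_indifferent_model_two_trials(self):
        dataset = SubjectDataset.from_sequences({"s": ([0, 1], [1, 0])})
        value = log_likelihood(dataset, [0.5], [0.0])
        assert value == pytest.approx(2 * np.log(0.5), abs=1e-12)

    def test_additivity_over_subjects(self, rng):
        a = SubjectDataset.from_sequences({"x": (rng.integers(0, 2, 40), rng.integers(0, 2, 40))})
        b = SubjectDataset.from_sequences({"y": (rng.integers(0, 2, 25), rng.integers(0, 2, 25))})
        both = SubjectDataset.from_sequences(
            {"x": (a.choices[0, :40], a.rewards[0, :40]),
             "y": (b.choices[0, :25], b.rewards[0, :25])}
        )
        total = log_likelihood(both, [0.3, 0.7], [2.0, 1.0])
        assert total == pytest.approx(
            log_likelihood(a, [0.3], [2.0]) + log_likelihood(b, [0.7], [1.0]), rel=1e-12
        )

    def test_hand_propagated_three_trial_oracle(self):
        # scalar hand propagation of the delta rule + logistic choice
        choices, rewards = [0, 0, 1], [1, 0, 1]
        alpha, beta, q0 = 0.3, 2.0, 0.5
        qa, qb, expected = q0, q0, 0.0
        for c, r in zip(choices, rewards):
            p_a = expit(beta * (qa - qb))
            expected += np.log(p_a if c == 0 else 1 - p_a)
            if c == 0:
                qa += alpha * (r - qa)
            else:
                qb += alpha * (r - qb)
        dataset = SubjectDataset.from_sequences({"s": (choices, rewards)})
        assert log_likelihood(dataset, [alpha], [beta], q0) == pytest.approx(expected, rel=1e-12)

    def test_subject_order_invariance(self, rng):
        dataset = make_dataset(rng, n_subjects=3, n_trials=50)
        forward = log_likelihood(dataset, [0.2, 0.5, 0.8], [1.0, 2.0, 3.0])
        reordered = SubjectDataset.from_sequences(
            {
                "s2": (dataset.choices[2, :50], dataset.rewards[2, :50]),
                "s0": (dataset.choices[0, :50], dataset.rewards[0, :50]),
                "s1": (dataset.choices[1, :50], dataset.rewards[1, :50]),
            }
        )
        backward = log_likelihood(reordered, [0.8, 0.2, 0.5], [3.0, 1.0, 2.0])
        assert forward == pytest.approx(backward, rel=1e-12)

    def test_alpha_out_of_domain_is_error_not_minus_inf(self, rng):
        dataset = make_dataset(rng)
        with pytest.raises(DomainError):
            log_likelihood(dataset, [1.2, 0.5], [1.0, 1.0])

    @pytest.mark.skipif(not HAVE_NUMBA, reason="numba kernel not active")
    def test_numba_and_numpy_kernels_agree(self, rng):
        dataset = make_dataset(rng, n_subjects=5, n_trials=80)
        alphas = rng.uniform(0, 1, 5)
        betas = rng.uniform(0, 8, 5)
        fast = per_subject_log_likelihood(dataset, alphas, betas)
        slow = _loglik_numpy(dataset.choices, dataset.rewards, dataset.lengths,
                             alphas, betas, 0.5)
        np.testing.assert_allclose(fast, slow, rtol=1e-10)

    def test_empty_dataset_rejected(self):
        with pytest.raises(DataError):
            SubjectDataset.from_sequences({})


class TestSampler:
    def test_draw_count_and_support(self, rng):
        dataset = make_dataset(rng)
        config = McmcConfig(n_chains=2, n_iterations=300, burn_in=100, thin=4, seed=1)
        samples = fit_hierarchical(dataset, config=config, rhat_threshold=np.inf)
        assert samples.retained_per_chain == len(range(100, 300, 4)) == 50
        assert samples.retained_total == 100
        assert samples.alpha.min() >= 0.0 and samples.alpha.max() <= 1.0
        assert samples.beta.min() >= 0.0 and samples.beta.max() <= 10.0
        assert samples.hypers[..., 1].min() >= 0.0  # sigma_alpha within U(0,1)

    def test_prior_only_recovers_uniform_hyperprior_means(self, rng):
        dataset = make_dataset(rng, n_subjects=4)
        config = McmcConfig(n_chains=3, n_iterations=4000, burn_in=1000, thin=2, seed=5)
        samples = fit_hierarchical(dataset, config=config, prior_only=True,
                                   rhat_threshold=np.inf)
        mu_alpha = samples.get("mu_alpha").ravel()
        mu_beta = samples.get("mu_beta").ravel()
        assert abs(mu_alpha.mean() - 0.5) < 0.05
        assert abs(mu_beta.mean() - 5.0) < 0.5

    def test_determinism_per_seed(self, rng):
        dataset = make_dataset(rng)
        config = McmcConfig(n_chains=2, n_iterations=200, burn_in=50, thin=3, seed=9)
        first = fit_hierarchical(dataset, config=config, rhat_threshold=np.inf)
        second = fit_hierarchical(dataset, config=config, rhat_threshold=np.inf)
        np.testing.assert_array_equal(first.alpha, second.alpha)
        np.testing.assert_array_equal(first.hypers, second.hypers)


def constant_free_samples(chains):
    """Wrap raw hyper draws (chains x draws x 4) into PosteriorSamples."""
    chains = np.asarray(chains, dtype=float)
    n_chains, n_draws, _ = chains.shape
    return PosteriorSamples(
        alpha=np.tile(chains[..., :1], (1, 1, 1)) * 0 + 0.5
        + 0.001 * np.random.default_rng(0).standard_normal((n_chains, n_draws, 1)),
        beta=np.ones((n_chains, n_draws, 1))
        + 0.001 * np.random.default_rng(1).standard_normal((n_chains, n_draws, 1)),
        hypers=chains,
        subject_ids=("s0",),
        config=McmcConfig(n_chains=n_chains, n_iterations=n_draws, burn_in=0, thin=1),
        priors=HierarchicalPriors(),
    )


class TestDiagnosticsAndSummary:
    def test_rhat_identical_chains_is_one(self):
        draws = np.random.default_rng(3).standard_normal((1, 4000, 4)) * 0.1 + 0.5
        samples = constant_free_samples(np.repeat(draws, 3, axis=0))
        values = rhat(samples)
        for name in ("mu_alpha", "sigma_alpha", "mu_beta", "sigma_beta"):
            assert values[name] == pytest.approx(1.0, abs=0.01)

    def test_rhat_detects_offset_chain(self):
        rng = np.random.default_rng(4)
        chains = rng.standard_normal((3, 1000, 4)) * 0.05 + 0.5
        chains[2] += 0.5  # 10 SDs off
        samples = constant_free_samples(chains)
        assert rhat(samples)["mu_alpha"] > 1.5

    def test_rhat_single_chain_unavailable(self):
        draws = np.random.default_rng(5).standard_normal((1, 100, 4)) * 0.05 + 0.5
        samples = constant_free_samples(draws)
        assert all(np.isnan(v) for v in rhat(samples).values())

    def test_summary_of_constant_and_bernoulli_draws(self):
        hypers = np.full((2, 100, 4), 0.25)
        samples = constant_free_samples(hypers)
        summary = posterior_summary(samples)
        row = summary.loc["mu_alpha"]
        assert row["mean"] == pytest.approx(0.25)
        assert row["ci_2.5"] == pytest.approx(0.25)
        assert row["ci_97.5"] == pytest.approx(0.25)
        mixed = np.zeros((2, 100, 4))
        mixed[:, 50:, :] = 1.0
        mean = posterior_summary(constant_free_samples(mixed)).loc["mu_beta", "mean"]
        assert mean == pytest.approx(0.5)
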