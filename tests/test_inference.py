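import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from biasedbayes.inference import (
    BiasParams,
    DiscreteDistribution,
    GaussianDist,
    LikelihoodTable,
    RewardFunction,
    biased_update,
    combine_with_reward,
    exponential_bias,
    gaussian_biased_update,
    point_estimate,
    sequential_update,
)

from conftest import random_discrete_problem


def brute_force_bayes(prior, likelihood):
    """Independent linear-space oracle for the unbiased update."""
    w = prior.probs * np.exp(likelihood.log_weight)
    return w / w.sum()


class TestBiasParams:
    @pytest.mark.parametrize("alpha,beta", [(-0.1, 1), (1, -2), (float("nan"), 1)])
    def test_rejects_invalid(self, alpha, beta):
        with pytest.raises(ValueError):
            BiasParams(alpha, beta)

    def test_zero_and_inf_allowed(self):
        assert BiasParams(0, 0).alpha == 0
        assert not BiasParams(math.inf, 1).finite


class TestDiscreteDistribution:
    def test_normalizes_on_construction(self):
        d = DiscreteDistribution([0, 1, 2], np.log([2.0, 4.0, 2.0]))
        assert d.probs == pytest.approx([0.25, 0.5, 0.25], abs=1e-12)

    def test_zero_mass_allowed_but_not_everywhere(self):
        d = DiscreteDistribution.from_probs([0, 1], [0.0, 1.0])
        assert d.prob_of(0) == 0.0
        with pytest.raises(ValueError, match="all-zero"):
            DiscreteDistribution.from_probs([0, 1], [0.0, 0.0])

    def test_support_validation(self):
        with pytest.raises(ValueError, match="increasing"):
            DiscreteDistribution.from_probs([1, 0], [0.5, 0.5])
        with pytest.raises(ValueError, match="unique"):
            DiscreteDistribution.from_probs(["a", "a"], [0.5, 0.5])


class TestBiasedUpdate:
    def test_disease_worked_example(self, disease):
        post = biased_update(*disease, BiasParams(1, 1))
        assert post.prob_of("ill") == pytest.approx(0.0098, abs=5e-5)

    def test_flattened_prior_yields_likelihood(self, disease):
        post = biased_update(*disease, BiasParams(0, 1))
        assert post.prob_of("ill") == pytest.approx(0.99, abs=1e-12)

    def test_rigidity_limit_returns_prior(self, disease):
        prior, likelihood = disease
        post = biased_update(prior, likelihood, BiasParams(1, 0))
        np.testing.assert_allclose(post.probs, prior.probs, atol=1e-15)

    def test_matches_gaussian_closed_form(self, gaussian_pair):
        prior, like = gaussian_pair
        grid = np.linspace(-8, 8, 2001)
        post = biased_update(
            prior.discretize(grid), like.to_likelihood(grid), BiasParams(2, 1)
        )
        mean = point_estimate(post, "mean")
        var = float(np.sum(post.probs * (grid - mean) ** 2))
        closed = gaussian_biased_update(prior, like, BiasParams(2, 1))
        assert closed.mean == pytest.approx(1.0)
        assert closed.variance == pytest.approx(1 / 3)
        assert mean == pytest.approx(closed.mean, abs=1e-3)
        assert var == pytest.approx(closed.variance, abs=1e-3)

    def test_support_mismatch_and_degenerate_errors(self, disease):
        prior, _ = disease
        other = LikelihoodTable.from_weights(["a", "b"], [1, 1])
        with pytest.raises(ValueError, match="support"):
            biased_update(prior, other, BiasParams(1, 1))
        p = DiscreteDistribution.from_probs([0, 1], [1, 0])
        l = LikelihoodTable.from_weights([0, 1], [0, 1])
        with pytest.raises(ValueError, match="degenerate"):
            biased_update(p, l, BiasParams(1, 1))

    def test_both_zero_gives_uniform_on_grid(self, disease):
        post = biased_update(*disease, BiasParams(0, 0))
        np.testing.assert_allclose(post.probs, [0.5, 0.5], atol=1e-15)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_unbiased_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        prior, likelihood = random_discrete_problem(rng)
        post = biased_update(prior, likelihood, BiasParams(1, 1))
        np.testing.assert_allclose(post.probs, brute_force_bayes(prior, likelihood), atol=1e-12)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        seed=st.integers(0, 10_000),
        alpha=st.floats(0, 4),
        beta=st.floats(0, 4),
    )
    def test_posterior_always_normalized(self, seed, alpha, beta):
        rng = np.random.default_rng(seed)
        prior, likelihood = random_discrete_problem(rng)
        post = biased_update(prior, likelihood, BiasParams(alpha, beta))
        assert abs(post.probs.sum() - 1.0) < 1e-12

    def test_mass_at_likelihood_mode_monotone_in_beta(self, disease):
        prior, likelihood = disease
        argmax = likelihood.support[np.argmax(likelihood.log_weight)]
        masses = [
            biased_update(prior, likelihood, BiasParams(1, b)).prob_of(argmax)
            for b in (1, 10, 100, 1000)
        ]
        assert all(m2 >= m1 for m1, m2 in zip(masses, masses[1:]))
        assert masses[-1] > 0.999


class TestExponentialBias:
    def test_identity_and_uniform_limits(self):
        rng = np.random.default_rng(0)
        d = DiscreteDistribution.from_probs(np.arange(10), rng.dirichlet(np.ones(10)))
        np.testing.assert_allclose(exponential_bias(d, 1.0).probs, d.probs, atol=1e-15)
        np.testing.assert_allclose(exponential_bias(d, 0.0).probs, np.full(10, 0.1), atol=1e-15)

    def test_beta_density_power_identity(self):
        # squaring a Beta(2,5) density gives a renormalized Beta(3,9) density
        x = np.linspace(0, 1, 2003)[1:-1]
        d = DiscreteDistribution.from_probs(x, stats.beta.pdf(x, 2, 5))
        expected = DiscreteDistribution.from_probs(x, stats.beta.pdf(x, 3, 9))
        np.testing.assert_allclose(exponential_bias(d, 2.0).probs, expected.probs, atol=1e-6)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000), gamma=st.floats(0, 5))
    def test_entropy_ordering(self, seed, gamma):
        rng = np.random.default_rng(seed)
        d = DiscreteDistribution.from_probs(np.arange(8), rng.dirichlet(np.ones(8)))
        h0, h1 = d.entropy(), exponential_bias(d, gamma).entropy()
        if gamma < 1:
            assert h1 >= h0 - 1e-10
        elif gamma > 1:
            assert h1 <= h0 + 1e-10

    def test_negative_gamma_rejected(self):
        d = DiscreteDistribution.uniform([0, 1])
        with pytest.raises(ValueError):
            exponential_bias(d, -0.5)


class TestGaussianBiasedUpdate:
    def test_symmetric_conjugate_case(self):
        post = gaussian_biased_update(GaussianDist(0, 1), GaussianDist(0, 1), BiasParams(1, 1))
        assert (post.mean, post.variance) == (0.0, 0.5)

    def test_huge_beta_converges_to_likelihood_mode(self, gaussian_pair):
        post = gaussian_biased_update(*gaussian_pair, BiasParams(1, 1e6))
        assert post.mean == pytest.approx(3.0, abs=1e-3)

    def test_flat_limit_is_improper(self, gaussian_pair):
        with pytest.raises(ValueError, match="improper"):
            gaussian_biased_update(*gaussian_pair, BiasParams(0, 0))


class TestSequentialUpdate:
    def test_order_invariance_of_unbiased_updates(self):
        rng = np.random.default_rng(1)
        support = np.arange(5)
        prior, l1 = random_discrete_problem(rng, support=support)
        _, l2 = random_discrete_problem(rng, support=support)
        a = sequential_update(prior, [l1, l2], BiasParams(1, 1))[-1]
        b = sequential_update(prior, [l2, l1], BiasParams(1, 1))[-1]
        np.testing.assert_allclose(a.probs, b.probs, atol=1e-12)

    def test_forgetting_washes_out_the_prior(self):
        # alpha=0.5, beta=0: after n steps the prior enters as p**(0.5**n)
        prior = DiscreteDistribution.from_probs([0, 1], [0.9, 0.1])
        flat_evidence = LikelihoodTable.from_weights([0, 1], [1.0, 1.0])
        traj = sequential_update(prior, [flat_evidence] * 10, BiasParams(0.5, 0))
        assert len(traj) == 11
        assert np.max(np.abs(traj[-1].probs - 0.5)) < 1e-3
        gamma = 0.5**10
        oracle = prior.probs**gamma / np.sum(prior.probs**gamma)
        np.testing.assert_allclose(traj[-1].probs, oracle, atol=1e-12)

    def test_repeated_likelihood_matches_conjugate_form(self, gaussian_pair):
        prior, like = gaussian_pair
        grid = np.linspace(-8, 8, 2001)
        traj = sequential_update(
            prior.discretize(grid), [like.to_likelihood(grid)] * 3, BiasParams(1, 1)
        )
        oracle = gaussian_biased_update(
            prior, GaussianDist(like.mean, like.variance / 3), BiasParams(1, 1)
        )
        mean = point_estimate(traj[-1], "mean")
        var = float(np.sum(traj[-1].probs * (grid - mean) ** 2))
        assert mean == pytest.approx(oracle.mean, abs=1e-3)
        assert var == pytest.approx(oracle.variance, abs=1e-3)

    def test_empty_stream_returns_initial_prior(self, disease):
        prior, _ = disease
        assert sequential_update(prior, [], BiasParams(1, 1)) == [prior]


class TestRewardCombination:
    def test_ev_ratio_and_identity_reward(self):
        support = ["H1", "H2"]
        post = DiscreteDistribution.uniform(support)
        ev = combine_with_reward(post, RewardFunction(support, [2.0, 1.0]))
        assert np.exp(ev.log_weight[0] - ev.log_weight[1]) == pytest.approx(2.0)
        flat = combine_with_reward(post, RewardFunction(support, [1.0, 1.0]))
        np.testing.assert_allclose(np.exp(flat.log_weight), post.probs, atol=1e-15)

    def test_reward_can_equalize_expected_value(self):
        post = DiscreteDistribution.from_probs(["H1", "H2"], [0.8, 0.2])
        ev = combine_with_reward(post, RewardFunction(["H1", "H2"], [1.0, 4.0]))
        assert ev.log_weight[0] == pytest.approx(ev.log_weight[1], abs=1e-12)

    def test_nonpositive_reward_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            RewardFunction(["H1", "H2"], [1.0, 0.0])


class TestPointEstimate:
    def test_mode_mean_median(self):
        d = DiscreteDistribution.from_probs([0, 1, 2], [0.2, 0.5, 0.3])
        assert point_estimate(d, "mode") == 1
        assert point_estimate(d, "mean") == pytest.approx(1.1)
        assert point_estimate(d, "median") == 1

    def test_mode_tie_breaks_to_smallest(self):
        d = DiscreteDistribution.uniform([0, 1])
        assert point_estimate(d, "mode") == 0

    def test_disease_mode_is_healthy(self, disease):
        post = biased_update(*disease, BiasParams(1, 1))
        assert point_estimate(post, "mode") == "healthy"

    def test_mean_on_categorical_support_rejected(self, disease):
        prior, _ = disease
        with pytest.raises(ValueError, match="numeric"):
            point_estimate(prior, "mean")
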