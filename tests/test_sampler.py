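import numpy as np
import pytest

from jointfc import (
    ChainSettings,
    ModelHyperparameters,
    conditional_theta_params,
    fit_all_pairs,
    gibbs_step_theta,
    metropolis_step_pi,
    run_chains_batch,
    run_pair_chain,
    simulate_pair_dataset,
)


class _StubRng:
    """Deterministic stand-in for a Generator in single-step tests."""

    def __init__(self, normal, uniform):
        self._normal = normal
        self._uniform = uniform

    def standard_normal(self):
        return self._normal

    def uniform(self):
        return self._uniform


class TestMetropolisStep:
    def test_out_of_bounds_proposal_rejected(self, hyper):
        theta = np.array([0.3, 0.2, 0.2, 0.3])
        # proposal = 0.05 + 1.0 * (-0.15) = -0.10, outside (0, 1)
        rng = _StubRng(normal=-0.15, uniform=0.99)
        new_pi, accepted = metropolis_step_pi(0.05, 1.0, theta, [50], hyper, rng)
        assert not accepted
        assert new_pi == 0.05

    def test_uphill_proposal_always_accepted(self, hyper):
        theta = np.array([0.3, 0.2, 0.2, 0.3])
        S = [300]
        # conditional mode is near 0.3; moving 0.05 -> 0.25 is uphill, and
        # uniform=1 (log ~ 0-) would reject anything not strictly uphill
        rng = _StubRng(normal=0.2, uniform=1.0 - 1e-12)
        new_pi, accepted = metropolis_step_pi(0.05, 1.0, theta, S, hyper, rng)
        assert accepted
        assert new_pi == pytest.approx(0.25)

    def test_constant_link_long_run_mean_matches_beta(self, constant_hyper):
        # S summing to 300 over 3 subjects: pi | S ~ Beta(301, 2701)
        Z = np.tile([25, 25, 25, 25], (3, 1))
        S = [100, 100, 100]
        settings = ChainSettings(n_iterations=4000, n_burnin=1000, thin=4, seed=9)
        post = run_pair_chain(Z, S, constant_hyper, settings)
        target = 301 / 3002
        sd = np.sqrt(target * (1 - target) / (3002 + 1))
        mc_se = post.pi_samples.std(ddof=1) / np.sqrt(post.pi_samples.size)
        assert abs(post.pi_mean - target) < 3 * max(mc_se, sd / np.sqrt(post.pi_samples.size))


class TestGibbsStep:
    def test_uniform_dirichlet_mean(self, rng):
        hyper = ModelHyperparameters(
            alpha1=1.0, alpha2=1.0, alpha3=1.0, alpha4=1.0
        )
        # alpha(0) = 0, no data: full conditional is Dirichlet(1,1,1,1)
        draws = np.array(
            [gibbs_step_theta([[0, 0, 0, 0]], 0.0, hyper, rng) for _ in range(4000)]
        )
        se = draws.std(axis=0, ddof=1) / np.sqrt(len(draws))
        assert np.all(np.abs(draws.mean(axis=0) - 0.25) < 4 * se)

    def test_huge_counts_concentrate_at_proportions(self, rng, hyper):
        Z = [[400000, 300000, 200000, 100000]]
        draws = np.array([gibbs_step_theta(Z, 0.5, hyper, rng) for _ in range(50)])
        assert np.allclose(draws.mean(axis=0), [0.4, 0.3, 0.2, 0.1], atol=0.005)

    def test_moments_match_dirichlet_formulas(self, rng, hyper):
        Z = [[40, 30, 20, 110]]
        pi = 0.5
        params = conditional_theta_params(Z, pi, hyper)
        total = params.sum()
        mean = params / total
        var = params * (total - params) / (total**2 * (total + 1))
        draws = np.array(
            [gibbs_step_theta(Z, pi, hyper, rng) for _ in range(10000)]
        )
        se_mean = np.sqrt(var / len(draws))
        assert np.all(np.abs(draws.mean(axis=0) - mean) < 4 * se_mean)
        assert np.allclose(draws.var(axis=0, ddof=1), var, rtol=0.15)


class TestRunPairChain:
    def test_same_seed_identical_samples(self, hyper, fast_settings, rng):
        Z, S, _, _ = simulate_pair_dataset(hyper, 5, rng=rng)
        a = run_pair_chain(Z, S, hyper, fast_settings)
        b = run_pair_chain(Z, S, hyper, fast_settings)
        assert np.array_equal(a.theta_samples, b.theta_samples)
        assert np.array_equal(a.pi_samples, b.pi_samples)
        assert a.acceptance_rate == b.acceptance_rate

    def test_kept_sample_count(self, hyper, fast_settings, rng):
        Z, S, _, _ = simulate_pair_dataset(hyper, 5, rng=rng)
        post = run_pair_chain(Z, S, hyper, fast_settings)
        assert post.theta_samples.shape == (fast_settings.n_kept, 4)
        assert post.pi_samples.shape == (fast_settings.n_kept,)
        assert np.all((post.pi_samples > 0) & (post.pi_samples < 1))
        assert np.allclose(post.theta_samples.sum(axis=1), 1.0)

    def test_constant_link_theta_matches_conjugate_posterior(
        self, constant_hyper, rng
    ):
        Z, S, _, _ = simulate_pair_dataset(constant_hyper, 10, rng=rng)
        settings = ChainSettings(n_iterations=5000, n_burnin=1000, thin=5, seed=2)
        post = run_pair_chain(Z, S, constant_hyper, settings)
        params = Z.sum(axis=0) + np.array([15.0, 10.0, 10.0, 10.0])
        target = params / params.sum()
        mc_se = post.theta_samples.std(axis=0, ddof=1) / np.sqrt(
            post.theta_samples.shape[0]
        )
        assert np.all(np.abs(post.theta_mean - target) < 3 * mc_se)

    def test_acceptance_rate_adapted_into_window(self, hyper, rng):
        # data at the study scale: N=15 subjects, T=100, M=1000
        settings = ChainSettings(n_iterations=3000, n_burnin=1000, seed=77)
        for _ in range(3):
            Z, S, _, _ = simulate_pair_dataset(hyper, 15, rng=rng)
            post = run_pair_chain(Z, S, hyper, settings)
            assert 0.15 <= post.acceptance_rate <= 0.40

    def test_structural_pull_on_theta1(self, hyper):
        # fixed functional counts; stronger structural evidence should
        # raise the posterior mean of joint activation
        N = 15
        Zsum = np.tile([300.0, 350.0, 330.0, 520.0], (4, 1))
        Ssum = np.array([100.0, 3000.0, 8000.0, 14000.0])
        settings = ChainSettings(n_iterations=4000, n_burnin=1000, seed=5)
        theta_s, _, _ = run_chains_batch(Zsum, Ssum, N, hyper, settings)
        means = theta_s[:, :, 0].mean(axis=1)
        assert np.all(np.diff(means) > 0)

    def test_empty_data_rejected(self, hyper, fast_settings):
        with pytest.raises(ValueError):
            run_pair_chain(np.empty((0, 4)), [], hyper, fast_settings)


class TestFitAllPairs:
    def _toy_dataset(self, hyper, seed=0):
        rng = np.random.default_rng(seed)
        dataset = {}
        for pair in [("r1", "r2"), ("r1", "r3"), ("r2", "r3")]:
            Z, S, _, _ = simulate_pair_dataset(hyper, 4, rng=rng)
            dataset[pair] = (Z, S)
        return dataset

    def test_processing_order_invariance(self, hyper, fast_settings):
        dataset = self._toy_dataset(hyper)
        reversed_dataset = dict(reversed(list(dataset.items())))
        a = fit_all_pairs(dataset, hyper, fast_settings)
        b = fit_all_pairs(reversed_dataset, hyper, fast_settings)
        assert set(a) == set(b) and len(a) == 3
        for pair in a:
            assert np.array_equal(a[pair].theta_samples, b[pair].theta_samples)

    def test_missing_structural_fallback(self, hyper, fast_settings, caplog):
        dataset = self._toy_dataset(hyper)
        dataset[("r1", "r3")] = (dataset[("r1", "r3")][0], None)
        with pytest.raises(ValueError):
            fit_all_pairs(dataset, hyper, fast_settings)
        with caplog.at_level("WARNING"):
            result = fit_all_pairs(
                dataset, hyper, fast_settings, on_missing_structural="flat"
            )
        assert result[("r1", "r3")].structural_fallback
        assert "falling back" in caplog.text
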