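"""RBM energies, conditionals and contrastive divergence vs exact oracles."""

import numpy as np
import pytest
from scipy.special import logsumexp
from scipy.stats import multivariate_normal, norm

from rgcmodes.rbm import (
    RBMParams,
    TrainConfig,
    all_binary_vectors,
    cd_update,
    energy,
    exact_loglik,
    exact_loglik_grad,
    hidden_given_visible,
    sample_visible,
    train_rbm,
    visible_given_hidden,
)


def _random_params(rng, d=4, nh=3, kind="binary", scale=0.7):
    return RBMParams(
        scale * rng.standard_normal((d, nh)),
        scale * rng.standard_normal(d),
        scale * rng.standard_normal(nh),
        visible_kind=kind,
    )


def _energy_loops(params, v, h):
    """Independent scalar-loop evaluation of the energy."""
    e = 0.0
    if params.visible_kind == "binary":
        for i in range(params.n_visible):
            e -= params.a[i] * v[i]
    else:
        for i in range(params.n_visible):
            e += 0.5 * (v[i] - params.a[i]) ** 2
    for j in range(params.n_hidden):
        e -= params.b[j] * h[j]
        for i in range(params.n_visible):
            e -= v[i] * params.W[i, j] * h[j]
    return e


class TestEnergy:
    def test_all_zero_configuration_has_zero_energy(self):
        p = _random_params(np.random.default_rng(0), kind="binary")
        assert energy(p, np.zeros(4), np.zeros(3)) == pytest.approx(0.0)

    def test_gaussian_energy_vanishes_at_visible_bias(self):
        p = _random_params(np.random.default_rng(1), kind="gaussian")
        assert energy(p, p.a.copy(), np.zeros(3)) == pytest.approx(0.0)

    @pytest.mark.parametrize("kind", ["binary", "gaussian"])
    def test_matches_scalar_loop_evaluation(self, kind):
        rng = np.random.default_rng(2)
        p = _random_params(rng, kind=kind)
        v = rng.standard_normal(4) if kind == "gaussian" else rng.integers(0, 2, 4).astype(float)
        h = rng.integers(0, 2, 3).astype(float)
        assert energy(p, v, h) == pytest.approx(_energy_loops(p, v, h), rel=1e-12)

    def test_dimension_mismatch_rejected(self):
        p = _random_params(np.random.default_rng(0))
        with pytest.raises(ValueError):
            energy(p, np.zeros(5), np.zeros(3))


class TestConditionals:
    def test_zero_weights_make_hidden_independent_of_input(self, rng):
        p = RBMParams(np.zeros((4, 3)), np.zeros(4), rng.standard_normal(3), "binary")
        from scipy.special import expit

        for v in (np.zeros(4), np.ones(4)):
            assert np.allclose(hidden_given_visible(p, v), expit(p.b))

    def test_fully_neutral_model_gives_half_probabilities(self):
        p = RBMParams(np.zeros((4, 3)), np.zeros(4), np.zeros(3), "binary")
        assert np.allclose(hidden_given_visible(p, np.ones(4)), 0.5)

    @pytest.mark.parametrize("kind", ["binary", "gaussian"])
    def test_hidden_conditional_matches_enumeration(self, kind):
        # oracle: p(h_j=1|v) from exp(-E) summed over all hidden vectors
        rng = np.random.default_rng(3)
        p = _random_params(rng, d=3, nh=3, kind=kind)
        v = rng.standard_normal(3) if kind == "gaussian" else np.array([1.0, 0.0, 1.0])
        hs = all_binary_vectors(3)
        loge = np.array([-energy(p, v, h) for h in hs])
        probs = np.exp(loge - logsumexp(loge))
        brute = np.array([probs[hs[:, j] == 1].sum() for j in range(3)])
        assert np.allclose(hidden_given_visible(p, v), brute, atol=1e-10)

    def test_visible_mean_at_zero_hidden_is_bias(self):
        p = _random_params(np.random.default_rng(4), kind="gaussian")
        assert np.allclose(visible_given_hidden(p, np.zeros(3)), p.a)

    def test_gaussian_sampling_mean_and_unit_variance(self, rng):
        p = _random_params(np.random.default_rng(5), kind="gaussian")
        h = np.array([1.0, 0.0, 1.0])
        draws = np.stack([sample_visible(p, h, rng) for _ in range(10_000)])
        target = p.a + p.W @ h
        se = 1.0 / np.sqrt(draws.shape[0])
        assert np.abs(draws.mean(axis=0) - target).max() < 3 * se * 1.5
        assert np.abs(draws.var(axis=0) - 1.0).max() < 0.06


class TestExactLoglik:
    def test_neutral_one_unit_model_is_uniform(self):
        p = RBMParams(np.zeros((1, 1)), np.zeros(1), np.zeros(1), "binary")
        for v in ([0.0], [1.0]):
            assert exact_loglik(p, np.array([v])) == pytest.approx(-np.log(2))

    def test_factorized_gaussian_limit(self):
        rng = np.random.default_rng(6)
        p = RBMParams(np.zeros((3, 2)), rng.standard_normal(3), rng.standard_normal(2), "gaussian")
        v = rng.standard_normal(3)
        expected = norm.logpdf(v - p.a).sum()
        assert exact_loglik(p, v[None, :]) == pytest.approx(expected, rel=1e-10)

    def test_binary_model_matches_naive_double_sum(self):
        rng = np.random.default_rng(7)
        p = _random_params(rng, d=3, nh=2, kind="binary")
        vs, hs = all_binary_vectors(3), all_binary_vectors(2)
        table = np.array([[np.exp(-energy(p, v, h)) for h in hs] for v in vs])
        z = table.sum()
        data = np.array([[1.0, 0.0, 1.0], [0.0, 0.0, 0.0]])
        naive = np.mean(
            [np.log(table[np.flatnonzero((vs == v).all(axis=1))[0]].sum() / z) for v in data]
        )
        assert exact_loglik(p, data) == pytest.approx(naive, abs=1e-12)

    def test_gaussian_model_matches_mixture_density(self):
        # P(v) is a mixture of unit-variance Gaussians, one per hidden vector
        rng = np.random.default_rng(8)
        p = _random_params(rng, d=2, nh=3, kind="gaussian", scale=0.5)
        hs = all_binary_vectors(3)
        logw = hs @ p.b + (hs @ p.W.T) @ p.a + 0.5 * np.sum((hs @ p.W.T) ** 2, axis=1)
        w = np.exp(logw - logsumexp(logw))
        v = rng.standard_normal(2)
        mix = sum(
            wi * multivariate_normal.pdf(v, mean=p.a + p.W @ h, cov=np.eye(2))
            for wi, h in zip(w, hs)
        )
        assert exact_loglik(p, v[None, :]) == pytest.approx(np.log(mix), rel=1e-10)

    def test_enumeration_guard(self):
        # gaussian models always enumerate the hidden side
        p = RBMParams(np.zeros((2, 25)), np.zeros(2), np.zeros(25), "gaussian")
        with pytest.raises(ValueError, match="enumeration"):
            exact_loglik(p, np.zeros((1, 2)))


class TestContrastiveDivergence:
    def test_zero_learning_rate_changes_nothing(self, rng):
        p = _random_params(np.random.default_rng(9), kind="binary")
        cfg = TrainConfig(n_hidden=3, learning_rate=0.0, momentum=0.0, weight_decay=0.0)
        batch = np.random.default_rng(0).integers(0, 2, (8, 4)).astype(float)
        new, _ = cd_update(p, batch, cfg, rng)
        assert np.array_equal(new.W, p.W) and np.array_equal(new.a, p.a)

    def test_cd1_update_aligns_with_exact_gradient(self):
        # averaged over many seeded CD-1 updates, the expected update
        # direction has positive inner product with the exact gradient
        rng_model = np.random.default_rng(10)
        p = _random_params(rng_model, d=6, nh=3, kind="binary")
        data = np.random.default_rng(11).integers(0, 2, (20, 6)).astype(float)
        cfg = TrainConfig(
            n_hidden=3, learning_rate=1.0, momentum=0.0, weight_decay=0.0, batch_size=20
        )
        acc = np.zeros(6 * 3 + 6 + 3)
        for seed in range(200):
            new, _ = cd_update(p, data, cfg, np.random.default_rng(seed))
            acc += np.concatenate(
                [(new.W - p.W).ravel(), new.a - p.a, new.b - p.b]
            )
        acc /= 200
        gW, ga, gb = exact_loglik_grad(p, data)
        exact = np.concatenate([gW.ravel(), ga, gb])
        cos = acc @ exact / (np.linalg.norm(acc) * np.linalg.norm(exact))
        assert cos > 0.5

    def test_likelihood_rises_over_training(self):
        # exact average log-likelihood increases between initialization
        # and the end of CD training on a small fixed dataset
        rng = np.random.default_rng(12)
        data = np.vstack([
            np.tile([1, 1, 1, 0, 0, 0], (15, 1)),
            np.tile([0, 0, 0, 1, 1, 1], (15, 1)),
        ]).astype(float)
        cfg = TrainConfig(
            n_hidden=3, learning_rate=0.05, momentum=0.5, weight_decay=1e-4,
            batch_size=10, epochs=200, seed=1,
        )
        params, _ = train_rbm(data, cfg, visible_kind="binary")
        init = RBMParams(
            cfg.init_sigma * np.random.default_rng(cfg.seed).standard_normal((6, 3)),
            np.zeros(6), np.zeros(3), "binary",
        )
        assert exact_loglik(params, data) > exact_loglik(init, data) + 0.5

    def test_nan_parameters_abort(self, rng):
        p = _random_params(np.random.default_rng(13), kind="binary")
        p2 = RBMParams(p.W, p.a, p.b, "binary")
        cfg = TrainConfig(n_hidden=3, learning_rate=np.inf, momentum=0.0)
        with pytest.raises(FloatingPointError):
            cd_update(p2, np.ones((4, 4)), cfg, rng)


class TestGibbsChainConsistency:
    def test_chain_frequencies_match_boltzmann_distribution(self):
        # empirical state frequencies of alternating Gibbs sampling
        # converge to exp(-E)/Z (chi-square on visible marginals)
        rng = np.random.default_rng(14)
        p = _random_params(rng, d=3, nh=2, kind="binary", scale=0.5)
        vs = all_binary_vectors(3)
        logpv = []
        hs = all_binary_vectors(2)
        for v in vs:
            logpv.append(logsumexp([-energy(p, v, h) for h in hs]))
        logpv = np.array(logpv)
        pv = np.exp(logpv - logsumexp(logpv))

        n_chains, n_sweeps, burn = 500, 200, 100  # 1e5 post-burn-in sweeps
        v = rng.integers(0, 2, (n_chains, 3)).astype(float)
        counts = np.zeros(8)
        weights = np.array([4, 2, 1])  # index order of all_binary_vectors
        for sweep in range(n_sweeps):
            ph = hidden_given_visible(p, v)
            h = (rng.random(ph.shape) < ph).astype(float)
            pvis = visible_given_hidden(p, h)
            v = (rng.random(pvis.shape) < pvis).astype(float)
            if sweep >= burn:
                np.add.at(counts, (v @ weights).astype(int), 1)
        total = counts.sum()
        chi2 = ((counts - total * pv) ** 2 / (total * pv)).sum()
        # 7 dof: 99.9th percentile is ~24.3
        assert chi2 < 24.3
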