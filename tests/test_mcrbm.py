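"""Mean-covariance RBM: conditional Gaussians, free energy, training."""

import numpy as np
import pytest
from scipy.special import logsumexp

from rgcmodes.information import normalized_mi
from rgcmodes.mcrbm import (
    McRBMParams,
    free_energy,
    free_energy_grad,
    init_mcrbm,
    mcrbm_conditional_gaussian,
    mean_unit_probs,
    precision_unit_probs,
    sample_visible_given_latents,
    train_mcrbm,
)
from rgcmodes.modes import infer_states, mode_census
from rgcmodes.rbm import TrainConfig, all_binary_vectors


def _random_params(rng, d=4, nm=3, nf=5, nc=3, scale=0.6):
    return McRBMParams(
        W=scale * rng.standard_normal((d, nm)),
        a=scale * rng.standard_normal(d),
        b_m=scale * rng.standard_normal(nm),
        C=scale * rng.standard_normal((d, nf)),
        P=-np.abs(rng.standard_normal((nf, nc))),
        b_c=scale * rng.standard_normal(nc),
    )


def _energy(params, v, h_m, h_c):
    """Scalar evaluation of the third-order energy."""
    cv = params.C.T @ v
    return (
        0.5 * v @ v
        - params.a @ v
        - v @ params.W @ h_m
        - params.b_m @ h_m
        - params.b_c @ h_c
        - 0.5 * np.sum(params.P * np.outer(cv**2, h_c))
    )


class TestConditionalGaussian:
    def test_all_precision_units_off_gives_identity_covariance(self):
        p = _random_params(np.random.default_rng(0))
        mean, cov = mcrbm_conditional_gaussian(p, np.zeros(3), np.zeros(3))
        assert np.allclose(cov, np.eye(4))
        assert np.allclose(mean, p.a)

    def test_covariance_symmetric_positive_definite(self):
        rng = np.random.default_rng(1)
        p = _random_params(rng)
        h_m = rng.integers(0, 2, 3).astype(float)
        h_c = rng.integers(0, 2, 3).astype(float)
        _, cov = mcrbm_conditional_gaussian(p, h_m, h_c)
        assert np.allclose(cov, cov.T)
        assert np.linalg.eigvalsh(cov).min() > 0

    def test_pd_for_every_reachable_precision_state(self):
        p = _random_params(np.random.default_rng(2), nc=8, nf=10)
        for h_c in all_binary_vectors(8):
            _, cov = mcrbm_conditional_gaussian(p, np.zeros(3), h_c)
            assert np.linalg.eigvalsh(cov).min() > 0

    def test_sampler_matches_analytic_moments(self):
        rng = np.random.default_rng(3)
        p = _random_params(rng, d=3, scale=0.4)
        h_m = np.array([1.0, 0.0, 1.0])
        h_c = np.array([1.0, 1.0, 0.0])
        mean, cov = mcrbm_conditional_gaussian(p, h_m, h_c)
        draws = sample_visible_given_latents(p, h_m, h_c, rng, size=20_000)
        assert np.abs(draws.mean(axis=0) - mean).max() < 4 * np.sqrt(cov.max() / 20_000) * 3
        emp_cov = np.cov(draws.T)
        assert np.abs(emp_cov - cov).max() < 0.1

    def test_positive_pooling_entries_rejected(self):
        rng = np.random.default_rng(4)
        with pytest.raises(ValueError, match="nonpositive"):
            McRBMParams(
                W=np.zeros((3, 2)), a=np.zeros(3), b_m=np.zeros(2),
                C=np.zeros((3, 4)), P=np.abs(rng.standard_normal((4, 2))),
                b_c=np.zeros(2),
            )

    def test_latent_length_mismatch_rejected(self):
        p = _random_params(np.random.default_rng(5))
        with pytest.raises(ValueError):
            mcrbm_conditional_gaussian(p, np.zeros(4), np.zeros(3))


class TestFreeEnergy:
    def test_matches_latent_enumeration(self):
        # F(v) = -log sum over all latent configurations of exp(-E)
        rng = np.random.default_rng(6)
        p = _random_params(rng, d=3, nm=2, nf=4, nc=2)
        v = rng.standard_normal(3)
        terms = [
            -_energy(p, v, hm, hc)
            for hm in all_binary_vectors(2)
            for hc in all_binary_vectors(2)
        ]
        assert free_energy(p, v)[0] == pytest.approx(-logsumexp(terms), rel=1e-10)

    def test_gradient_matches_finite_differences(self):
        rng = np.random.default_rng(7)
        p = _random_params(rng, d=4)
        v = rng.standard_normal(4)
        g = free_energy_grad(p, v)[0]
        eps = 1e-6
        for i in range(4):
            vp, vm = v.copy(), v.copy()
            vp[i] += eps
            vm[i] -= eps
            num = (free_energy(p, vp)[0] - free_energy(p, vm)[0]) / (2 * eps)
            assert g[i] == pytest.approx(num, rel=1e-5, abs=1e-7)

    def test_unit_conditionals_consistent_with_energy(self):
        # p(h_m_j=1|v) and p(h_c_k=1|v) from the analytic sigmoids match
        # Boltzmann ratios of the enumerated energy
        rng = np.random.default_rng(8)
        p = _random_params(rng, d=3, nm=2, nf=4, nc=2)
        v = rng.standard_normal(3)
        hms, hcs = all_binary_vectors(2), all_binary_vectors(2)
        w = np.array([[np.exp(-_energy(p, v, hm, hc)) for hc in hcs] for hm in hms])
        w /= w.sum()
        pm_brute = np.array([w[hms[:, j] == 1].sum() for j in range(2)])
        pc_brute = np.array([w[:, hcs[:, k] == 1].sum() for k in range(2)])
        assert np.allclose(mean_unit_probs(p, v), pm_brute, atol=1e-10)
        assert np.allclose(precision_unit_probs(p, v), pc_brute, atol=1e-10)


class TestTraining:
    def _clusters(self, rng, n=200):
        mu = np.full(6, 1.2)
        X = np.vstack([
            mu + 0.3 * rng.standard_normal((n, 6)),
            -mu + 0.3 * rng.standard_normal((n, 6)),
        ])
        return (X - X.mean(0)) / X.std(0)

    @pytest.mark.parametrize("neg_phase", ["hmc", "gibbs"])
    def test_two_cluster_modes_recovered(self, neg_phase):
        X = self._clusters(np.random.default_rng(0))
        cfg = TrainConfig(
            n_hidden=4, n_factors=8, n_precision=4, epochs=150,
            learning_rate=2e-3, seed=1, neg_phase=neg_phase,
        )
        params, trace = train_mcrbm(X, cfg)
        census = mode_census(infer_states(params, X))
        assert census["fraction"].head(2).sum() > 0.9
        assert trace[-1] < trace[0]

    def test_seed_reproducibility(self):
        X = self._clusters(np.random.default_rng(1), n=60)
        cfg = TrainConfig(n_hidden=3, n_factors=6, n_precision=3, epochs=10, seed=3)
        p1, _ = train_mcrbm(X, cfg)
        p2, _ = train_mcrbm(X, cfg)
        assert np.array_equal(p1.W, p2.W) and np.array_equal(p1.C, p2.C)

    def test_time_shuffling_destroys_stimulus_information(self):
        # stimulus-locked data vs the same rows with time scrambled
        # relative to the labels: the intact model's states carry more
        # stimulus NMI
        rng = np.random.default_rng(2)
        labels = np.repeat(np.arange(4), 100)
        patterns = rng.standard_normal((4, 6)) * 1.5
        X = patterns[labels] + 0.4 * rng.standard_normal((400, 6))
        X = (X - X.mean(0)) / X.std(0)
        shuffled = X[rng.permutation(400)]
        cfg = TrainConfig(n_hidden=4, n_factors=8, n_precision=4, epochs=80,
                          learning_rate=2e-3, seed=5)
        p_int, _ = train_mcrbm(X, cfg)
        p_shuf, _ = train_mcrbm(shuffled, cfg)
        nmi_int = normalized_mi(labels, infer_states(p_int, X).state_id)
        nmi_shuf = normalized_mi(labels, infer_states(p_shuf, shuffled).state_id)
        assert nmi_int > nmi_shuf

    def test_pooling_stays_nonpositive_through_training(self):
        X = self._clusters(np.random.default_rng(3), n=60)
        cfg = TrainConfig(n_hidden=3, n_factors=6, n_precision=3, epochs=15, seed=7)
        params, _ = train_mcrbm(X, cfg)
        assert (params.P <= 0).all()

    def test_init_pooling_covers_all_factors(self):
        cfg = TrainConfig(n_hidden=4, n_factors=10, n_precision=3)
        p = init_mcrbm(5, cfg, np.random.default_rng(0))
        assert (p.P.sum(axis=1) < 0).all()  # every factor pooled somewhere
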