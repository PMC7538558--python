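"""Mean-covariance restricted Boltzmann machine (mcRBM).

A third-order factored energy model over real-valued visibles v with two
sets of binary latents: mean units h_m (modeling the conditional mean,
as in a Gaussian RBM) and precision units h_c (modeling the conditional
covariance through factor loadings C pooled by a nonpositive matrix P):

    E(v, h_m, h_c) = 1/2 v'v - a'v - v'W h_m - b_m'h_m - b_c'h_c
                     - 1/2 sum_{f,k} P_{fk} h_c_k (C_f . v)^2

With P <= 0 elementwise, conditioning on any binary (h_m, h_c) leaves v
exactly jointly Gaussian with positive-definite precision

    Lambda(h_c) = I - C diag(P h_c) C'

and mean Lambda^{-1}(a + W h_m).  Every binary latent vector therefore
indexes one Gaussian mode of the visible distribution, which is what
makes the model suited to discovering stimulus-locked modes in
population firing rates.

Training is contrastive divergence; the negative phase samples visibles
either by hybrid Monte Carlo on the marginal free energy (latents
integrated out) or by one block-Gibbs sweep (sample latents, then the
exact conditional Gaussian).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.linalg import cho_factor, cho_solve, cholesky
from scipy.special import expit

from .rbm import TrainConfig, all_binary_vectors

__all__ = [
    "McRBMParams",
    "mean_unit_probs",
    "precision_unit_probs",
    "mcrbm_conditional_gaussian",
    "sample_visible_given_latents",
    "free_energy",
    "free_energy_grad",
    "train_mcrbm",
    "TrainingDivergence",
]


class TrainingDivergence(RuntimeError):
    """Raised when training explodes; carries the last stable parameters."""

    def __init__(self, message: str, last_params: "McRBMParams | None" = None):
        super().__init__(message)
        self.last_params = last_params


@dataclass
class McRBMParams:
    # mean part
    W: np.ndarray  # (n_visible, n_mean)
    a: np.ndarray  # (n_visible,)
    b_m: np.ndarray  # (n_mean,)
    # covariance part
    C: np.ndarray  # (n_visible, n_factors)
    P: np.ndarray  # (n_factors, n_precision), entries <= 0
    b_c: np.ndarray  # (n_precision,)

    def __post_init__(self) -> None:
        for name in ("W", "a", "b_m", "C", "P", "b_c"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        d = self.a.shape[0]
        if self.W.shape[0] != d or self.C.shape[0] != d:
            raise ValueError("visible dimensions inconsistent")
        if self.W.shape[1] != self.b_m.shape[0]:
            raise ValueError("mean-unit dimensions inconsistent")
        if self.P.shape != (self.C.shape[1], self.b_c.shape[0]):
            raise ValueError("factor/precision dimensions inconsistent")
        if (self.P > 1e-12).any():
            raise ValueError("pooling matrix P must be nonpositive")

    @property
    def n_visible(self) -> int:
        return self.a.shape[0]

    @property
    def n_mean(self) -> int:
        return self.b_m.shape[0]

    @property
    def n_factors(self) -> int:
        return self.C.shape[1]

    @property
    def n_precision(self) -> int:
        return self.b_c.shape[0]


def mean_unit_probs(params: McRBMParams, v: np.ndarray) -> np.ndarray:
    """p(h_m_j = 1 | v); batched over leading axes."""
    return expit(params.b_m + np.asarray(v, dtype=float) @ params.W)


def precision_unit_probs(params: McRBMParams, v: np.ndarray) -> np.ndarray:
    """p(h_c_k = 1 | v); drive is 1/2 P'(C'v)^2 + b_c (nonpositive pooling)."""
    f = (np.asarray(v, dtype=float) @ params.C) ** 2
    return expit(params.b_c + 0.5 * f @ params.P)


def _precision_matrix(params: McRBMParams, h_precision: np.ndarray) -> np.ndarray:
    s = -(params.P @ np.asarray(h_precision, dtype=float))  # (F,), >= 0
    return np.eye(params.n_visible) + (params.C * s) @ params.C.T


def mcrbm_conditional_gaussian(
    params: McRBMParams, h_mean: np.ndarray, h_precision: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Exact Gaussian conditional of v given binary latents.

    Returns (mean, covariance); the covariance is the inverse of the
    identity-regularized precision I - C diag(P h_c) C', symmetric
    positive definite for every binary h_c because P <= 0.
    """
    h_mean = np.asarray(h_mean, dtype=float)
    h_precision = np.asarray(h_precision, dtype=float)
    if h_mean.shape != (params.n_mean,) or h_precision.shape != (params.n_precision,):
        raise ValueError("latent vector lengths do not match parameters")
    lam = _precision_matrix(params, h_precision)
    L = cho_factor(lam, lower=True)
    cov = cho_solve(L, np.eye(params.n_visible))
    cov = 0.5 * (cov + cov.T)
    mean = cho_solve(L, params.a + params.W @ h_mean)
    return mean, cov


def sample_visible_given_latents(
    params: McRBMParams,
    h_mean: np.ndarray,
    h_precision: np.ndarray,
    rng: np.random.Generator,
    size: int = 1,
) -> np.ndarray:
    """Draw v ~ N(mean, precision^{-1}) without forming the covariance."""
    lam = _precision_matrix(params, np.asarray(h_precision, dtype=float))
    U = cholesky(lam, lower=False)  # lam = U'U
    mean = cho_solve((U, False), params.a + params.W @ np.asarray(h_mean, dtype=float))
    z = rng.standard_normal((size, params.n_visible))
    # solve U x = z  =>  cov(x) = lam^{-1}
    x = np.linalg.solve(U, z.T).T
    return mean + x


def free_energy(params: McRBMParams, v: np.ndarray) -> np.ndarray:
    """-log sum_{h_m,h_c} exp(-E(v, h_m, h_c)) up to a constant; batched."""
    v = np.atleast_2d(np.asarray(v, dtype=float))
    quad = 0.5 * np.sum(v**2, axis=1) - v @ params.a
    mean_term = np.logaddexp(0.0, params.b_m + v @ params.W).sum(axis=1)
    fdrive = params.b_c + 0.5 * ((v @ params.C) ** 2) @ params.P
    cov_term = np.logaddexp(0.0, fdrive).sum(axis=1)
    return quad - mean_term - cov_term


def free_energy_grad(params: McRBMParams, v: np.ndarray) -> np.ndarray:
    v = np.atleast_2d(np.asarray(v, dtype=float))
    p_m = mean_unit_probs(params, v)
    cv = v @ params.C  # (m, F)
    p_c = expit(params.b_c + 0.5 * (cv**2) @ params.P)
    return v - params.a - p_m @ params.W.T - (cv * (p_c @ params.P.T)) @ params.C.T


def _neg_stats_v(params: McRBMParams, v: np.ndarray):
    """Rao-Blackwellized sufficient statistics -dE/dtheta averaged at v."""
    m = v.shape[0]
    p_m = mean_unit_probs(params, v)
    cv = v @ params.C
    p_c = expit(params.b_c + 0.5 * (cv**2) @ params.P)
    sW = v.T @ p_m / m
    sa = v.mean(axis=0)
    sbm = p_m.mean(axis=0)
    sbc = p_c.mean(axis=0)
    sC = v.T @ (cv * (p_c @ params.P.T)) / m
    sP = 0.5 * (cv**2).T @ p_c / m
    return sW, sa, sbm, sbc, sC, sP


def _gibbs_negative(params, v0, rng):
    h_m = (rng.random((v0.shape[0], params.n_mean)) < mean_unit_probs(params, v0)).astype(float)
    h_c = (
        rng.random((v0.shape[0], params.n_precision)) < precision_unit_probs(params, v0)
    ).astype(float)
    out = np.empty_like(v0)
    for i in range(v0.shape[0]):
        out[i] = sample_visible_given_latents(params, h_m[i], h_c[i], rng, size=1)[0]
    return out


def _hmc_negative(params, v0, rng, n_steps, step_size):
    """One HMC trajectory per chain on the marginal free energy.

    Returns (samples, acceptance rate, adapted step size).
    """
    v = v0.copy()
    p = rng.standard_normal(v.shape)
    e0 = free_energy(params, v) + 0.5 * np.sum(p**2, axis=1)
    p = p - 0.5 * step_size * free_energy_grad(params, v)
    x = v + step_size * p
    for _ in range(n_steps - 1):
        p = p - step_size * free_energy_grad(params, x)
        x = x + step_size * p
    p = p - 0.5 * step_size * free_energy_grad(params, x)
    e1 = free_energy(params, x) + 0.5 * np.sum(p**2, axis=1)
    accept = rng.random(v.shape[0]) < np.exp(np.clip(e0 - e1, -50, 50))
    v[accept] = x[accept]
    rate = accept.mean()
    new_step = step_size * (1.02 if rate > 0.9 else 0.98)
    return v, rate, float(np.clip(new_step, 1e-4, 0.5))


def init_mcrbm(n_visible: int, config: TrainConfig, rng: np.random.Generator) -> McRBMParams:
    W = config.init_sigma * rng.standard_normal((n_visible, config.n_hidden))
    C = config.init_sigma * rng.standard_normal((n_visible, config.n_factors))
    # block pooling: each precision unit pools a contiguous group of factors
    P = np.zeros((config.n_factors, config.n_precision))
    group = int(np.ceil(config.n_factors / config.n_precision))
    for k in range(config.n_precision):
        P[k * group : (k + 1) * group, k] = -1.0
    return McRBMParams(
        W=W,
        a=np.zeros(n_visible),
        b_m=np.zeros(config.n_hidden),
        C=C,
        P=P,
        b_c=np.full(config.n_precision, 2.0),
    )


def train_mcrbm(
    data: np.ndarray,
    config: TrainConfig,
) -> tuple[McRBMParams, list[float]]:
    """CD training of an mcRBM on standardized data (rows = samples).

    The negative phase starts at the data (CD-1 style) and uses either
    HMC on the marginal free energy (``config.neg_phase == "hmc"``) or
    one block-Gibbs sweep.  Deterministic under ``config.seed``; raises
    :class:`TrainingDivergence` (carrying the last stable parameters) if
    the reconstruction error explodes.
    """
    data = np.asarray(data, dtype=float)
    if data.ndim != 2:
        raise ValueError("data must be 2-D (samples x visibles)")
    if config.neg_phase not in ("hmc", "gibbs"):
        raise ValueError("neg_phase must be 'hmc' or 'gibbs'")
    rng = np.random.default_rng(config.seed)
    params = init_mcrbm(data.shape[1], config, rng)
    vel = {k: 0.0 for k in ("W", "a", "b_m", "b_c", "C", "P")}
    step_size = config.hmc_step_size
    trace: list[float] = []
    n = data.shape[0]
    last_stable = params
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        for start in range(0, n, config.batch_size):
            batch = data[order[start : start + config.batch_size]]
            pos = _neg_stats_v(params, batch)
            if config.neg_phase == "hmc":
                vneg, _, step_size = _hmc_negative(
                    params, batch, rng, config.hmc_steps, step_size
                )
            else:
                vneg = _gibbs_negative(params, batch, rng)
            neg = _neg_stats_v(params, vneg)
            grads = dict(zip(("W", "a", "b_m", "b_c", "C", "P"), (p - q for p, q in zip(pos, neg))))
            grads["W"] -= config.weight_decay * params.W
            grads["C"] -= config.weight_decay * params.C
            updates = {}
            for k, g in grads.items():
                vel[k] = config.momentum * vel[k] + config.learning_rate * g
                updates[k] = getattr(params, k) + vel[k]
            updates["P"] = np.minimum(updates["P"], 0.0)  # keep pooling nonpositive
            params = McRBMParams(**updates)
            if not all(np.isfinite(getattr(params, k)).all() for k in updates):
                raise TrainingDivergence(
                    f"non-finite parameters at epoch {epoch}", last_params=last_stable
                )
        # reconstruction error through the latent means, on a fixed subsample
        sub = data[: min(256, n)]
        p_m = mean_unit_probs(params, sub)
        p_c = precision_unit_probs(params, sub)
        recon = np.empty_like(sub)
        for i in range(sub.shape[0]):
            lam = _precision_matrix(params, (p_c[i] >= 0.5).astype(float))
            recon[i] = np.linalg.solve(lam, params.a + params.W @ (p_m[i] >= 0.5).astype(float))
        err = float(np.mean((recon - sub) ** 2))
        trace.append(err)
        if not np.isfinite(err) or err > 1e6:
            raise TrainingDivergence(
                f"reconstruction error diverged at epoch {epoch}: {err:.3g}",
                last_params=last_stable,
            )
        last_stable = params
    return params, trace


def enumerate_precision_states(params: McRBMParams) -> np.ndarray:
    """All reachable precision-unit configurations (for PD audits)."""
    return all_binary_vectors(params.n_precision)
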