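"""Restricted Boltzmann machines with binary or Gaussian visible units.

Energy of a joint configuration (binary visibles):

    E(v, h) = -a'v - b'h - v'W h

and with real-valued visibles (independent unit-variance Gaussian noise):

    E(v, h) = 1/2 ||v - a||^2 - b'h - v'W h

with P(v, h) proportional to exp(-E).  Hidden units are binary in both
cases and conditionally independent given the visibles; training is by
contrastive divergence (CD-k) with momentum and weight decay.

Exact small-model quantities (log-likelihood, log-likelihood gradient)
are computed by brute-force enumeration over hidden configurations (for
Gaussian visibles the integral over v is analytic per hidden vector);
they serve as oracles for the stochastic training code.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from itertools import product

import numpy as np
from scipy.special import expit, logsumexp

__all__ = [
    "RBMParams",
    "TrainConfig",
    "energy",
    "hidden_given_visible",
    "visible_given_hidden",
    "sample_hidden",
    "sample_visible",
    "cd_update",
    "train_rbm",
    "exact_loglik",
    "exact_loglik_grad",
    "all_binary_vectors",
]

_ENUM_LIMIT = 20  # max units enumerated on one side (2^20 configurations)


@dataclass
class RBMParams:
    W: np.ndarray  # (n_visible, n_hidden)
    a: np.ndarray  # visible biases
    b: np.ndarray  # hidden biases
    visible_kind: str = "gaussian"  # or "binary"

    def __post_init__(self) -> None:
        self.W = np.asarray(self.W, dtype=float)
        self.a = np.asarray(self.a, dtype=float)
        self.b = np.asarray(self.b, dtype=float)
        if self.W.shape != (self.a.shape[0], self.b.shape[0]):
            raise ValueError("parameter shapes are inconsistent")
        if self.visible_kind not in ("binary", "gaussian"):
            raise ValueError("visible_kind must be 'binary' or 'gaussian'")
        for arr in (self.W, self.a, self.b):
            if not np.isfinite(arr).all():
                raise ValueError("parameters must be finite")

    @property
    def n_visible(self) -> int:
        return self.a.shape[0]

    @property
    def n_hidden(self) -> int:
        return self.b.shape[0]


@dataclass
class TrainConfig:
    """Contrastive-divergence training hyperparameters.

    Defaults: CD-1, learning rate 1e-3, momentum 0.9, weight decay 1e-4,
    batch size 64.  ``n_factors``/``n_precision`` apply to the
    mean-covariance variant only; ``neg_phase`` selects the negative-
    phase sampler there ("hmc" or "gibbs").
    """

    n_hidden: int = 16
    n_factors: int = 64
    n_precision: int = 16
    cd_k: int = 1
    learning_rate: float = 1e-3
    momentum: float = 0.9
    weight_decay: float = 1e-4
    batch_size: int = 64
    epochs: int = 50
    seed: int = 0
    neg_phase: str = "hmc"
    hmc_steps: int = 20
    hmc_step_size: float = 0.05
    init_sigma: float = 0.01

    def __post_init__(self) -> None:
        if min(self.n_hidden, self.cd_k, self.batch_size, self.epochs) < 1:
            raise ValueError("n_hidden, cd_k, batch_size and epochs must be positive")
        if self.learning_rate < 0 or self.weight_decay < 0 or not 0 <= self.momentum < 1:
            raise ValueError("invalid optimizer settings")


def energy(params: RBMParams, v: np.ndarray, h: np.ndarray) -> float:
    v = np.asarray(v, dtype=float)
    h = np.asarray(h, dtype=float)
    if v.shape != (params.n_visible,) or h.shape != (params.n_hidden,):
        raise ValueError("v/h dimensions do not match parameters")
    inter = -params.b @ h - v @ params.W @ h
    if params.visible_kind == "binary":
        return float(-params.a @ v + inter)
    return float(0.5 * np.sum((v - params.a) ** 2) + inter)


def hidden_given_visible(params: RBMParams, v: np.ndarray) -> np.ndarray:
    """p(h_j = 1 | v), independent across hidden units.  Accepts batches."""
    v = np.asarray(v, dtype=float)
    if v.shape[-1] != params.n_visible:
        raise ValueError("v dimension does not match parameters")
    return expit(params.b + v @ params.W)


def visible_given_hidden(params: RBMParams, h: np.ndarray) -> np.ndarray:
    """Conditional parameters of v given h.

    Gaussian visibles: the mean vector (unit variance per coordinate).
    Binary visibles: activation probabilities.
    """
    h = np.asarray(h, dtype=float)
    if h.shape[-1] != params.n_hidden:
        raise ValueError("h dimension does not match parameters")
    act = params.a + h @ params.W.T
    if params.visible_kind == "binary":
        return expit(act)
    return act


def sample_hidden(params: RBMParams, v: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    p = hidden_given_visible(params, v)
    return (rng.random(p.shape) < p).astype(float)


def sample_visible(params: RBMParams, h: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    out = visible_given_hidden(params, h)
    if params.visible_kind == "binary":
        return (rng.random(out.shape) < out).astype(float)
    return out + rng.standard_normal(out.shape)


@dataclass
class _Momentum:
    dW: np.ndarray
    da: np.ndarray
    db: np.ndarray

    @staticmethod
    def zeros(params: RBMParams) -> "_Momentum":
        return _Momentum(np.zeros_like(params.W), np.zeros_like(params.a), np.zeros_like(params.b))


def cd_update(
    params: RBMParams,
    minibatch: np.ndarray,
    config: TrainConfig,
    rng: np.random.Generator,
    state: _Momentum | None = None,
) -> tuple[RBMParams, _Momentum]:
    """One CD-k parameter update on a minibatch (rows are visible vectors).

    Positive statistics use hidden probabilities at the data; the
    negative phase runs k alternating Gibbs sweeps from the data.
    """
    v0 = np.asarray(minibatch, dtype=float)
    if v0.ndim != 2 or v0.shape[1] != params.n_visible:
        raise ValueError("minibatch rows must match the visible dimension")
    if state is None:
        state = _Momentum.zeros(params)
    m = v0.shape[0]
    ph0 = hidden_given_visible(params, v0)
    h = (rng.random(ph0.shape) < ph0).astype(float)
    vk = v0
    for _ in range(config.cd_k):
        vk = sample_visible(params, h, rng)
        phk = hidden_given_visible(params, vk)
        h = (rng.random(phk.shape) < phk).astype(float)
    gW = (v0.T @ ph0 - vk.T @ phk) / m - config.weight_decay * params.W
    ga = (v0 - vk).mean(axis=0)
    gb = (ph0 - phk).mean(axis=0)
    dW = config.momentum * state.dW + config.learning_rate * gW
    da = config.momentum * state.da + config.learning_rate * ga
    db = config.momentum * state.db + config.learning_rate * gb
    for arr in (params.W + dW, params.a + da, params.b + db):
        if not np.isfinite(arr).all():
            raise FloatingPointError("CD update produced non-finite parameters")
    new = replace(params, W=params.W + dW, a=params.a + da, b=params.b + db)
    return new, _Momentum(dW, da, db)


def init_params(
    n_visible: int, config: TrainConfig, rng: np.random.Generator, visible_kind: str = "gaussian"
) -> RBMParams:
    W = config.init_sigma * rng.standard_normal((n_visible, config.n_hidden))
    return RBMParams(W, np.zeros(n_visible), np.zeros(config.n_hidden), visible_kind)


def train_rbm(
    data: np.ndarray,
    config: TrainConfig,
    visible_kind: str = "gaussian",
) -> tuple[RBMParams, list[float]]:
    """CD training; returns parameters and a per-epoch reconstruction-error trace."""
    data = np.asarray(data, dtype=float)
    rng = np.random.default_rng(config.seed)
    params = init_params(data.shape[1], config, rng, visible_kind)
    state = _Momentum.zeros(params)
    trace = []
    n = data.shape[0]
    for _ in range(config.epochs):
        order = rng.permutation(n)
        for start in range(0, n, config.batch_size):
            batch = data[order[start : start + config.batch_size]]
            params, state = cd_update(params, batch, config, rng, state)
        recon = visible_given_hidden(params, hidden_given_visible(params, data))
        trace.append(float(np.mean((recon - data) ** 2)))
    return params, trace


def all_binary_vectors(n: int) -> np.ndarray:
    if n > _ENUM_LIMIT:
        raise ValueError(f"enumeration limited to {_ENUM_LIMIT} units (got {n})")
    return np.array(list(product((0.0, 1.0), repeat=n)))


def _log_unnorm_pv(params: RBMParams, v: np.ndarray) -> np.ndarray:
    """log sum_h exp(-E(v, h)) for rows of v (the negative free energy)."""
    act = params.b + v @ params.W
    soft = np.logaddexp(0.0, act).sum(axis=-1)
    if params.visible_kind == "binary":
        return v @ params.a + soft
    return -0.5 * np.sum((v - params.a) ** 2, axis=-1) + soft


def log_partition(params: RBMParams) -> float:
    """Exact log Z by enumeration (hidden side; for binary models the
    visible side is used when smaller)."""
    if params.visible_kind == "binary":
        if params.n_visible <= params.n_hidden:
            vs = all_binary_vectors(params.n_visible)
            return float(logsumexp(_log_unnorm_pv(params, vs)))
        hs = all_binary_vectors(params.n_hidden)
        act = params.a + hs @ params.W.T
        return float(
            logsumexp(hs @ params.b + np.logaddexp(0.0, act).sum(axis=-1))
        )
    hs = all_binary_vectors(params.n_hidden)
    wh = hs @ params.W.T  # (2^nh, d)
    expo = hs @ params.b + wh @ params.a + 0.5 * np.sum(wh**2, axis=-1)
    return float(
        0.5 * params.n_visible * np.log(2 * np.pi) + logsumexp(expo)
    )


def exact_loglik(params: RBMParams, data: np.ndarray) -> float:
    """Average log P(v) with the partition function computed exactly.

    Feasible only for small hidden layers (enumeration over all hidden
    configurations; Gaussian visibles are integrated analytically).
    """
    data = np.atleast_2d(np.asarray(data, dtype=float))
    logz = log_partition(params)
    return float(np.mean(_log_unnorm_pv(params, data)) - logz)


def exact_loglik_grad(params: RBMParams, data: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Exact gradient of the average log-likelihood (binary visibles).

    Data term minus exact model expectations of (v h', v, h), computed
    by enumerating the joint configuration space.  Oracle for CD.
    """
    if params.visible_kind != "binary":
        raise ValueError("exact gradient oracle implemented for binary visibles")
    data = np.atleast_2d(np.asarray(data, dtype=float))
    ph = hidden_given_visible(params, data)
    pos_W = data.T @ ph / data.shape[0]
    pos_a = data.mean(axis=0)
    pos_b = ph.mean(axis=0)

    vs = all_binary_vectors(params.n_visible)
    logp = _log_unnorm_pv(params, vs)
    p = np.exp(logp - logsumexp(logp))  # P(v)
    ph_all = hidden_given_visible(params, vs)
    neg_W = vs.T @ (ph_all * p[:, None])
    neg_a = p @ vs
    neg_b = p @ ph_all
    return pos_W - neg_W, pos_a - neg_a, pos_b - neg_b
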