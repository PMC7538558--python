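"""Conditional restricted Boltzmann machine (cRBM) for population dynamics.

A Gaussian-visible RBM whose biases are conditioned on a window of past
visible frames: with history frames v_{t-k*s} (k = 1..n, spacing s bins)
the effective biases are

    a_hat(t) = a + sum_k A_k v_{t-k*s}
    b_hat(t) = b + sum_k B_k' v_{t-k*s}

and the per-frame energy is the static Gaussian-RBM energy with (a_hat,
b_hat) in place of (a, b).  Because the new connections act purely as
dynamic biases, contrastive divergence is unchanged apart from gradient
terms for the autoregressive weights A_k and the history-to-hidden
weights B_k.

The history span is tied to the stimulus by the counterphase rule: the
most delayed layer should see activity evoked half a temporal period
earlier than the present frame, so for a periodic stimulus the spacing
is derived from the period (with a tolerance, since the half period need
not be an integer multiple of the order).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.special import expit

from .rbm import RBMParams, TrainConfig, all_binary_vectors, exact_loglik

__all__ = [
    "CRBMParams",
    "dynamic_biases",
    "counterphase_spacing",
    "make_history_dataset",
    "hidden_probs",
    "train_crbm",
    "crbm_exact_loglik",
]


@dataclass
class CRBMParams:
    W: np.ndarray  # (n_visible, n_hidden) static weights
    a: np.ndarray  # (n_visible,)
    b: np.ndarray  # (n_hidden,)
    A: np.ndarray  # (order, n_visible, n_visible): A[k-1] links v_{t-k*s} -> v_t
    B: np.ndarray  # (order, n_visible, n_hidden): B[k-1] links v_{t-k*s} -> h_t
    order: int
    frame_spacing: int

    def __post_init__(self) -> None:
        for name in ("W", "a", "b", "A", "B"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        d, nh = self.W.shape
        if self.a.shape != (d,) or self.b.shape != (nh,):
            raise ValueError("bias shapes inconsistent with W")
        if self.order < 1:
            raise ValueError("order must be >= 1")
        if self.A.shape != (self.order, d, d) or self.B.shape != (self.order, d, nh):
            raise ValueError("A/B shapes inconsistent with order and W")
        if self.frame_spacing < 1:
            raise ValueError("frame_spacing must be >= 1")

    @property
    def n_visible(self) -> int:
        return self.W.shape[0]

    @property
    def n_hidden(self) -> int:
        return self.W.shape[1]

    @property
    def span_bins(self) -> int:
        """Bins covered by the most delayed layer."""
        return self.order * self.frame_spacing


def counterphase_spacing(
    order: int,
    stimulus_period_s: float,
    bin_width_s: float,
    tol: float = 0.25,
) -> int:
    """Spacing (bins) so the most delayed layer sits ~half a period back.

    Rounds order * spacing to the nearest achievable match of the half
    period; raises if no integer spacing lands within ``tol`` (relative)
    of the half period, reporting the nearest feasible spacing.
    """
    if order < 1 or stimulus_period_s <= 0 or bin_width_s <= 0:
        raise ValueError("order, period and bin width must be positive")
    half_bins = stimulus_period_s / (2.0 * bin_width_s)
    spacing = max(1, int(round(half_bins / order)))
    achieved = order * spacing
    if abs(achieved - half_bins) > tol * half_bins:
        raise ValueError(
            f"counterphase rule unsatisfiable: order {order} x spacing {spacing} "
            f"= {achieved} bins vs half period {half_bins:.2f} bins "
            f"(> {tol:.0%} off); nearest feasible spacing is {spacing}"
        )
    return spacing


def dynamic_biases(params: CRBMParams, history: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Effective (visible, hidden) biases given a history window.

    ``history`` has shape (order, n_visible) or (m, order, n_visible);
    index k-1 holds v_{t-k*spacing} (nearest delay first).
    """
    history = np.asarray(history, dtype=float)
    squeeze = history.ndim == 2
    if squeeze:
        history = history[None]
    if history.shape[1:] != (params.order, params.n_visible):
        raise ValueError(
            f"history must have shape (order={params.order}, n_visible={params.n_visible})"
        )
    a_hat = params.a + np.einsum("kpq,mkq->mp", params.A, history)
    b_hat = params.b + np.einsum("kqj,mkq->mj", params.B, history)
    if squeeze:
        return a_hat[0], b_hat[0]
    return a_hat, b_hat


def make_history_dataset(
    V: np.ndarray, order: int, spacing: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Slice (T, d) standardized rates into (present, history, t_index).

    history[m, k-1] = V[t_m - k*spacing]; only frames with a full
    history are kept.
    """
    V = np.asarray(V, dtype=float)
    T = V.shape[0]
    t0 = order * spacing
    if T <= t0:
        raise ValueError("not enough time bins to form any history window")
    t_idx = np.arange(t0, T)
    present = V[t_idx]
    hist = np.stack([V[t_idx - k * spacing] for k in range(1, order + 1)], axis=1)
    return present, hist, t_idx


def hidden_probs(params: CRBMParams, v: np.ndarray, history: np.ndarray) -> np.ndarray:
    """p(h=1 | v, history) with the dynamic hidden bias."""
    v = np.asarray(v, dtype=float)
    _, b_hat = dynamic_biases(params, history)
    return expit(b_hat + v @ params.W)


def init_crbm(
    n_visible: int, order: int, spacing: int, config: TrainConfig, rng: np.random.Generator
) -> CRBMParams:
    return CRBMParams(
        W=config.init_sigma * rng.standard_normal((n_visible, config.n_hidden)),
        a=np.zeros(n_visible),
        b=np.zeros(config.n_hidden),
        A=np.zeros((order, n_visible, n_visible)),
        B=np.zeros((order, n_visible, config.n_hidden)),
        order=order,
        frame_spacing=spacing,
    )


def train_crbm(
    V: np.ndarray,
    order: int = 12,
    *,
    frame_spacing: int | None = None,
    stimulus_period_s: float | None = None,
    bin_width_s: float | None = None,
    config: TrainConfig | None = None,
) -> tuple[CRBMParams, list[float]]:
    """CD-k training of a Gaussian-visible cRBM on standardized rates.

    ``V`` is (time, neurons).  The spacing is either given explicitly or
    derived from the stimulus period via the counterphase rule.  Returns
    the parameters and a per-epoch reconstruction-error trace.
    """
    config = config or TrainConfig()
    if frame_spacing is None:
        if stimulus_period_s is None or bin_width_s is None:
            raise ValueError(
                "provide frame_spacing, or stimulus_period_s + bin_width_s for the "
                "counterphase rule"
            )
        frame_spacing = counterphase_spacing(order, stimulus_period_s, bin_width_s)
    present, hist, _ = make_history_dataset(V, order, frame_spacing)
    rng = np.random.default_rng(config.seed)
    params = init_crbm(present.shape[1], order, frame_spacing, config, rng)
    vel = {k: 0.0 for k in ("W", "a", "b", "A", "B")}
    trace: list[float] = []
    n = present.shape[0]
    for _ in range(config.epochs):
        order_idx = rng.permutation(n)
        for start in range(0, n, config.batch_size):
            sel = order_idx[start : start + config.batch_size]
            v0, hk = present[sel], hist[sel]
            m = v0.shape[0]
            a_hat, b_hat = dynamic_biases(params, hk)
            ph0 = expit(b_hat + v0 @ params.W)
            h = (rng.random(ph0.shape) < ph0).astype(float)
            vk = v0
            for _k in range(config.cd_k):
                vk = a_hat + h @ params.W.T + rng.standard_normal(v0.shape)
                phk = expit(b_hat + vk @ params.W)
                h = (rng.random(phk.shape) < phk).astype(float)
            gW = (v0.T @ ph0 - vk.T @ phk) / m - config.weight_decay * params.W
            ga = (v0 - vk).mean(axis=0)
            gb = (ph0 - phk).mean(axis=0)
            gA = np.einsum("mp,mkq->kpq", v0 - vk, hk) / m - config.weight_decay * params.A
            gB = np.einsum("mkq,mj->kqj", hk, ph0 - phk) / m - config.weight_decay * params.B
            for key, g in zip(("W", "a", "b", "A", "B"), (gW, ga, gb, gA, gB)):
                vel[key] = config.momentum * vel[key] + config.learning_rate * g
            params = replace(
                params,
                W=params.W + vel["W"],
                a=params.a + vel["a"],
                b=params.b + vel["b"],
                A=params.A + vel["A"],
                B=params.B + vel["B"],
            )
            if not np.isfinite(params.W).all():
                raise FloatingPointError("cRBM training produced non-finite weights")
        a_hat, b_hat = dynamic_biases(params, hist)
        recon = a_hat + expit(b_hat + present @ params.W) @ params.W.T
        trace.append(float(np.mean((recon - present) ** 2)))
    return params, trace


def crbm_exact_loglik(params: CRBMParams, present: np.ndarray, history: np.ndarray) -> float:
    """Average exact log p(v_t | history_t) by hidden-state enumeration.

    Feasible for small hidden layers only; the Gaussian integral over v
    is analytic per hidden configuration, exactly as for the static
    Gaussian RBM but with per-sample dynamic biases.
    """
    present = np.atleast_2d(np.asarray(present, dtype=float))
    a_hat, b_hat = dynamic_biases(params, history)
    a_hat = np.atleast_2d(a_hat)
    b_hat = np.atleast_2d(b_hat)
    total = 0.0
    for v, a, b in zip(present, a_hat, b_hat):
        static = RBMParams(params.W, a, b, visible_kind="gaussian")
        total += exact_loglik(static, v[None, :])
    return total / present.shape[0]
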