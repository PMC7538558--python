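"""Firing-rate inference from spike trains.

The observation model is a log-Gaussian Cox process: spike counts in
small time bins are Poisson with intensity exp(g), where g follows a
Gaussian-process prior with a squared-exponential kernel over time.  The
MAP estimate of g is found per neuron by Newton iteration on the binned
Poisson likelihood (the Laplace-mode computation, in the numerically
stable B = I + W^{1/2} K W^{1/2} form), and the inferred rate is
exp(g)/bin_width, which is strictly positive.

The module also implements the neuron-selection filter used before
population modeling: neurons whose firing-rate derivative spans less
than a threshold (silent or tonic cells) are removed, and the remaining
rates are standardized per neuron to zero mean and unit variance, the
scale assumed by Gaussian-visible energy models.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve

__all__ = [
    "FiringRateMatrix",
    "SelectionReport",
    "Standardization",
    "bin_spikes",
    "lgcp_fit",
    "derivative_range",
    "select_active_neurons",
    "standardize",
]


@dataclass
class FiringRateMatrix:
    """Neurons x time-bins nonnegative firing rates (Hz)."""

    rates: np.ndarray  # (n_neurons, n_bins)
    bin_width_s: float
    neuron_ids: np.ndarray
    time_origin_s: float = 0.0

    def __post_init__(self) -> None:
        self.rates = np.asarray(self.rates, dtype=float)
        if self.rates.ndim != 2:
            raise ValueError("rates must be 2-D (neurons x bins)")
        if self.bin_width_s <= 0:
            raise ValueError("bin_width_s must be positive")
        if self.rates.size and self.rates.min() < 0:
            raise ValueError("rates must be nonnegative")
        self.neuron_ids = np.asarray(self.neuron_ids)
        if self.neuron_ids.shape[0] != self.rates.shape[0]:
            raise ValueError("neuron_ids must align with rate rows")

    @property
    def n_neurons(self) -> int:
        return self.rates.shape[0]

    @property
    def n_bins(self) -> int:
        return self.rates.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_bins * self.bin_width_s

    @property
    def times_s(self) -> np.ndarray:
        """Bin centers."""
        return self.time_origin_s + (np.arange(self.n_bins) + 0.5) * self.bin_width_s


@dataclass
class SelectionReport:
    kept_ids: np.ndarray
    dropped_ids: np.ndarray
    derivative_range: pd.Series  # indexed by neuron id, Hz/s
    threshold: float

    def to_frame(self) -> pd.DataFrame:
        kept = set(np.asarray(self.kept_ids).tolist())
        return pd.DataFrame(
            {
                "neuron_id": self.derivative_range.index,
                "derivative_range_hz_per_s": self.derivative_range.values,
                "kept": [i in kept for i in self.derivative_range.index],
                "threshold": self.threshold,
            }
        )


@dataclass
class Standardization:
    """Per-neuron mean/sd recorded so the transform can be inverted."""

    mean: np.ndarray
    sd: np.ndarray

    def apply(self, rates: np.ndarray) -> np.ndarray:
        return (rates - self.mean[:, None]) / self.sd[:, None]

    def invert(self, standardized: np.ndarray) -> np.ndarray:
        return standardized * self.sd[:, None] + self.mean[:, None]


def bin_spikes(spike_train_set, bin_width_s: float, n_bins: int | None = None) -> np.ndarray:
    """Count spikes per neuron in half-open bins [b*d, (b+1)*d).

    Spikes exactly on a bin boundary land in the later bin.  Total counts
    are conserved for any bin width.
    """
    if bin_width_s <= 0:
        raise ValueError("bin_width_s must be positive")
    if n_bins is None:
        n_bins = max(1, int(np.ceil(spike_train_set.duration_s / bin_width_s - 1e-9)))
    counts = np.zeros((len(spike_train_set.spikes), n_bins), dtype=int)
    total = sum(len(s) for s in spike_train_set.spikes)
    if total == 0:
        import warnings

        warnings.warn("spike set is empty; returning a zero count matrix", stacklevel=2)
        return counts
    for i, times in enumerate(spike_train_set.spikes):
        if len(times) == 0:
            continue
        idx = np.floor(np.asarray(times) / bin_width_s).astype(int)
        idx = np.clip(idx, 0, n_bins - 1)  # spike exactly at duration -> last bin
        np.add.at(counts[i], idx, 1)
    return counts


def _se_kernel(times: np.ndarray, lengthscale: float, variance: float) -> np.ndarray:
    d = times[:, None] - times[None, :]
    return variance * np.exp(-0.5 * (d / lengthscale) ** 2)


def _newton_map(y, K, mu, max_iter, tol):
    """MAP of a log-Gaussian Cox bin model; GPML Alg. 3.1 with backtracking.

    Parametrized through a = K^{-1}(f - mu) so the objective
    psi = 0.5 a'(f - mu) - sum(y f - exp(f)) is cheap to evaluate.
    """
    n = y.shape[0]
    f = np.full(n, mu) if np.isscalar(mu) else mu.copy()
    mu_vec = np.full(n, mu) if np.isscalar(mu) else mu
    a = np.zeros(n)

    def psi(a_vec, f_vec):
        return 0.5 * a_vec @ (f_vec - mu_vec) - (y @ f_vec - np.exp(f_vec).sum())

    obj = psi(a, f)
    for it in range(max_iter):
        w = np.exp(f)
        sqw = np.sqrt(w)
        B = np.eye(n) + sqw[:, None] * K * sqw[None, :]
        L = cho_factor(B, lower=True, check_finite=False)
        grad = y - w
        b = w * (f - mu_vec) + grad
        a_new = b - sqw * cho_solve(L, sqw * (K @ b), check_finite=False)
        # backtracking line search in a-space
        step = 1.0
        for _ in range(30):
            a_try = a + step * (a_new - a)
            f_try = mu_vec + K @ a_try
            obj_try = psi(a_try, f_try)
            if obj_try <= obj + 1e-12:
                break
            step *= 0.5
        else:
            raise RuntimeError(
                f"LGCP Newton line search failed at iteration {it} "
                f"(objective {obj:.6g}); no rate estimate returned"
            )
        delta = np.max(np.abs(f_try - f))
        a, f, obj = a_try, f_try, obj_try
        if delta < tol:
            return f
    raise RuntimeError(
        f"LGCP Newton did not converge within {max_iter} iterations "
        f"(last step {delta:.3g}); no rate estimate returned"
    )


def lgcp_fit(
    counts: np.ndarray,
    bin_width_s: float,
    *,
    kernel_lengthscale_s: float = 0.25,
    kernel_variance: float = 1.0,
    mean_log_rate: np.ndarray | float | None = None,
    neuron_ids: np.ndarray | None = None,
    max_iter: int = 100,
    tol: float = 1e-6,
    jitter: float = 1e-8,
) -> FiringRateMatrix:
    """MAP log-Gaussian Cox rate inference on binned counts.

    ``mean_log_rate`` is the prior mean of the log intensity in log-Hz
    (scalar, per-neuron array, or None to use each neuron's empirical
    mean rate).  The squared-exponential kernel operates on bin centers.
    """
    counts = np.asarray(counts)
    if counts.ndim != 2:
        raise ValueError("counts must be 2-D (neurons x bins)")
    if counts.size and counts.min() < 0:
        raise ValueError("counts must be nonnegative")
    if not np.issubdtype(counts.dtype, np.integer):
        if not np.allclose(counts, np.round(counts)):
            raise ValueError("counts must be integers")
        counts = np.round(counts).astype(int)
    n_neurons, n_bins = counts.shape
    if neuron_ids is None:
        neuron_ids = np.arange(n_neurons)

    t = (np.arange(n_bins) + 0.5) * bin_width_s
    K = _se_kernel(t, kernel_lengthscale_s, kernel_variance)
    K[np.diag_indices_from(K)] += jitter

    # prior mean of log expected COUNT per bin (log rate + log bin width)
    if mean_log_rate is None:
        emp = counts.mean(axis=1) / bin_width_s
        mu_rate = np.log(np.maximum(emp, 1e-3))
    else:
        mu_rate = np.broadcast_to(np.asarray(mean_log_rate, dtype=float), (n_neurons,)).copy()
    mu_count = mu_rate + np.log(bin_width_s)

    log_rate = np.empty((n_neurons, n_bins))
    for i in range(n_neurons):
        f = _newton_map(counts[i].astype(float), K, np.full(n_bins, mu_count[i]), max_iter, tol)
        log_rate[i] = f - np.log(bin_width_s)
    return FiringRateMatrix(np.exp(log_rate), bin_width_s, neuron_ids)


def derivative_range(rate_trace: np.ndarray, bin_width_s: float) -> float:
    """max - min of the finite-difference derivative of a rate trace (Hz/s).

    Zero both for constant traces and for linear ramps: a perfectly
    ramping neuron counts as "tonic" under this statistic.
    """
    trace = np.asarray(rate_trace, dtype=float)
    if trace.ndim != 1 or trace.shape[0] < 2:
        raise ValueError("rate trace must be 1-D with at least 2 samples")
    d = np.diff(trace) / bin_width_s
    return float(d.max() - d.min())


def select_active_neurons(
    rate_matrix: FiringRateMatrix, threshold: float
) -> tuple[FiringRateMatrix, SelectionReport]:
    """Drop silent/tonic neurons whose derivative range is below threshold."""
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    ranges = np.array(
        [derivative_range(row, rate_matrix.bin_width_s) for row in rate_matrix.rates]
    )
    keep = ranges >= threshold
    if not keep.any():
        raise ValueError(
            "selection removed every neuron; reduce the derivative-range threshold"
        )
    report = SelectionReport(
        kept_ids=rate_matrix.neuron_ids[keep],
        dropped_ids=rate_matrix.neuron_ids[~keep],
        derivative_range=pd.Series(ranges, index=rate_matrix.neuron_ids),
        threshold=float(threshold),
    )
    kept = FiringRateMatrix(
        rate_matrix.rates[keep],
        rate_matrix.bin_width_s,
        rate_matrix.neuron_ids[keep],
        rate_matrix.time_origin_s,
    )
    return kept, report


def standardize(rate_matrix: FiringRateMatrix) -> tuple[np.ndarray, Standardization]:
    """Per-neuron zero-mean/unit-sd transform; stats kept for inversion."""
    rates = rate_matrix.rates
    mean = rates.mean(axis=1)
    sd = rates.std(axis=1)
    if (sd == 0).any():
        bad = rate_matrix.neuron_ids[sd == 0]
        raise ValueError(f"zero-variance rows (should have been filtered): {bad.tolist()}")
    stats = Standardization(mean=mean, sd=sd)
    return stats.apply(rates), stats
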