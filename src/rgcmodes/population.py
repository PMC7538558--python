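"""Synthetic retinal ganglion cell population.

The ground-truth encoder is a linear-nonlinear cascade: each neuron has
a difference-of-Gaussians (center-surround) spatial receptive field with
ON or OFF polarity placed on the 64x64 electrode lattice, a response
latency in frames, a gain and a baseline rate.  The rate of neuron n at
frame t is

    rate(n, t) = baseline_n + gain_n * max(<kernel_n, frame_{t-latency_n}>, 0)

Both Gaussian components of the kernel are normalized to unit mass, so
the kernel integrates to zero and a uniform frame evokes exactly the
baseline rate.

Graded encoding impairment (the analog of progressively blocking GABA
receptors) is modeled as a loss of spatio-temporal precision: the kernel
sigmas are widened by adding a level-dependent blur width in quadrature
(exactly equivalent to blurring the kernel with a Gaussian, so the
response to any spatial frequency is attenuated monotonically in level
and most strongly at high frequencies), and response latency jitter is
added as temporal smoothing of the stimulus-driven rate.

Spikes are drawn from the rates as a log-Gaussian Cox process: Poisson
counts per frame bin whose log-intensity is log(rate) plus an optional
smooth Gaussian-process perturbation, matching the model assumed by the
rate-inference stage.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .rates import FiringRateMatrix

__all__ = [
    "PopulationModel",
    "SpikeTrainSet",
    "build_population",
    "apply_impairment",
    "simulate_rates",
    "sample_spikes",
    "IMPAIRMENT_BLUR_PX",
    "IMPAIRMENT_JITTER_FRAMES",
]

LATTICE = 64

#: Kernel-widening (pixels, added in quadrature to both DoG sigmas) and
#: latency-jitter (frames, sd of the temporal smoothing of the driven
#: rate) per impairment level 0/1/2.
IMPAIRMENT_BLUR_PX = (0.0, 6.0, 12.0)
IMPAIRMENT_JITTER_FRAMES = (0.0, 3.0, 6.0)


@dataclass
class PopulationModel:
    """Ground-truth encoding model for a population of simulated RGCs."""

    rf_center: np.ndarray  # (n, 2) lattice (x, y), within [0, 63]
    sigma_center_px: np.ndarray  # (n,)
    sigma_surround_px: np.ndarray  # (n,)
    polarity: np.ndarray  # (n,) +1 (ON) or -1 (OFF)
    gain: np.ndarray  # (n,) Hz per unit of rectified drive
    baseline_rate_hz: np.ndarray  # (n,)
    latency_frames: np.ndarray  # (n,) int
    jitter_sd_frames: float = 0.0
    impairment_level: int = 0
    lattice: int = LATTICE
    seed: int = 0

    def __post_init__(self) -> None:
        self.rf_center = np.asarray(self.rf_center, dtype=float)
        if self.rf_center.ndim != 2 or self.rf_center.shape[1] != 2:
            raise ValueError("rf_center must be (n, 2)")
        if self.rf_center.min() < 0 or self.rf_center.max() > self.lattice - 1:
            raise ValueError("rf centers must lie within the electrode lattice")
        if (np.asarray(self.gain) < 0).any():
            raise ValueError("gain must be nonnegative")
        if (np.asarray(self.baseline_rate_hz) < 0).any():
            raise ValueError("baseline rate must be nonnegative")

    @property
    def n_neurons(self) -> int:
        return self.rf_center.shape[0]

    @property
    def electrode_xy(self) -> np.ndarray:
        """Nearest electrode coordinate for each neuron."""
        return np.rint(self.rf_center).astype(int)


@dataclass
class SpikeTrainSet:
    """Per-neuron sorted spike times plus electrode coordinates."""

    spikes: list  # list of 1-D float arrays, seconds
    duration_s: float
    electrode_xy: np.ndarray  # (n, 2) int lattice coordinates
    neuron_ids: np.ndarray

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise ValueError("duration must be positive")
        for i, t in enumerate(self.spikes):
            t = np.asarray(t, dtype=float)
            if t.size and (t.min() < 0 or t.max() > self.duration_s):
                raise ValueError(f"neuron {i}: spike times outside [0, duration]")
            if t.size > 1 and (np.diff(t) < 0).any():
                raise ValueError(f"neuron {i}: spike times must be sorted")
            self.spikes[i] = t

    @property
    def n_neurons(self) -> int:
        return len(self.spikes)

    @property
    def n_spikes(self) -> int:
        return int(sum(len(t) for t in self.spikes))


def build_population(
    n_neurons: int,
    seed: int,
    rf_config: dict | None = None,
) -> PopulationModel:
    """Place a population of LN neurons on the electrode lattice.

    ``rf_config`` keys (all optional):

    - ``layout``: "uniform" (default) or "jittered_grid"
    - ``region``: (x0, x1, y0, y1) lattice bounds to restrict placement
    - ``sigma_center_px``: (lo, hi) uniform range, default (3.5, 4.5)
    - ``surround_ratio``: surround/center sigma, default 2.0
    - ``gain``: Hz per unit drive, default 150.0
    - ``baseline_rate_hz``: default 2.0
    - ``latency_frames``: default 2
    - ``on_fraction``: fraction of ON cells, default 0.5
    """
    if n_neurons < 1:
        raise ValueError("n_neurons must be >= 1")
    cfg = dict(rf_config or {})
    rng = np.random.default_rng(seed)
    x0, x1, y0, y1 = cfg.get("region", (0, LATTICE - 1, 0, LATTICE - 1))
    layout = cfg.get("layout", "uniform")
    if layout == "uniform":
        xs = rng.uniform(x0, x1, n_neurons)
        ys = rng.uniform(y0, y1, n_neurons)
    elif layout == "jittered_grid":
        side = int(np.ceil(np.sqrt(n_neurons)))
        gx, gy = np.meshgrid(np.linspace(x0, x1, side), np.linspace(y0, y1, side))
        pts = np.c_[gx.ravel(), gy.ravel()][:n_neurons]
        jitter = rng.uniform(-0.5, 0.5, pts.shape) * (x1 - x0) / max(side, 2)
        xs, ys = np.clip(pts[:, 0] + jitter[:, 0], x0, x1), np.clip(
            pts[:, 1] + jitter[:, 1], y0, y1
        )
    else:
        raise ValueError(f"unknown layout {layout!r}")

    lo, hi = cfg.get("sigma_center_px", (3.5, 4.5))
    sigma_c = rng.uniform(lo, hi, n_neurons)
    sigma_s = sigma_c * cfg.get("surround_ratio", 2.0)
    on_frac = cfg.get("on_fraction", 0.5)
    polarity = np.where(rng.random(n_neurons) < on_frac, 1.0, -1.0)
    gain = np.full(n_neurons, float(cfg.get("gain", 150.0)))
    baseline = np.full(n_neurons, float(cfg.get("baseline_rate_hz", 2.0)))
    latency = np.full(n_neurons, int(cfg.get("latency_frames", 2)))
    return PopulationModel(
        rf_center=np.c_[xs, ys],
        sigma_center_px=sigma_c,
        sigma_surround_px=sigma_s,
        polarity=polarity,
        gain=gain,
        baseline_rate_hz=baseline,
        latency_frames=latency,
        seed=seed,
    )


def apply_impairment(population: PopulationModel, level: int) -> PopulationModel:
    """Graded encoding impairment: widen kernels and add latency jitter.

    Level 0 returns an identical model.  Levels must be applied to an
    unimpaired model so that widths are strictly monotone across levels.
    """
    if level not in (0, 1, 2):
        raise ValueError("impairment level must be 0, 1 or 2")
    if level == 0:
        return replace(population)
    if population.impairment_level != 0:
        raise ValueError("impairment must be applied to an unimpaired model")
    blur = IMPAIRMENT_BLUR_PX[level]
    return replace(
        population,
        sigma_center_px=np.sqrt(population.sigma_center_px**2 + blur**2),
        sigma_surround_px=np.sqrt(population.sigma_surround_px**2 + blur**2),
        jitter_sd_frames=IMPAIRMENT_JITTER_FRAMES[level],
        impairment_level=level,
    )


def _kernels(population: PopulationModel, frame_shape: tuple[int, int]) -> np.ndarray:
    """DoG kernels rasterized on the stimulus frame grid, (n, H*W)."""
    h, w = frame_shape
    # map lattice coordinates onto the frame pixel grid
    sx = (w - 1) / (population.lattice - 1)
    sy = (h - 1) / (population.lattice - 1)
    yy, xx = np.mgrid[0:h, 0:w]
    ks = np.empty((population.n_neurons, h * w))
    for i in range(population.n_neurons):
        cx = population.rf_center[i, 0] * sx
        cy = population.rf_center[i, 1] * sy
        d2 = (xx - cx) ** 2 + (yy - cy) ** 2
        gc = np.exp(-0.5 * d2 / population.sigma_center_px[i] ** 2)
        gs = np.exp(-0.5 * d2 / population.sigma_surround_px[i] ** 2)
        gc /= gc.sum()
        gs /= gs.sum()
        ks[i] = population.polarity[i] * (gc - gs).ravel()
    return ks


def simulate_rates(population: PopulationModel, stimulus) -> FiringRateMatrix:
    """LN-cascade ground-truth rates, one bin per stimulus frame.

    Frames earlier than a neuron's latency are treated as uniform mean
    luminance (zero drive).  Latency jitter (impairment) enters as its
    expected effect: Gaussian temporal smoothing of the driven rate.
    """
    if stimulus.n_frames == 0:
        raise ValueError("stimulus is empty")
    frames = stimulus.frames.reshape(stimulus.n_frames, -1)
    ks = _kernels(population, stimulus.frame_shape)
    drive0 = ks @ frames.T  # (n, T), aligned at zero latency
    drive = np.zeros_like(drive0)
    for lat in np.unique(population.latency_frames):
        sel = population.latency_frames == lat
        if lat == 0:
            drive[sel] = drive0[sel]
        else:
            drive[sel, lat:] = drive0[sel, :-lat]
    if population.jitter_sd_frames > 0:
        drive = gaussian_filter1d(drive, population.jitter_sd_frames, axis=1, mode="nearest")
    rates = population.baseline_rate_hz[:, None] + population.gain[:, None] * np.maximum(
        drive, 0.0
    )
    return FiringRateMatrix(
        rates,
        bin_width_s=1.0 / stimulus.frame_rate_hz,
        neuron_ids=np.arange(population.n_neurons),
    )


def sample_spikes(
    rates: FiringRateMatrix,
    seed: int,
    doubly_stochastic_sd: float = 0.25,
    lengthscale_s: float = 0.1,
    electrode_xy: np.ndarray | None = None,
) -> SpikeTrainSet:
    """Draw spikes from the rates as a log-Gaussian Cox process.

    With ``doubly_stochastic_sd`` > 0 the log-intensity of each neuron is
    perturbed by an independent smooth Gaussian-process draw (squared-
    exponential kernel, sd ``doubly_stochastic_sd``), mean-corrected by
    -sd^2/2 so the expected intensity still equals the supplied rate.
    With sd = 0 the process is inhomogeneous Poisson.  Deterministic
    under a fixed seed.
    """
    if (rates.rates < 0).any():
        raise ValueError("rates must be nonnegative")
    rng = np.random.default_rng(seed)
    n, T = rates.rates.shape
    dt = rates.bin_width_s
    lam = rates.rates.copy()
    if doubly_stochastic_sd > 0:
        t = (np.arange(T) + 0.5) * dt
        d = t[:, None] - t[None, :]
        K = doubly_stochastic_sd**2 * np.exp(-0.5 * (d / lengthscale_s) ** 2)
        K[np.diag_indices_from(K)] += 1e-10
        L = np.linalg.cholesky(K)
        z = (L @ rng.standard_normal((T, n))).T  # (n, T)
        lam = lam * np.exp(z - 0.5 * doubly_stochastic_sd**2)
    counts = rng.poisson(lam * dt)
    spikes = []
    for i in range(n):
        times = []
        (bins,) = np.nonzero(counts[i])
        for b in bins:
            times.append(b * dt + rng.random(counts[i, b]) * dt)
        arr = np.sort(np.concatenate(times)) if times else np.empty(0)
        spikes.append(np.minimum(arr, rates.duration_s))
    if electrode_xy is None:
        electrode_xy = np.zeros((n, 2), dtype=int)
    return SpikeTrainSet(
        spikes=spikes,
        duration_s=rates.duration_s,
        electrode_xy=electrode_xy,
        neuron_ids=np.asarray(rates.neuron_ids),
    )
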