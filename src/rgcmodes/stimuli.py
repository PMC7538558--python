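"""Visual stimulus generation.

Two stimulus families are supported, mirroring the protocols used for
multi-electrode-array recordings of mouse retina:

* drifting square-wave gratings at configurable orientation, spatial
  frequency (cycles/degree), temporal frequency and Michelson contrast;
* "natural scans": a window sliding along a trajectory over a large
  texture image (e.g. a brick wall), one crop per frame.

Frames are luminance images in [0, 1].  Per-frame metadata (orientation,
spatial frequency, phase bin, condition tag) is carried in a pandas
DataFrame aligned with the frame axis; the phase of a drifting grating is
discretized into a configurable number of bins per temporal cycle so that
it can serve as a discrete stimulus label downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "StimulusSequence",
    "make_grating_sequence",
    "make_natural_scan",
    "grating_session",
    "brick_texture",
    "raster_scan_trajectory",
]

LABEL_COLUMNS = ("orientation_deg", "spatial_freq_cpd", "phase_bin", "condition_tag")

#: Fixed convention mapping pixels to visual angle: the full frame width
#: covers this many degrees of visual field.  Any fixed convention keeps
#: the ordering of spatial frequencies; this one puts the three grating
#: frequencies used in the impairment protocol (0.011/0.023/0.045 cpd)
#: at 0.5, 1.0 and 2.0 cycles per 64-pixel frame.
DEGREES_PER_FRAME_WIDTH = 45.0


@dataclass
class StimulusSequence:
    """A sequence of luminance frames with per-frame labels."""

    frames: np.ndarray  # (time, height, width), luminance in [0, 1]
    frame_rate_hz: float
    labels: pd.DataFrame  # one row per frame

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3:
            raise ValueError("frames must be a 3-D (time, height, width) array")
        if self.frame_rate_hz <= 0:
            raise ValueError("frame_rate_hz must be positive")
        if self.frames.size and (self.frames.min() < -1e-9 or self.frames.max() > 1 + 1e-9):
            raise ValueError("frame luminance must lie within [0, 1]")
        if len(self.labels) != self.frames.shape[0]:
            raise ValueError("labels must have exactly one record per frame")
        missing = [c for c in LABEL_COLUMNS if c not in self.labels.columns]
        if missing:
            raise ValueError(f"labels missing columns: {missing}")
        self.labels = self.labels.reset_index(drop=True)

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.frames.shape[1], self.frames.shape[2]

    @property
    def duration_s(self) -> float:
        return self.n_frames / self.frame_rate_hz

    @staticmethod
    def concatenate(parts: list["StimulusSequence"]) -> "StimulusSequence":
        if not parts:
            raise ValueError("nothing to concatenate")
        rate = parts[0].frame_rate_hz
        shape = parts[0].frame_shape
        for p in parts[1:]:
            if p.frame_rate_hz != rate or p.frame_shape != shape:
                raise ValueError("all parts must share frame rate and frame shape")
        frames = np.concatenate([p.frames for p in parts], axis=0)
        labels = pd.concat([p.labels for p in parts], ignore_index=True)
        return StimulusSequence(frames, rate, labels)


def make_grating_sequence(
    orientation_deg: float,
    spatial_freq_cpd: float,
    *,
    temporal_freq_hz: float = 1.0,
    contrast: float = 0.5,
    mean_luminance: float = 0.5,
    duration_s: float = 1.0,
    frame_rate_hz: float = 30.0,
    frame_size: tuple[int, int] = (64, 64),
    phase_bins_per_cycle: int = 8,
    degrees_per_frame_width: float = DEGREES_PER_FRAME_WIDTH,
    condition_tag: str = "grating",
) -> StimulusSequence:
    """Drifting square-wave grating.

    ``orientation_deg`` is the orientation of the bars; the grating drifts
    perpendicular to them.  ``spatial_freq_cpd`` is in cycles per degree
    of visual angle, converted to cycles/pixel through the fixed
    degrees-per-frame-width convention.  The returned frames have
    Michelson contrast equal to ``contrast`` (about ``mean_luminance``).
    """
    if not 0.0 <= contrast <= 1.0:
        raise ValueError("contrast must lie in [0, 1]")
    if spatial_freq_cpd <= 0:
        raise ValueError("spatial frequency must be positive")
    if not 0.0 <= orientation_deg < 360.0:
        raise ValueError("orientation must lie in [0, 360)")
    if duration_s <= 0:
        raise ValueError("duration must be positive")
    h, w = frame_size
    if h <= 0 or w <= 0:
        raise ValueError("frame size must be positive")
    lo = mean_luminance * (1.0 - contrast)
    hi = mean_luminance * (1.0 + contrast)
    if lo < -1e-12 or hi > 1.0 + 1e-12:
        raise ValueError("mean_luminance and contrast drive luminance outside [0, 1]")
    if phase_bins_per_cycle < 1:
        raise ValueError("phase_bins_per_cycle must be >= 1")

    n_frames = int(round(duration_s * frame_rate_hz))
    deg_per_px = degrees_per_frame_width / w
    f_px = spatial_freq_cpd * deg_per_px  # cycles per pixel
    drift = np.deg2rad(orientation_deg + 90.0)  # drift axis, normal to bars
    yy, xx = np.mgrid[0:h, 0:w]
    u = xx * np.cos(drift) + yy * np.sin(drift)

    t = np.arange(n_frames) / frame_rate_hz
    phase_cycles = (temporal_freq_hz * t) % 1.0
    arg = 2.0 * np.pi * (f_px * u)[None, :, :] - (2.0 * np.pi * phase_cycles)[:, None, None]
    square = np.where(np.sin(arg) >= 0.0, 1.0, -1.0)
    frames = mean_luminance * (1.0 + contrast * square)
    np.clip(frames, 0.0, 1.0, out=frames)

    phase_bin = np.floor(phase_cycles * phase_bins_per_cycle).astype(int)
    phase_bin = np.minimum(phase_bin, phase_bins_per_cycle - 1)
    labels = pd.DataFrame(
        {
            "orientation_deg": float(orientation_deg),
            "spatial_freq_cpd": float(spatial_freq_cpd),
            "phase_bin": phase_bin,
            "condition_tag": condition_tag,
        }
    )
    return StimulusSequence(frames, frame_rate_hz, labels)


def grating_session(
    orientations_deg: list[float],
    spatial_freq_cpd: float,
    *,
    seconds_per_orientation: float = 3.0,
    temporal_freq_hz: float = 1.0,
    contrast: float = 0.5,
    mean_luminance: float = 0.5,
    frame_rate_hz: float = 30.0,
    frame_size: tuple[int, int] = (64, 64),
    phase_bins_per_cycle: int = 8,
    condition_tag: str = "grating",
) -> StimulusSequence:
    """Concatenated grating blocks, one per orientation (a recording session)."""
    parts = [
        make_grating_sequence(
            ori,
            spatial_freq_cpd,
            temporal_freq_hz=temporal_freq_hz,
            contrast=contrast,
            mean_luminance=mean_luminance,
            duration_s=seconds_per_orientation,
            frame_rate_hz=frame_rate_hz,
            frame_size=frame_size,
            phase_bins_per_cycle=phase_bins_per_cycle,
            condition_tag=condition_tag,
        )
        for ori in orientations_deg
    ]
    return StimulusSequence.concatenate(parts)


def make_natural_scan(
    image: np.ndarray,
    window_hw: tuple[int, int],
    trajectory: np.ndarray,
    frame_rate_hz: float = 30.0,
    condition_tag: str = "scan",
) -> StimulusSequence:
    """Sliding-window scan over a large image.

    ``window_hw`` are window half-sizes (rows, cols); frame ``t`` is the
    crop of ``image`` centered at ``trajectory[t]`` (row, col).  The
    trajectory index is recorded in the per-frame condition tag so that
    it can serve as a discrete stimulus label.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise ValueError("image must be 2-D")
    if image.min() < -1e-9 or image.max() > 1 + 1e-9:
        raise ValueError("image luminance must lie within [0, 1]")
    hh, hw = window_hw
    if hh < 1 or hw < 1:
        raise ValueError("window half-sizes must be >= 1")
    trajectory = np.asarray(trajectory, dtype=int)
    if trajectory.ndim != 2 or trajectory.shape[1] != 2:
        raise ValueError("trajectory must be an (n, 2) array of (row, col) points")
    rows, cols = trajectory[:, 0], trajectory[:, 1]
    if (
        (rows - hh < 0).any()
        or (rows + hh > image.shape[0]).any()
        or (cols - hw < 0).any()
        or (cols + hw > image.shape[1]).any()
    ):
        raise ValueError("trajectory window exceeds image bounds")

    frames = np.stack([image[r - hh : r + hh, c - hw : c + hw] for r, c in trajectory])
    labels = pd.DataFrame(
        {
            "orientation_deg": np.nan,
            "spatial_freq_cpd": np.nan,
            "phase_bin": -1,
            "condition_tag": [f"{condition_tag}_{i}" for i in range(len(trajectory))],
        }
    )
    return StimulusSequence(frames, frame_rate_hz, labels)


def brick_texture(
    shape: tuple[int, int] = (256, 256),
    brick: tuple[int, int] = (16, 32),
    mortar: int = 2,
    seed: int = 0,
) -> np.ndarray:
    """Synthetic brick-wall texture in [0, 1] (stand-in for a photographed wall)."""
    rng = np.random.default_rng(seed)
    h, w = shape
    bh, bw = brick
    img = np.full(shape, 0.35)
    for r0 in range(0, h, bh):
        row_idx = r0 // bh
        offset = (bw // 2) * (row_idx % 2)
        for c0 in range(-offset, w, bw):
            level = 0.45 + 0.4 * rng.random()
            r1, c1 = min(r0 + bh - mortar, h), min(c0 + bw - mortar, w)
            img[max(r0, 0) : r1, max(c0, 0) : c1] = level
    img += 0.03 * rng.standard_normal(shape)
    return np.clip(img, 0.0, 1.0)


def raster_scan_trajectory(
    image_shape: tuple[int, int],
    window_hw: tuple[int, int],
    n_points: int,
    step: int = 4,
) -> np.ndarray:
    """Deterministic serpentine trajectory keeping the window inside the image."""
    hh, hw = window_hw
    r_lo, r_hi = hh, image_shape[0] - hh
    c_lo, c_hi = hw, image_shape[1] - hw
    pts = []
    r, c, dc = r_lo, c_lo, step
    while len(pts) < n_points:
        pts.append((r, c))
        c2 = c + dc
        if c2 < c_lo or c2 >= c_hi:
            dc = -dc
            r2 = r + step
            r = r2 if r2 < r_hi else r_lo
        else:
            c = c2
    return np.asarray(pts[:n_points], dtype=int)
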