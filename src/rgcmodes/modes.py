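"""Latent-state extraction and state-triggered stimulus averaging.

A trained model maps each firing-rate sample to a vector of binary
latent activations; the full vector is the sample's *state* (a mode of
the modeled distribution), and each coordinate is a *unit*.  What a
state or unit encodes is visualized with an average closely related to
the spike-triggered average: collect the stimulus frames at the times
whose samples activate the state/unit and average them pixelwise.  For
the temporal (conditional) model the averaging preserves temporal
order, producing a sequence of averages over the history slots.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit

from .crbm import CRBMParams, dynamic_biases, make_history_dataset
from .mcrbm import McRBMParams, mean_unit_probs, precision_unit_probs
from .rbm import RBMParams, hidden_given_visible

__all__ = [
    "BinaryStateTable",
    "ModeImage",
    "ModeSequence",
    "EmptyModeError",
    "infer_states",
    "state_triggered_average",
    "unit_triggered_average",
    "temporal_sta",
    "mode_census",
    "state_stimulus_histogram",
    "best_frame_match",
]


class EmptyModeError(ValueError):
    """Requested state/unit never occurs in the table."""


def _pack_ids(states: np.ndarray) -> np.ndarray:
    if states.shape[1] > 62:
        raise ValueError("state encoding limited to 62 latent units")
    weights = 1 << np.arange(states.shape[1], dtype=np.int64)
    return states.astype(np.int64) @ weights


@dataclass
class BinaryStateTable:
    """Per-sample binary latent vectors aligned with stimulus frames."""

    states: np.ndarray  # (n_samples, n_units) bool
    unit_kind: list  # per-column tag: "mean", "precision" or "hidden"
    sample_index: np.ndarray  # frame index of each sample in the stimulus

    def __post_init__(self) -> None:
        self.states = np.asarray(self.states, dtype=bool)
        self.sample_index = np.asarray(self.sample_index, dtype=int)
        if self.states.ndim != 2:
            raise ValueError("states must be 2-D")
        if len(self.unit_kind) != self.states.shape[1]:
            raise ValueError("unit_kind must tag every column")
        if self.sample_index.shape[0] != self.states.shape[0]:
            raise ValueError("sample_index must align with state rows")
        self.state_id = _pack_ids(self.states)

    @property
    def n_samples(self) -> int:
        return self.states.shape[0]

    @property
    def n_units(self) -> int:
        return self.states.shape[1]


def _binarize(probs: np.ndarray, rule: str, rng: np.random.Generator | None) -> np.ndarray:
    if rule == "threshold":
        return probs >= 0.5  # probabilities of exactly 0.5 round up
    if rule == "sample":
        if rng is None:
            raise ValueError("binarize_rule='sample' requires an rng")
        return rng.random(probs.shape) < probs
    raise ValueError(f"unknown binarize rule {rule!r}")


def infer_states(
    model,
    V: np.ndarray,
    *,
    binarize_rule: str = "threshold",
    mean_only: bool = False,
    sample_index: np.ndarray | None = None,
    rng: np.random.Generator | None = None,
) -> BinaryStateTable:
    """Binary latent states for every firing-rate sample.

    ``V`` is (time, neurons), standardized consistently with training.
    For an mcRBM the state concatenates binarized mean-unit and
    precision-unit activations (``mean_only`` drops the precision part);
    for a cRBM samples without a full history window are dropped and the
    surviving frame indices are recorded in ``sample_index``.
    """
    V = np.asarray(V, dtype=float)
    if isinstance(model, McRBMParams):
        if V.shape[1] != model.n_visible:
            raise ValueError("data dimension does not match model")
        probs = mean_unit_probs(model, V)
        kinds = ["mean"] * model.n_mean
        if not mean_only:
            probs = np.hstack([probs, precision_unit_probs(model, V)])
            kinds += ["precision"] * model.n_precision
    elif isinstance(model, CRBMParams):
        if V.shape[1] != model.n_visible:
            raise ValueError("data dimension does not match model")
        present, hist, t_idx = make_history_dataset(V, model.order, model.frame_spacing)
        _, b_hat = dynamic_biases(model, hist)
        probs = expit(b_hat + present @ model.W)
        kinds = ["hidden"] * model.n_hidden
        if sample_index is None:
            sample_index = t_idx
        else:
            sample_index = np.asarray(sample_index)[t_idx]
    elif isinstance(model, RBMParams):
        if V.shape[1] != model.n_visible:
            raise ValueError("data dimension does not match model")
        probs = hidden_given_visible(model, V)
        kinds = ["hidden"] * model.n_hidden
    else:
        raise TypeError(f"unsupported model type {type(model).__name__}")
    states = _binarize(probs, binarize_rule, rng)
    if sample_index is None:
        sample_index = np.arange(states.shape[0])
    return BinaryStateTable(states, kinds, sample_index)


@dataclass
class ModeImage:
    mean_frame: np.ndarray
    n_samples_averaged: int
    identifier: tuple  # ("state", id) or ("unit", index)
    lag_frames: int
    n_skipped: int = 0


@dataclass
class ModeSequence:
    mean_frames: list  # ordered most-delayed first
    n_samples_averaged: int
    identifier: tuple
    lag_frames: int
    slot_lags: list  # frame lag of each slot relative to the trigger


def _triggered_mean(frame_idx: np.ndarray, stimulus, lag_frames: int, ident) -> ModeImage:
    shifted = frame_idx - lag_frames
    ok = shifted >= 0
    if not ok.any():
        raise EmptyModeError(f"{ident}: no triggering samples remain after lag {lag_frames}")
    mean = stimulus.frames[shifted[ok]].mean(axis=0)
    return ModeImage(mean, int(ok.sum()), ident, lag_frames, n_skipped=int((~ok).sum()))


def state_triggered_average(
    table: BinaryStateTable, stimulus, state_id: int, lag_frames: int = 0
) -> ModeImage:
    """Pixelwise mean of frames at times (t - lag) where the state occurs."""
    mask = table.state_id == state_id
    if not mask.any():
        raise EmptyModeError(f"state {state_id} never occurs")
    return _triggered_mean(table.sample_index[mask], stimulus, lag_frames, ("state", state_id))


def unit_triggered_average(
    table: BinaryStateTable, stimulus, unit_index: int, lag_frames: int = 0
) -> ModeImage:
    """As the state-triggered average, triggered on one unit being active."""
    mask = table.states[:, unit_index]
    if not mask.any():
        raise EmptyModeError(f"unit {unit_index} is never active")
    return _triggered_mean(table.sample_index[mask], stimulus, lag_frames, ("unit", unit_index))


def temporal_sta(
    table: BinaryStateTable,
    stimulus,
    *,
    state_id: int | None = None,
    unit_index: int | None = None,
    order: int,
    spacing: int,
    lag_frames: int = 0,
) -> ModeSequence:
    """Sequence of averages over the history slots, most delayed first.

    Slot k (k = order .. 1) averages frames at t - lag - k*spacing over
    the triggering samples; samples lacking a full history are skipped.
    """
    if (state_id is None) == (unit_index is None):
        raise ValueError("specify exactly one of state_id or unit_index")
    if state_id is not None:
        mask = table.state_id == state_id
        ident = ("state", state_id)
    else:
        mask = table.states[:, unit_index]
        ident = ("unit", unit_index)
    if not mask.any():
        raise EmptyModeError(f"{ident} never occurs")
    idx = table.sample_index[mask]
    deepest = lag_frames + order * spacing
    ok = idx - deepest >= 0
    if not ok.any():
        raise EmptyModeError(f"{ident}: no triggering samples with a full history")
    idx = idx[ok]
    slot_lags = [lag_frames + k * spacing for k in range(order, 0, -1)]
    frames = [stimulus.frames[idx - sl].mean(axis=0) for sl in slot_lags]
    return ModeSequence(frames, int(idx.size), ident, lag_frames, slot_lags)


def mode_census(table: BinaryStateTable) -> pd.DataFrame:
    """Occupancy of every observed state, sorted descending."""
    if table.n_samples == 0:
        raise ValueError("state table is empty")
    ids, counts = np.unique(table.state_id, return_counts=True)
    df = pd.DataFrame({"state_id": ids, "count": counts})
    df["fraction"] = df["count"] / table.n_samples
    return df.sort_values(["count", "state_id"], ascending=[False, True]).reset_index(drop=True)


def state_stimulus_histogram(
    table: BinaryStateTable, stimulus_labels, state_id: int
) -> pd.Series:
    """Counts of each stimulus label among a state's triggering samples."""
    labels = np.asarray(stimulus_labels)
    mask = table.state_id == state_id
    if not mask.any():
        raise EmptyModeError(f"state {state_id} never occurs")
    triggered = labels[table.sample_index[mask]]
    vals, counts = np.unique(triggered, return_counts=True)
    return pd.Series(counts, index=vals, name=f"state_{state_id}")


def best_frame_match(image: np.ndarray, frames: np.ndarray) -> tuple[int, float]:
    """Index and Pearson r of the stimulus frame best matching an average."""
    x = image.ravel() - image.mean()
    F = frames.reshape(frames.shape[0], -1)
    F = F - F.mean(axis=1, keepdims=True)
    num = F @ x
    den = np.linalg.norm(F, axis=1) * np.linalg.norm(x)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(den > 0, num / den, 0.0)
    best = int(np.argmax(r))
    return best, float(r[best])
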