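"""HDF5 / text serialization for stimuli, spikes, rates, models and states."""

from __future__ import annotations

import numpy as np
import pandas as pd
import h5py

from .crbm import CRBMParams
from .mcrbm import McRBMParams
from .modes import BinaryStateTable
from .population import SpikeTrainSet
from .rates import FiringRateMatrix
from .rbm import RBMParams
from .stimuli import LABEL_COLUMNS, StimulusSequence

__all__ = [
    "save_stimulus",
    "load_stimulus",
    "save_spikes",
    "load_spikes",
    "spikes_to_tsv",
    "spikes_from_tsv",
    "save_rates",
    "load_rates",
    "save_model",
    "load_model",
    "save_states",
    "load_states",
]

_STR = h5py.string_dtype(encoding="utf-8")


def _write_attrs(g, **attrs) -> None:
    for k, v in attrs.items():
        if v is not None:
            g.attrs[k] = v


def save_stimulus(path, stim: StimulusSequence, *, seed=None, config_hash=None) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("frames", data=stim.frames, compression=None)
        g = f.create_group("labels")
        for col in LABEL_COLUMNS:
            vals = stim.labels[col].to_numpy()
            if vals.dtype == object:
                vals = vals.astype(str).astype(_STR)
            g.create_dataset(col, data=vals)
        _write_attrs(f, frame_rate=stim.frame_rate_hz, seed=seed, config_hash=config_hash)


def load_stimulus(path) -> StimulusSequence:
    with h5py.File(path, "r") as f:
        frames = f["frames"][...]
        labels = {}
        for col in LABEL_COLUMNS:
            vals = f["labels"][col][...]
            if vals.dtype.kind in ("S", "O"):
                vals = np.array([v.decode() if isinstance(v, bytes) else v for v in vals])
            labels[col] = vals
        rate = float(f.attrs["frame_rate"])
    return StimulusSequence(frames, rate, pd.DataFrame(labels))


def save_spikes(path, sts: SpikeTrainSet, *, seed=None, config_hash=None) -> None:
    with h5py.File(path, "w") as f:
        flat = np.concatenate([s for s in sts.spikes]) if sts.n_spikes else np.empty(0)
        lengths = np.array([len(s) for s in sts.spikes])
        f.create_dataset("spike_times", data=flat)
        f.create_dataset("spike_counts", data=lengths)
        f.create_dataset("electrode_xy", data=np.asarray(sts.electrode_xy))
        f.create_dataset("neuron_ids", data=np.asarray(sts.neuron_ids))
        _write_attrs(f, duration_s=sts.duration_s, seed=seed, config_hash=config_hash)


def load_spikes(path) -> SpikeTrainSet:
    with h5py.File(path, "r") as f:
        flat = f["spike_times"][...]
        lengths = f["spike_counts"][...]
        xy = f["electrode_xy"][...]
        ids = f["neuron_ids"][...]
        dur = float(f.attrs["duration_s"])
    splits = np.cumsum(lengths)[:-1]
    return SpikeTrainSet(list(np.split(flat, splits)), dur, xy, ids)


def spikes_to_tsv(path, sts: SpikeTrainSet) -> None:
    """Two-column text format: neuron_id, spike_time_s, sorted by neuron then time."""
    with open(path, "w") as fh:
        fh.write("neuron_id\tspike_time_s\n")
        for nid, times in zip(sts.neuron_ids, sts.spikes):
            for t in times:
                fh.write(f"{nid}\t{t:.6f}\n")


def spikes_from_tsv(path, duration_s: float, electrode_xy=None) -> SpikeTrainSet:
    df = pd.read_csv(path, sep="\t")
    ids = df["neuron_id"].unique()
    spikes = [df.loc[df["neuron_id"] == i, "spike_time_s"].to_numpy() for i in ids]
    if electrode_xy is None:
        electrode_xy = np.zeros((len(ids), 2), dtype=int)
    return SpikeTrainSet(spikes, duration_s, electrode_xy, ids)


def save_rates(path, frm: FiringRateMatrix, *, seed=None, config_hash=None) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("rates", data=frm.rates)
        f.create_dataset("neuron_ids", data=np.asarray(frm.neuron_ids))
        _write_attrs(
            f,
            bin_width=frm.bin_width_s,
            time_origin=frm.time_origin_s,
            seed=seed,
            config_hash=config_hash,
        )


def load_rates(path) -> FiringRateMatrix:
    with h5py.File(path, "r") as f:
        return FiringRateMatrix(
            f["rates"][...],
            float(f.attrs["bin_width"]),
            f["neuron_ids"][...],
            float(f.attrs.get("time_origin", 0.0)),
        )


_MODEL_FIELDS = {
    "rbm": ("W", "a", "b"),
    "mcrbm": ("W", "a", "b_m", "C", "P", "b_c"),
    "crbm": ("W", "a", "b", "A", "B"),
}


def save_model(path, params, *, seed=None, config_hash=None, loss_trace=None) -> None:
    if isinstance(params, McRBMParams):
        kind = "mcrbm"
    elif isinstance(params, CRBMParams):
        kind = "crbm"
    elif isinstance(params, RBMParams):
        kind = "rbm"
    else:
        raise TypeError(f"unsupported model type {type(params).__name__}")
    with h5py.File(path, "w") as f:
        for name in _MODEL_FIELDS[kind]:
            f.create_dataset(name, data=getattr(params, name))
        _write_attrs(f, model_kind=kind, seed=seed, config_hash=config_hash)
        if kind == "rbm":
            f.attrs["visible_kind"] = params.visible_kind
        if kind == "crbm":
            f.attrs["order"] = params.order
            f.attrs["frame_spacing"] = params.frame_spacing
        if loss_trace is not None:
            f.create_dataset("loss_trace", data=np.asarray(loss_trace))


def load_model(path):
    with h5py.File(path, "r") as f:
        kind = f.attrs["model_kind"]
        arrays = {name: f[name][...] for name in _MODEL_FIELDS[kind]}
        if kind == "rbm":
            return RBMParams(visible_kind=f.attrs["visible_kind"], **arrays)
        if kind == "mcrbm":
            return McRBMParams(**arrays)
        return CRBMParams(
            order=int(f.attrs["order"]), frame_spacing=int(f.attrs["frame_spacing"]), **arrays
        )


def save_states(path, table: BinaryStateTable, *, config_hash=None) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("states", data=table.states.astype(np.uint8))
        f.create_dataset("sample_index", data=table.sample_index)
        f.create_dataset("unit_kind", data=np.array(table.unit_kind, dtype=_STR))
        _write_attrs(f, config_hash=config_hash)


def load_states(path) -> BinaryStateTable:
    with h5py.File(path, "r") as f:
        kinds = [k.decode() if isinstance(k, bytes) else k for k in f["unit_kind"][...]]
        return BinaryStateTable(f["states"][...].astype(bool), kinds, f["sample_index"][...])
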