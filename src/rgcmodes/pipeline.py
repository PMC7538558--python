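"""Experiment orchestration: configuration, patch partition, staged runs.

The electrode lattice is divided into a 4x4 grid of non-overlapping
16x16-electrode patches, labelled t0..t15 row-major; population models
are trained per patch to keep the visible dimension manageable.  A
declarative YAML config describes one full experiment (stimulus,
population, rate inference, model, analysis, evaluation); ``run``
executes every stage in order, persisting each stage's artifacts to the
output directory together with the config hash and seed so a rerun with
the same config reproduces byte-identical tables.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import information, io, modes
from .crbm import counterphase_spacing, train_crbm
from .mcrbm import train_mcrbm
from .population import apply_impairment, build_population, sample_spikes, simulate_rates
from .protocols import PROTOCOL_LENGTHSCALE_S, PROTOCOL_SELECT_THRESHOLD
from .rates import bin_spikes, lgcp_fit, select_active_neurons, standardize
from .rbm import TrainConfig, train_rbm
from .stimuli import grating_session, make_grating_sequence

__all__ = [
    "PatchAssignment",
    "partition_patches",
    "ExperimentConfig",
    "run_experiment",
]

N_PATCH_SIDE = 4
PATCH_ELECTRODES = 16
LATTICE = 64


@dataclass
class PatchAssignment:
    """Per-neuron membership in the 16 non-overlapping 16x16 patches."""

    patch_index: np.ndarray  # (n,) int in 0..15
    electrode_xy: np.ndarray

    def members(self, patch: int) -> np.ndarray:
        return np.flatnonzero(self.patch_index == patch)

    def counts(self) -> np.ndarray:
        return np.bincount(self.patch_index, minlength=N_PATCH_SIDE**2)


def partition_patches(electrode_xy: np.ndarray) -> PatchAssignment:
    """Assign each electrode coordinate to its patch t0..t15 (row-major).

    patch = (row // 16) * 4 + (col // 16), with (col, row) = (x, y).
    """
    xy = np.asarray(electrode_xy, dtype=int)
    if xy.ndim != 2 or xy.shape[1] != 2:
        raise ValueError("electrode_xy must be (n, 2)")
    if xy.min() < 0 or xy.max() >= LATTICE:
        raise ValueError("electrode coordinates must lie within the 64x64 lattice")
    col, row = xy[:, 0], xy[:, 1]
    idx = (row // PATCH_ELECTRODES) * N_PATCH_SIDE + (col // PATCH_ELECTRODES)
    return PatchAssignment(idx.astype(int), xy)


@dataclass
class ExperimentConfig:
    """Declarative description of one experiment run (YAML-serializable)."""

    stimulus: dict = field(default_factory=lambda: {
        "kind": "grating_session",
        "orientations_deg": [0, 45, 90, 135, 180, 225, 270, 315],
        "spatial_freq_cpd": 0.023,
        "seconds_per_orientation": 3.0,
    })
    population: dict = field(default_factory=lambda: {
        "n_neurons": 200,
        "impairment_level": 0,
        "rf_config": {},
    })
    rate_inference: dict = field(default_factory=lambda: {
        "kernel_lengthscale_s": PROTOCOL_LENGTHSCALE_S,
        "select_threshold": PROTOCOL_SELECT_THRESHOLD,
        "doubly_stochastic_sd": 0.25,
    })
    model: dict = field(default_factory=lambda: {
        "kind": "mcrbm",
        "train": {"n_hidden": 8, "n_factors": 32, "n_precision": 8, "epochs": 40},
    })
    analysis: dict = field(default_factory=lambda: {
        "patch": None,  # patch id 0..15, or None for the whole array
        "lag_frames": 2,
        "top_k_states": 3,
        "mean_only": False,
    })
    evaluation: dict = field(default_factory=lambda: {
        "labels": "phase",  # "phase", "orientation_phase" or "condition"
        "null_reps": 50,
    })
    seed: int = 0

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        cfg = cls()
        for key, val in d.items():
            if not hasattr(cfg, key):
                raise ValueError(f"unknown config section {key!r}")
            current = getattr(cfg, key)
            if isinstance(current, dict):
                merged = dict(current)
                merged.update(val)
                setattr(cfg, key, merged)
            else:
                setattr(cfg, key, val)
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @property
    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=float)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _derived_seed(seed: int, k: int) -> int:
    return (seed * 1009 + k) % 2**31


def _build_stimulus(cfg: ExperimentConfig):
    spec = dict(cfg.stimulus)
    kind = spec.pop("kind")
    if kind == "grating_session":
        return grating_session(
            spec["orientations_deg"],
            spec["spatial_freq_cpd"],
            seconds_per_orientation=spec.get("seconds_per_orientation", 3.0),
            temporal_freq_hz=spec.get("temporal_freq_hz", 1.0),
            contrast=spec.get("contrast", 0.5),
        )
    if kind == "grating":
        return make_grating_sequence(
            spec.get("orientation_deg", 0.0),
            spec["spatial_freq_cpd"],
            duration_s=spec.get("duration_s", 30.0),
            temporal_freq_hz=spec.get("temporal_freq_hz", 1.0),
            contrast=spec.get("contrast", 0.5),
        )
    raise ValueError(f"unknown stimulus kind {kind!r}")


def _evaluation_labels(cfg: ExperimentConfig, stimulus, table, lag: int) -> np.ndarray:
    frame_idx = table.sample_index - lag
    labels = stimulus.labels.iloc[frame_idx]
    kind = cfg.evaluation.get("labels", "phase")
    if kind == "phase":
        return labels["phase_bin"].to_numpy()
    if kind == "orientation_phase":
        return (
            labels["orientation_deg"].astype(str) + "_" + labels["phase_bin"].astype(str)
        ).to_numpy()
    if kind == "condition":
        return labels["condition_tag"].to_numpy()
    raise ValueError(f"unknown label kind {kind!r}")


def run_experiment(config: ExperimentConfig, outdir) -> dict:
    """Execute the full pipeline for one config; artifacts land in ``outdir``.

    Stages: stimulus -> population -> true rates -> spikes -> LGCP rates
    -> selection -> standardize -> patch restriction -> train -> states
    -> census/STA -> evaluation.  Every array artifact is HDF5, every
    table CSV; all stamped with the config hash.  Deterministic under
    the config seed.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    chash = config.config_hash
    seed = config.seed
    log: list[str] = []

    def _log(stage: str) -> None:
        log.append(stage)

    config.to_yaml(outdir / "config.yaml")

    stim = _build_stimulus(config)
    io.save_stimulus(outdir / "stimulus.h5", stim, seed=seed, config_hash=chash)
    _log("stimulus")

    pop = build_population(
        config.population["n_neurons"],
        _derived_seed(seed, 0),
        config.population.get("rf_config") or None,
    )
    level = config.population.get("impairment_level", 0)
    if level:
        pop = apply_impairment(pop, level)
    true_rates = simulate_rates(pop, stim)
    spikes = sample_spikes(
        true_rates,
        _derived_seed(seed, 1),
        doubly_stochastic_sd=config.rate_inference.get("doubly_stochastic_sd", 0.25),
        electrode_xy=pop.electrode_xy,
    )
    io.save_spikes(outdir / "spikes.h5", spikes, seed=seed, config_hash=chash)
    io.spikes_to_tsv(outdir / "spikes.tsv", spikes)
    _log("spikes")

    counts = bin_spikes(spikes, true_rates.bin_width_s, n_bins=true_rates.n_bins)
    inferred = lgcp_fit(
        counts,
        true_rates.bin_width_s,
        kernel_lengthscale_s=config.rate_inference.get(
            "kernel_lengthscale_s", PROTOCOL_LENGTHSCALE_S
        ),
        neuron_ids=np.asarray(spikes.neuron_ids),
    )
    io.save_rates(outdir / "rates.h5", inferred, seed=seed, config_hash=chash)
    _log("rates")

    kept, report = select_active_neurons(
        inferred, config.rate_inference.get("select_threshold", PROTOCOL_SELECT_THRESHOLD)
    )
    report.to_frame().to_csv(outdir / "selection.csv", index=False, float_format="%.10g")
    _log("selection")

    patch = config.analysis.get("patch")
    assignment = partition_patches(spikes.electrode_xy)
    if patch is not None:
        member_ids = set(np.asarray(spikes.neuron_ids)[assignment.members(int(patch))].tolist())
        keep_mask = np.array([i in member_ids for i in kept.neuron_ids])
        if not keep_mask.any():
            raise ValueError(f"patch {patch} holds no selected neurons")
        from .rates import FiringRateMatrix

        kept = FiringRateMatrix(
            kept.rates[keep_mask], kept.bin_width_s, kept.neuron_ids[keep_mask]
        )
    pd.DataFrame(
        {"neuron_id": spikes.neuron_ids, "patch": assignment.patch_index}
    ).to_csv(outdir / "patches.csv", index=False)

    Vstd, stats = standardize(kept)
    V = Vstd.T  # (time, neurons)
    _log("standardize")

    kind = config.model.get("kind", "mcrbm")
    tc_kwargs = dict(config.model.get("train", {}))
    tc_kwargs.setdefault("seed", _derived_seed(seed, 2))
    tc = TrainConfig(**tc_kwargs)
    if kind == "mcrbm":
        params, trace = train_mcrbm(V, tc)
    elif kind == "rbm":
        params, trace = train_rbm(V, tc, visible_kind="gaussian")
    elif kind == "crbm":
        order = config.model.get("order", 12)
        period = config.model.get("stimulus_period_s", 1.0)
        spacing = config.model.get(
            "frame_spacing", counterphase_spacing(order, period, kept.bin_width_s)
        )
        params, trace = train_crbm(V, order, frame_spacing=spacing, config=tc)
    else:
        raise ValueError(f"unknown model kind {kind!r}")
    io.save_model(outdir / "model.h5", params, seed=seed, config_hash=chash, loss_trace=trace)
    _log("train")

    table = modes.infer_states(
        params, V, mean_only=config.analysis.get("mean_only", False)
    )
    io.save_states(outdir / "states.h5", table, config_hash=chash)
    census = modes.mode_census(table)
    census.to_csv(outdir / "census.csv", index=False, float_format="%.10g")
    _log("states")

    lag = int(config.analysis.get("lag_frames", 2))
    top_k = int(config.analysis.get("top_k_states", 3))
    sta_rows = []
    mode_dir = outdir / "modes"
    mode_dir.mkdir(exist_ok=True)
    for _, row in census.head(top_k).iterrows():
        sid = int(row.state_id)
        img = modes.state_triggered_average(table, stim, sid, lag_frames=lag)
        idx, r = modes.best_frame_match(img.mean_frame, stim.frames)
        sta_rows.append(
            {"state_id": sid, "occupancy": int(row["count"]), "best_frame": idx, "pearson_r": r}
        )
        _save_png(mode_dir / f"state_{sid}.png", img.mean_frame)
    pd.DataFrame(sta_rows).to_csv(outdir / "sta_matches.csv", index=False, float_format="%.10g")
    _log("modes")

    labels = _evaluation_labels(config, stim, table, lag)
    res = information.mi_result(labels, table.state_id)
    null = information.shuffled_null_nmi(
        labels,
        table.state_id,
        n_reps=int(config.evaluation.get("null_reps", 50)),
        seed=_derived_seed(seed, 3),
    )
    eval_df = pd.DataFrame(
        [
            {
                "nmi": res.nmi,
                "mi_bits": res.mi_bits,
                "stimulus_entropy_bits": res.stimulus_entropy_bits,
                "n_samples": res.n_samples,
                "null_nmi_mean": float(null.mean()),
                "null_nmi_p95": float(np.quantile(null, 0.95)),
                "config_hash": chash,
                "seed": seed,
            }
        ]
    )
    eval_df.to_csv(outdir / "evaluation.csv", index=False, float_format="%.10g")
    _log("evaluate")

    (outdir / "stages.log").write_text("\n".join(log) + "\n")
    return {
        "config_hash": chash,
        "stimulus": stim,
        "population": pop,
        "rates": inferred,
        "selection": report,
        "model": params,
        "states": table,
        "census": census,
        "sta_matches": pd.DataFrame(sta_rows),
        "evaluation": eval_df,
        "outdir": outdir,
    }


def _save_png(path, frame: np.ndarray) -> None:
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.image as mpimg

    mpimg.imsave(path, frame, cmap="gray", vmin=0.0, vmax=1.0)
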