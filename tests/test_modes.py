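"""State/unit-triggered stimulus averaging and state bookkeeping."""

import numpy as np
import pandas as pd
import pytest

from rgcmodes.mcrbm import McRBMParams
from rgcmodes.modes import (
    BinaryStateTable,
    EmptyModeError,
    best_frame_match,
    infer_states,
    mode_census,
    state_stimulus_histogram,
    state_triggered_average,
    temporal_sta,
    unit_triggered_average,
)
from rgcmodes.rbm import RBMParams, all_binary_vectors, energy
from rgcmodes.stimuli import make_grating_sequence


def _table(states, idx=None):
    states = np.asarray(states, dtype=bool)
    if idx is None:
        idx = np.arange(states.shape[0])
    return BinaryStateTable(states, ["hidden"] * states.shape[1], idx)


@pytest.fixture(scope="module")
def stim():
    return make_grating_sequence(0.0, 0.023, duration_s=1.0)


class TestInferStates:
    def test_half_probabilities_round_up(self):
        # with all parameters zero every activation probability is
        # exactly 0.5, which binarizes to 1 by convention
        p = RBMParams(np.zeros((3, 2)), np.zeros(3), np.zeros(2), "gaussian")
        t = infer_states(p, np.zeros((4, 3)))
        assert t.states.all()

    def test_duplicate_samples_get_identical_states(self, rng):
        p = RBMParams(rng.standard_normal((3, 2)), np.zeros(3), np.zeros(2), "gaussian")
        v = rng.standard_normal(3)
        t = infer_states(p, np.vstack([v, v]))
        assert np.array_equal(t.states[0], t.states[1])
        assert t.state_id[0] == t.state_id[1]

    def test_thresholded_states_match_map_enumeration(self, rng):
        # hidden units are conditionally independent, so the thresholded
        # vector equals the brute-force MAP over all hidden vectors
        p = RBMParams(rng.standard_normal((4, 3)), np.zeros(4), rng.standard_normal(3),
                      "gaussian")
        V = rng.standard_normal((10, 4))
        t = infer_states(p, V)
        hs = all_binary_vectors(3)
        for v, s in zip(V, t.states):
            es = np.array([energy(p, v, h) for h in hs])
            assert np.array_equal(hs[np.argmin(es)], s.astype(float))

    def test_mcrbm_state_concatenates_mean_and_precision(self, rng):
        p = McRBMParams(
            W=rng.standard_normal((3, 2)), a=np.zeros(3), b_m=np.zeros(2),
            C=rng.standard_normal((3, 4)), P=-np.ones((4, 2)), b_c=np.zeros(2),
        )
        V = rng.standard_normal((5, 3))
        full = infer_states(p, V)
        mean_only = infer_states(p, V, mean_only=True)
        assert full.n_units == 4 and mean_only.n_units == 2
        assert full.unit_kind == ["mean", "mean", "precision", "precision"]
        assert np.array_equal(full.states[:, :2], mean_only.states)


class TestTriggeredAverages:
    def test_single_occurrence_returns_that_frame(self, stim):
        t = _table([[1, 0]] + [[0, 1]] * 9)
        img = state_triggered_average(t, stim, t.state_id[0])
        assert np.array_equal(img.mean_frame, stim.frames[0])
        assert img.n_samples_averaged == 1

    def test_two_identical_frames_average_to_the_frame(self, stim):
        # frames 0 and 30 of a 1 Hz grating are a full period apart
        t = _table([[1, 0], [1, 0]], idx=np.array([0, 30]))
        stim2 = make_grating_sequence(0.0, 0.023, duration_s=2.0)
        img = state_triggered_average(t, stim2, t.state_id[0])
        assert np.allclose(img.mean_frame, stim2.frames[0])

    def test_absent_state_raises_empty_mode(self, stim):
        t = _table([[1, 0]] * 5)
        with pytest.raises(EmptyModeError):
            state_triggered_average(t, stim, 999)

    def test_lag_skips_early_samples_and_reports_count(self, stim):
        t = _table([[1]] * 5, idx=np.arange(5))
        img = state_triggered_average(t, stim, t.state_id[0], lag_frames=2)
        assert img.n_samples_averaged == 3 and img.n_skipped == 2

    def test_unit_always_on_averages_all_frames(self, stim):
        t = _table(np.ones((stim.n_frames, 2)))
        img = unit_triggered_average(t, stim, 0)
        assert np.allclose(img.mean_frame, stim.frames.mean(axis=0))

    def test_unit_never_on_raises(self, stim):
        t = _table(np.c_[np.ones(5), np.zeros(5)])
        with pytest.raises(EmptyModeError):
            unit_triggered_average(t, stim, 1)

    def test_unit_trigger_set_is_union_of_its_states(self, stim, rng):
        states = rng.integers(0, 2, (30, 3)).astype(bool)
        states[:, 0] |= states.sum(axis=1) == 0  # avoid empty rows issue
        t = _table(states)
        unit = 1
        if not t.states[:, unit].any():
            pytest.skip("unit never active in draw")
        img_unit = unit_triggered_average(t, stim, unit)
        ids_with_bit = [sid for sid in np.unique(t.state_id) if (sid >> unit) & 1]
        n_union = sum((t.state_id == sid).sum() for sid in ids_with_bit)
        assert img_unit.n_samples_averaged == n_union
        weighted = sum(
            state_triggered_average(t, stim, sid).mean_frame * (t.state_id == sid).sum()
            for sid in ids_with_bit
        ) / n_union
        assert np.allclose(img_unit.mean_frame, weighted)

    def test_average_stays_inside_frame_value_hull(self, stim, rng):
        t = _table(rng.integers(0, 2, (30, 2)).astype(bool) | True)
        img = unit_triggered_average(t, stim, 0)
        assert img.mean_frame.min() >= stim.frames.min() - 1e-12
        assert img.mean_frame.max() <= stim.frames.max() + 1e-12

    def test_linearity_over_label_groups(self, stim):
        # the mode image equals the label-histogram-weighted mean of the
        # per-label mean frames (exact identity)
        labels = stim.labels["phase_bin"].to_numpy()
        t = _table([[1]] * stim.n_frames)
        sid = t.state_id[0]
        img = state_triggered_average(t, stim, sid)
        hist = state_stimulus_histogram(t, labels, sid)
        per_label = {
            lab: stim.frames[labels == lab].mean(axis=0) for lab in hist.index
        }
        weighted = sum(per_label[lab] * n for lab, n in hist.items()) / hist.sum()
        assert np.allclose(img.mean_frame, weighted)


class TestTemporalSta:
    def test_single_trigger_returns_actual_history(self, stim):
        t = _table([[1]], idx=np.array([20]))
        seq = temporal_sta(t, stim, state_id=t.state_id[0], order=3, spacing=2)
        # most delayed first: frames 14, 16, 18
        assert seq.slot_lags == [6, 4, 2]
        for frame, lag in zip(seq.mean_frames, seq.slot_lags):
            assert np.array_equal(frame, stim.frames[20 - lag])

    def test_static_stimulus_gives_identical_slots(self):
        stim = make_grating_sequence(0.0, 0.023, contrast=0.0, duration_s=1.0)
        t = _table([[1]] * 10, idx=np.arange(15, 25))
        seq = temporal_sta(t, stim, state_id=t.state_id[0], order=3, spacing=2)
        for f in seq.mean_frames[1:]:
            assert np.allclose(f, seq.mean_frames[0])

    def test_insufficient_history_raises(self, stim):
        t = _table([[1]], idx=np.array([2]))
        with pytest.raises(EmptyModeError):
            temporal_sta(t, stim, state_id=t.state_id[0], order=3, spacing=2)

    def test_exactly_one_target_required(self, stim):
        t = _table([[1]] * 5)
        with pytest.raises(ValueError):
            temporal_sta(t, stim, order=2, spacing=1)


class TestCensusAndHistogram:
    def test_single_state_has_fraction_one(self):
        c = mode_census(_table([[1, 0]] * 7))
        assert len(c) == 1 and c.fraction.iloc[0] == 1.0

    def test_fractions_sum_to_one(self, rng):
        c = mode_census(_table(rng.integers(0, 2, (50, 4)).astype(bool)))
        assert c.fraction.sum() == pytest.approx(1.0)
        assert (c["count"].diff().dropna() <= 0).all()  # sorted descending

    def test_distinct_states_bounded_by_unit_count(self, rng):
        c = mode_census(_table(rng.integers(0, 2, (200, 3)).astype(bool)))
        assert len(c) <= 2**3

    def test_histogram_point_mass_for_single_label_state(self, stim):
        labels = np.array(["a"] * 10 + ["b"] * 20)
        states = np.zeros((30, 1), dtype=bool)
        states[:10, 0] = True
        t = _table(states)
        hist = state_stimulus_histogram(t, labels, 1)
        assert list(hist.index) == ["a"] and hist.iloc[0] == 10

    def test_histogram_counts_sum_to_occupancy(self, rng, stim):
        labels = rng.integers(0, 4, 30)
        t = _table(rng.integers(0, 2, (30, 2)).astype(bool))
        census = mode_census(t)
        sid = int(census.state_id.iloc[0])
        hist = state_stimulus_histogram(t, labels, sid)
        assert hist.sum() == census["count"].iloc[0]


class TestBestFrameMatch:
    def test_exact_frame_scores_unit_correlation(self, stim):
        idx, r = best_frame_match(stim.frames[7], stim.frames)
        assert r == pytest.approx(1.0)
        assert np.array_equal(stim.frames[idx], stim.frames[7])
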