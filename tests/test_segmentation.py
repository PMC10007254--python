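"""Windowing arithmetic, epileptic-state interval construction, labeling by
containment, the R&K→AASM map, and seeded balancing — all with brute-force
or closed-form oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from crossphys.segmentation import (
    EPILEPTIC_STATES,
    INTERICTAL,
    PREICTAL_BANDS,
    SEIZURE_WINDOWS,
    SLEEP_WINDOWS,
    WindowRule,
    balance_states,
    build_state_map,
    label_windows,
    map_hypnogram_to_aasm,
    map_rk_to_aasm,
    slice_windows,
)
from crossphys.signal_io import Hypnogram, Recording


def _rec(n_samples, fs=1.0, seed=0):
    rng = np.random.default_rng(seed)
    return Recording(signal=rng.standard_normal((1, n_samples)), fs_hz=fs, channel_names=["x"])


class TestSliceWindows:
    @pytest.mark.parametrize(
        "dur_s,rule,expected",
        [
            (600, SEIZURE_WINDOWS, 296),  # 10-s windows, 8-s overlap
            (300, SLEEP_WINDOWS, 37),  # 30-s windows, 22.5-s overlap
            (10, SEIZURE_WINDOWS, 1),
            (9, SEIZURE_WINDOWS, 0),
        ],
    )
    def test_window_counts_match_closed_form(self, dur_s, rule, expected):
        fs = 16.0
        out = slice_windows(_rec(int(dur_s * fs), fs=fs), rule)
        assert len(out) == expected

    def test_single_window_when_exact_fit_no_overlap(self):
        out = slice_windows(_rec(100, fs=10.0), WindowRule(window_s=10.0, overlap_s=0.0))
        assert len(out) == 1

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(length=st.integers(30, 5000), window=st.integers(10, 100), step=st.integers(1, 50))
    def test_count_formula_randomized(self, length, window, step):
        if step >= window or length < window:
            return
        rule = WindowRule(window_s=float(window), overlap_s=float(window - step))
        out = slice_windows(_rec(length, fs=1.0), rule)
        assert len(out) == (length - window) // step + 1
        assert np.allclose(np.diff(out.start_s), step)

    def test_window_content_reconstructs_source(self):
        rec = _rec(200, fs=4.0, seed=1)
        rule = WindowRule(window_s=5.0, overlap_s=3.0)
        out = slice_windows(rec, rule)
        for k in (0, 3, len(out) - 1):
            i0 = int(out.start_s[k] * rec.fs_hz)
            assert np.array_equal(out.windows[k], rec.signal[0, i0 : i0 + 20])

    def test_overlap_bounds(self):
        with pytest.raises(ValueError):
            WindowRule(window_s=10.0, overlap_s=10.0)


class TestStateMap:
    def test_single_onset_band_positions(self):
        m = build_state_map((3600.0,), duration_s=3700.0)
        assert m["preictal_20_10"] == ((2400.0, 3000.0),)
        assert m["preictal_30_20"] == ((1800.0, 2400.0),)
        assert m["preictal_40_30"] == ((1200.0, 1800.0),)
        assert m[INTERICTAL] == ((0.0, 600.0),)  # 3600 - 3000

    def test_early_onset_clips_bands_empty(self):
        m = build_state_map((1500.0,), duration_s=2000.0)
        assert m["preictal_40_30"] == ()  # [-900, -300) clipped away
        assert m["preictal_30_20"] == ((0.0, 300.0),)

    def test_two_onsets_interictal_interval_arithmetic(self):
        m = build_state_map((0.0, 7200.0), duration_s=7200.0)
        assert m[INTERICTAL] == ((0.0, 4200.0),)
        assert m["preictal_40_30"] == ((4800.0, 5400.0),)

    def test_states_never_overlap_and_respect_gap_rule(self):
        # brute-force membership oracle on a 1-s grid
        onsets = (3000.0, 9500.0, 16000.0)
        dur = 18000.0
        m = build_state_map(onsets, duration_s=dur)
        for t in np.arange(0.0, dur, 7.0):
            hits = [s for s in EPILEPTIC_STATES for a, b in m[s] if a <= t < b]
            assert len(hits) <= 1
            if hits and hits[0] == INTERICTAL:
                next_onsets = [o for o in onsets if o > t]
                assert next_onsets and next_onsets[0] - t >= 3000.0
        for band, lo, hi in (("preictal_20_10", 1200, 600), ("preictal_30_20", 1800, 1200), ("preictal_40_30", 2400, 1800)):
            for a, b in m[band]:
                onset = next(o for o in onsets if o >= b)
                assert a >= onset - lo and b <= onset - hi


class TestLabelWindows:
    def test_window_inside_band_gets_band_label(self):
        rec = _rec(3700, fs=1.0)
        windows = slice_windows(rec, WindowRule(window_s=10.0, overlap_s=8.0))
        m = build_state_map((3600.0,), duration_s=3700.0)
        labeled = label_windows(windows, m, subject_id="p1", dataset_tag="d1")
        k = np.searchsorted(windows.start_s, 2400.0)
        assert windows.start_s[k] == 2400.0
        row = np.nonzero(labeled.windows[:, 0] == windows.windows[k, 0])[0]
        lab = labeled.labels[np.nonzero([np.array_equal(w, windows.windows[k]) for w in labeled.windows])[0][0]]
        assert lab == "preictal_20_10"

    def test_straddling_windows_dropped(self):
        rec = _rec(100, fs=1.0)
        windows = slice_windows(rec, WindowRule(window_s=10.0, overlap_s=5.0))
        hyp = Hypnogram(("W",) * 2 + ("N2",), epoch_s=30.0)  # boundary at 60 s
        labeled = label_windows(windows, hyp)
        starts_kept = []
        for w in labeled.windows:
            k = next(i for i in range(len(windows)) if np.array_equal(windows.windows[i], w))
            starts_kept.append(windows.start_s[k])
        # no kept window may straddle 60 s
        assert all(not (s < 60 < s + 10) for s in starts_kept)

    def test_counts_match_brute_force_containment(self):
        rec = _rec(20000, fs=1.0, seed=2)
        windows = slice_windows(rec, WindowRule(window_s=10.0, overlap_s=8.0))
        m = build_state_map((9000.0, 19000.0), duration_s=20000.0)
        labeled = label_windows(windows, m)
        brute = {}
        for s in EPILEPTIC_STATES:
            n = 0
            for start in windows.start_s:
                if any(a <= start and start + 10.0 <= b for a, b in m[s]):
                    n += 1
            if n:
                brute[s] = n
        assert labeled.label_counts == brute


class TestRkToAasm:
    @pytest.mark.parametrize(
        "rk,aasm",
        [("W", "W"), ("S1", "N1"), ("S2", "N2"), ("S3", "N3"), ("S4", "N3"), ("REM", "REM")],
    )
    def test_mapping(self, rk, aasm):
        assert map_rk_to_aasm(rk) == aasm

    def test_movement_drops(self):
        assert map_rk_to_aasm("MOVEMENT") == "DROP"

    def test_idempotent_on_aasm(self):
        for s in ("W", "N1", "N2", "N3", "REM"):
            assert map_rk_to_aasm(map_rk_to_aasm(s)) == map_rk_to_aasm(s)

    def test_unknown_code(self):
        with pytest.raises(ValueError, match="S9"):
            map_rk_to_aasm("S9")

    def test_hypnogram_mapping_preserves_grid(self):
        hyp = Hypnogram(("W", "S1", "S3", "S4", "MOVEMENT", "REM"), epoch_s=30.0)
        mapped = map_hypnogram_to_aasm(hyp)
        assert mapped.stages == ("W", "N1", "N3", "N3", "DROP", "REM")
        assert mapped.epoch_s == 30.0


class TestBalanceStates:
    def _epochs(self, counts, seed=0):
        rng = np.random.default_rng(seed)
        labels = np.concatenate([[s] * n for s, n in counts.items()])
        n = len(labels)
        from crossphys.signal_io import EpochSet

        return EpochSet(
            windows=rng.standard_normal((n, 8)).astype(np.float32),
            labels=labels,
            groups=np.full(n, "g"),
            dataset_tags=np.full(n, "d"),
            fs_hz=1.0,
            window_s=8.0,
        )

    def test_counts_equalized(self):
        ep = self._epochs({"a": 100, "b": 80, "c": 90})
        out = balance_states(ep, per_state_n=80, seed=1)
        assert out.label_counts == {"a": 80, "b": 80, "c": 80}

    def test_default_uses_minimum(self):
        ep = self._epochs({"a": 100, "b": 80})
        assert balance_states(ep, seed=0).label_counts == {"a": 80, "b": 80}

    def test_seed_reproducible_and_subset(self):
        ep = self._epochs({"a": 50, "b": 60})
        out1 = balance_states(ep, per_state_n=30, seed=5)
        out2 = balance_states(ep, per_state_n=30, seed=5)
        assert np.array_equal(out1.windows, out2.windows)
        # every selected window exists exactly once in the source
        src = {w.tobytes() for w in ep.windows}
        sel = [w.tobytes() for w in out1.windows]
        assert set(sel) <= src and len(sel) == len(set(sel))

    def test_missing_state_named(self):
        ep = self._epochs({"a": 10})
        with pytest.raises(ValueError, match="b"):
            balance_states(ep, expected_states=("a", "b"))

    def test_oversized_request_rejected(self):
        ep = self._epochs({"a": 10, "b": 5})
        with pytest.raises(ValueError):
            balance_states(ep, per_state_n=8)
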