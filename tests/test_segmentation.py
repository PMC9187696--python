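"""Window cutting, reference sampling, region averaging, resampling."""

import dataclasses

import numpy as np
import pytest

from ierp import (
    SegmentationConfig,
    average_by_region,
    resample_windows,
    sample_reference_windows,
    segment_windows,
)


class TestSegmentWindows:
    def test_sample_index_mapping(self, simple_recording, marker_track):
        rec = simple_recording(np.arange(2048.0)[None, :], fs=256.0)
        stack = segment_windows(rec, marker_track([1.0]))
        assert stack.n_samples == 205
        np.testing.assert_array_equal(stack.data[0, 0], np.arange(205.0, 410.0))
        assert stack.rel_time_axis[51] == 0.0

    def test_edge_marker_dropped(self, simple_recording, marker_track):
        rec = simple_recording(np.zeros((1, 2048)), fs=256.0)
        stack = segment_windows(rec, marker_track([0.05, 1.0]))
        assert stack.n_windows == 1 and stack.n_dropped_edge == 1

    def test_no_full_window_errors(self, simple_recording, marker_track):
        rec = simple_recording(np.zeros((1, 100)), fs=256.0)
        with pytest.raises(ValueError, match="window"):
            segment_windows(rec, marker_track([0.05]))

    def test_zero_recording_gives_zero_windows(self, simple_recording, marker_track):
        rec = simple_recording(np.zeros((2, 2048)), fs=256.0)
        stack = segment_windows(rec, marker_track([1.0, 2.0]))
        assert not np.any(stack.data)


class TestReferenceSampling:
    def test_avoids_onset_half(self, simple_recording, marker_track):
        rng = np.random.default_rng(0)
        rec = simple_recording(rng.normal(size=(1, 90 * 256)), fs=256.0)
        onsets = marker_track(np.arange(1.0, 44.0, 1.0))
        cfg = SegmentationConfig(n_reference=20, seed=1)
        ref = sample_reference_windows(rec, onsets, cfg)
        assert ref.n_windows == 20
        # windows [-0.2, +0.6] around onsets at 1..43 s; all refs must sit later
        assert ref.source_marker_times.min() > 43.0

    def test_disjoint_at_zero_relaxation(self, simple_recording, marker_track):
        rng = np.random.default_rng(1)
        rec = simple_recording(rng.normal(size=(1, 90 * 256)), fs=256.0)
        onsets = marker_track(np.arange(2.0, 88.0, 2.0))
        cfg = SegmentationConfig(n_reference=30, seed=2)
        ref = sample_reference_windows(rec, onsets, cfg)
        assert ref.info["overlap_fraction_note"] == 0.0
        spans = ref.window_spans(0.2)
        for t in onsets.times_s:
            assert not np.any((spans[:, 0] <= t + 0.6) & (spans[:, 1] >= t - 0.2))

    def test_dense_onsets_error_without_relaxation(
        self, simple_recording, marker_track
    ):
        rng = np.random.default_rng(2)
        rec = simple_recording(rng.normal(size=(1, 30 * 256)), fs=256.0)
        onsets = marker_track(np.arange(0.5, 29.0, 0.3))
        cfg = SegmentationConfig(n_reference=10, seed=3, max_note_overlap=0.0)
        with pytest.raises(ValueError, match="reference windows obtainable"):
            sample_reference_windows(rec, onsets, cfg)

    def test_deterministic(self, simple_recording, marker_track):
        rng = np.random.default_rng(3)
        rec = simple_recording(rng.normal(size=(1, 60 * 256)), fs=256.0)
        onsets = marker_track(np.arange(2.0, 30.0, 2.0))
        cfg = SegmentationConfig(n_reference=15, seed=7)
        a = sample_reference_windows(rec, onsets, cfg)
        b = sample_reference_windows(rec, onsets, cfg)
        np.testing.assert_array_equal(a.source_marker_times, b.source_marker_times)


class TestRegionAveraging:
    def test_one_channel_per_region_is_identity(self, simple_recording, marker_track):
        rng = np.random.default_rng(4)
        rec = simple_recording(
            rng.normal(size=(2, 2048)), fs=256.0,
            regions=["superior temporal", "insular"],
        )
        stack = segment_windows(rec, marker_track([1.0, 3.0]))
        out = average_by_region(stack)
        np.testing.assert_array_equal(out["superior temporal"].windows,
                                      stack.data[:, 0, :])

    def test_opposite_channels_cancel(self, simple_recording, marker_track):
        rng = np.random.default_rng(5)
        x = rng.normal(size=2048)
        rec = simple_recording(np.vstack([x, -x]), fs=256.0)
        stack = segment_windows(rec, marker_track([1.0]))
        out = average_by_region(stack)
        np.testing.assert_allclose(out["superior temporal"].windows, 0, atol=1e-12)

    def test_constant_channels_average(self, simple_recording, marker_track):
        data = np.vstack([np.full(2048, v) for v in (1.0, 2.0, 3.0)])
        rec = simple_recording(data, fs=256.0)
        stack = segment_windows(rec, marker_track([1.0]))
        out = average_by_region(stack)
        np.testing.assert_allclose(out["superior temporal"].windows, 2.0)

    def test_empty_region_omitted(self, simple_recording, marker_track):
        rec = simple_recording(np.zeros((1, 2048)), fs=256.0)
        stack = segment_windows(rec, marker_track([1.0]))
        out = average_by_region(stack, regions=["superior temporal", "insular"])
        assert "insular" not in out and "superior temporal" in out

    def test_region_and_window_averaging_commute(
        self, simple_recording, marker_track
    ):
        rng = np.random.default_rng(6)
        rec = simple_recording(rng.normal(size=(4, 4096)), fs=256.0)
        stack = segment_windows(rec, marker_track([1.0, 3.0, 5.0, 7.0]))
        ws = average_by_region(stack)["superior temporal"]
        direct = stack.data.mean(axis=1).mean(axis=0)  # region-mean then window-mean
        np.testing.assert_allclose(ws.windows.mean(axis=0), direct, atol=1e-10)


class TestResampleWindows:
    def test_count_contract(self, make_window_set):
        ws = make_window_set(np.random.default_rng(0).normal(size=(44, 205)))
        assert resample_windows(ws, 200, seed=1).n_windows == 200

    def test_single_window_repeats(self, make_window_set):
        ws = make_window_set(np.ones((1, 205)))
        out = resample_windows(ws, 200, seed=2)
        assert out.n_windows == 200
        np.testing.assert_array_equal(out.source_indices, np.zeros(200, int))

    def test_deterministic(self, make_window_set):
        ws = make_window_set(np.random.default_rng(1).normal(size=(10, 50)))
        a = resample_windows(ws, 30, seed=5)
        b = resample_windows(ws, 30, seed=5)
        np.testing.assert_array_equal(a.windows, b.windows)

    def test_empty_errors(self, make_window_set):
        ws = make_window_set(np.empty((0, 205)))
        with pytest.raises(ValueError, match="empty"):
            resample_windows(ws, 200, seed=0)
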