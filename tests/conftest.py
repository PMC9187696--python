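import numpy as np
import pytest

from ierp import SyntheticSessionSpec
from ierp.containers import ErpWindowSet, MarkerTrack, Recording


@pytest.fixture
def two_region_spec():
    """Small but non-degenerate session: two subregions, short duration."""
    def make(seed=0, **overrides):
        kwargs = dict(
            seed=seed,
            duration_s=40.0,
            region_names=("superior temporal", "rostral middle frontal"),
            n_channels_per_region=3,
            n_phrase_boundaries=4,
            ied_rate_hz=0.0,
        )
        kwargs.update(overrides)
        return SyntheticSessionSpec(**kwargs)
    return make


@pytest.fixture
def make_window_set():
    def make(windows, condition="note_onset", region="superior temporal", fs=256.0):
        windows = np.asarray(windows, dtype=float)
        return ErpWindowSet(
            windows=windows,
            rel_time_axis=(np.arange(windows.shape[1]) - windows.shape[1] // 4) / fs,
            condition=condition,
            region=region,
            source_marker_times=np.arange(windows.shape[0], dtype=float),
            fs=fs,
        )
    return make


@pytest.fixture
def simple_recording():
    def make(data, fs=256.0, regions=None):
        data = np.asarray(data, dtype=float)
        n = data.shape[0]
        if regions is None:
            regions = ["superior temporal"] * n
        return Recording(
            data=data,
            fs=fs,
            channel_labels=[f"ch{i}" for i in range(n)],
            channel_regions=regions,
        )
    return make


@pytest.fixture
def marker_track():
    def make(times, kind="note_onset", strengths=None):
        return MarkerTrack(
            times_s=np.asarray(times, dtype=float), kind=kind,
            strengths=None if strengths is None else np.asarray(strengths, float),
        )
    return make
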