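"""Core data containers shared across the analysis pipeline.

The pipeline operates on three kinds of objects:

* :class:`Recording` — a multichannel iEEG signal matrix with per-channel
  cortical subregion labels,
* :class:`MarkerTrack` — an ordered list of stimulus event times (note
  onsets, phrase boundaries, or reference positions),
* :class:`ErpWindowSet` / :class:`ChannelWindowStack` — stacks of
  equal-length peri-stimulus windows sharing a relative time axis.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

#: Cortical subregions used for region-level averaging.  These are the
#: eight Desikan–Killiany-style subregions in which depth-electrode
#: contacts were grouped; anything else maps to "other".
SUBREGIONS: tuple[str, ...] = (
    "middle temporal",
    "superior temporal",
    "rostral anterior cingulate",
    "rostral middle frontal",
    "medial orbitofrontal",
    "superior frontal",
    "insular",
    "caudal middle frontal",
)

OTHER_REGION = "other"

MARKER_KINDS = ("note_onset", "phrase_boundary", "reference")

#: Default peri-stimulus window: 200 ms before to 600 ms after the marker.
PRE_MS_DEFAULT = 200.0
POST_MS_DEFAULT = 600.0


def window_sample_counts(fs: float, pre_ms: float, post_ms: float) -> tuple[int, int]:
    """Number of samples before/after the window centre.

    Sample counts are floored so the contract is exact: at 256 Hz with the
    default 200/600 ms window this yields (51, 153) and a total window
    length of 205 samples (centre sample included).
    """
    pre = int(np.floor(pre_ms * fs / 1000.0))
    post = int(np.floor(post_ms * fs / 1000.0))
    return pre, post


def relative_time_axis(fs: float, pre_ms: float, post_ms: float) -> np.ndarray:
    """Relative time axis in seconds, zero at the marker sample."""
    pre, post = window_sample_counts(fs, pre_ms, post_ms)
    return np.arange(-pre, post + 1) / fs


@dataclass
class Recording:
    """A multichannel iEEG recording in physical units (microvolts).

    Parameters
    ----------
    data : ndarray, shape (n_channels, n_samples)
        Signal matrix in µV.
    fs : float
        Sampling rate in Hz.
    channel_labels : list of str
        One label per row of ``data``.
    channel_regions : list of str
        Cortical subregion per channel (one of :data:`SUBREGIONS` or
        ``"other"``).
    """

    data: np.ndarray
    fs: float
    channel_labels: list[str]
    channel_regions: list[str]
    session_id: str = ""
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("Recording.data must be 2-D (channels x samples)")
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        self.channel_labels = list(self.channel_labels)
        self.channel_regions = list(self.channel_regions)
        n = self.data.shape[0]
        if len(self.channel_labels) != n or len(self.channel_regions) != n:
            raise ValueError(
                "channel_labels/channel_regions length must equal the number "
                f"of data rows ({n}); got {len(self.channel_labels)} labels "
                f"and {len(self.channel_regions)} regions"
            )

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def copy(self) -> "Recording":
        return dataclasses.replace(
            self,
            data=self.data.copy(),
            channel_labels=list(self.channel_labels),
            channel_regions=list(self.channel_regions),
        )

    def select_channels(self, keep: Sequence[int]) -> "Recording":
        keep = list(keep)
        return dataclasses.replace(
            self,
            data=self.data[keep],
            channel_labels=[self.channel_labels[i] for i in keep],
            channel_regions=[self.channel_regions[i] for i in keep],
        )


@dataclass
class MarkerTrack:
    """Ordered stimulus event times of a single kind.

    Times are strictly ascending and nonnegative.  ``strengths`` holds the
    per-event onset-envelope magnitude (note onsets only).
    """

    times_s: np.ndarray
    kind: str
    strengths: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.times_s = np.asarray(self.times_s, dtype=float)
        if self.times_s.ndim != 1:
            raise ValueError("times_s must be 1-D")
        if self.kind not in MARKER_KINDS:
            raise ValueError(f"kind must be one of {MARKER_KINDS}, got {self.kind!r}")
        if len(self.times_s) and np.any(np.diff(self.times_s) <= 0):
            raise ValueError("marker times must be strictly ascending")
        if len(self.times_s) and self.times_s[0] < 0:
            raise ValueError("marker times must be nonnegative")
        if self.strengths is not None:
            self.strengths = np.asarray(self.strengths, dtype=float)
            if self.strengths.shape != self.times_s.shape:
                raise ValueError("strengths must match times_s in length")

    def __len__(self) -> int:
        return len(self.times_s)


@dataclass
class ErpWindowSet:
    """Stack of equal-length windows for one condition and one subregion.

    ``windows`` has shape (n_windows, n_samples); ``rel_time_axis`` runs
    from -pre to +post seconds with zero at the marker sample.
    """

    windows: np.ndarray
    rel_time_axis: np.ndarray
    condition: str
    region: str
    source_marker_times: np.ndarray
    fs: float
    source_indices: np.ndarray | None = None  # bootstrap audit trail

    def __post_init__(self) -> None:
        self.windows = np.asarray(self.windows, dtype=float)
        self.rel_time_axis = np.asarray(self.rel_time_axis, dtype=float)
        self.source_marker_times = np.asarray(self.source_marker_times, dtype=float)
        if self.windows.ndim != 2:
            raise ValueError("windows must be 2-D (n_windows x n_samples)")
        if self.windows.shape[1] != len(self.rel_time_axis):
            raise ValueError("window length must match rel_time_axis")
        if self.windows.shape[0] != len(self.source_marker_times):
            raise ValueError("one source marker time per window required")

    @property
    def n_windows(self) -> int:
        return self.windows.shape[0]

    @property
    def n_samples(self) -> int:
        return self.windows.shape[1]


@dataclass
class ChannelWindowStack:
    """Per-channel peri-stimulus windows, prior to region averaging.

    ``data`` has shape (n_windows, n_channels, n_samples).  Rejection (IED
    overlap) operates on this object so a window is dropped across *all*
    channels at once; region averaging then collapses the channel axis.
    """

    data: np.ndarray
    fs: float
    rel_time_axis: np.ndarray
    condition: str
    source_marker_times: np.ndarray
    channel_labels: list[str]
    channel_regions: list[str]
    n_dropped_edge: int = 0
    info: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("data must be 3-D (windows x channels x samples)")
        self.source_marker_times = np.asarray(self.source_marker_times, dtype=float)
        if self.data.shape[0] != len(self.source_marker_times):
            raise ValueError("one source marker time per window required")
        if self.data.shape[1] != len(self.channel_labels):
            raise ValueError("one label per channel required")

    @property
    def n_windows(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    def window_spans(self, pre_s: float) -> np.ndarray:
        """Absolute (start, end) time span of every window, in seconds."""
        n = self.n_samples
        starts = self.source_marker_times - pre_s
        return np.column_stack([starts, starts + (n - 1) / self.fs])

    def select_windows(self, keep: Sequence[int]) -> "ChannelWindowStack":
        keep = np.asarray(list(keep), dtype=int)
        return dataclasses.replace(
            self,
            data=self.data[keep],
            source_marker_times=self.source_marker_times[keep],
        )
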