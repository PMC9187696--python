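"""Stimulus-marker construction.

Two marker levels are built:

* note onsets — peak picking on an onset-strength envelope, discarding
  the weakest half of the candidates (stronger attacks evoke larger
  responses, so weak onsets are excluded from the evoked-response
  comparison);
* phrase boundaries — expert annotations on the score transferred onto
  audio time through a dynamic-time-warping (DTW) alignment of
  score-derived features with audio features.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

from .containers import MarkerTrack

VALID_STEPS = ((1, 0), (0, 1), (1, 1))


@dataclass
class WarpPath:
    """Monotone DTW alignment path between two feature sequences.

    ``pairs`` is an (L, 2) integer array of (i, j) index pairs starting at
    (0, 0) and ending at (len(A)-1, len(B)-1); successive pairs differ by
    one of the steps (1,0), (0,1), (1,1).
    """

    pairs: np.ndarray
    total_cost: float

    def __post_init__(self) -> None:
        self.pairs = np.asarray(self.pairs, dtype=int)
        if self.pairs.ndim != 2 or self.pairs.shape[1] != 2:
            raise ValueError("pairs must be (L, 2)")
        steps = np.diff(self.pairs, axis=0)
        for s in steps:
            if tuple(s) not in VALID_STEPS:
                raise ValueError(f"invalid warp step {tuple(s)}")


def pick_note_onsets(
    envelope: np.ndarray,
    fs_env: float,
    keep_fraction: float = 0.5,
    min_gap_ms: float = 50.0,
) -> MarkerTrack:
    """Pick note onsets from an onset-strength envelope.

    Candidates are strict local maxima separated by at least
    ``min_gap_ms`` (when two maxima fall closer, the larger survives).
    The ``ceil(keep_fraction * n_candidates)`` strongest candidates are
    retained, with ties broken toward the earlier peak; the default 0.5
    discards the weak half of the onsets.
    """
    envelope = np.asarray(envelope, dtype=float)
    if envelope.size == 0:
        raise ValueError("empty envelope")
    if not 0 < keep_fraction <= 1:
        raise ValueError("keep_fraction must be in (0, 1]")
    interior = np.arange(1, len(envelope) - 1)
    is_max = (envelope[interior] > envelope[interior - 1]) & (
        envelope[interior] > envelope[interior + 1]
    )
    cand = interior[is_max]
    # enforce the minimum inter-peak gap, keeping the higher peak
    min_gap = int(round(min_gap_ms * fs_env / 1000.0))
    if min_gap > 0 and len(cand) > 1:
        order = cand[np.argsort(-envelope[cand], kind="stable")]
        accepted: list[int] = []
        for idx in order:
            if all(abs(idx - a) >= min_gap for a in accepted):
                accepted.append(int(idx))
        cand = np.sort(accepted)
    if len(cand) == 0:
        return MarkerTrack(times_s=np.empty(0), kind="note_onset",
                           strengths=np.empty(0))
    n_keep = int(np.ceil(keep_fraction * len(cand)))
    # strongest first; stable sort on -strength breaks ties by earlier time
    order = np.argsort(-envelope[cand], kind="stable")[:n_keep]
    kept = np.sort(cand[order])
    return MarkerTrack(
        times_s=kept / fs_env, kind="note_onset", strengths=envelope[kept]
    )


def _local_cost_matrix(
    feat_a: np.ndarray, feat_b: np.ndarray,
    local_cost: str | Callable[[np.ndarray, np.ndarray], float] = "euclidean",
) -> np.ndarray:
    a = np.atleast_2d(np.asarray(feat_a, float))
    b = np.atleast_2d(np.asarray(feat_b, float))
    if a.shape[0] == 1 and a.ndim == 2 and np.asarray(feat_a).ndim == 1:
        a = a.T
    if b.shape[0] == 1 and b.ndim == 2 and np.asarray(feat_b).ndim == 1:
        b = b.T
    if a.shape[1] != b.shape[1]:
        raise ValueError(
            f"feature dimensionality mismatch: {a.shape[1]} vs {b.shape[1]}"
        )
    if callable(local_cost):
        c = np.empty((a.shape[0], b.shape[0]))
        for i in range(a.shape[0]):
            for j in range(b.shape[0]):
                c[i, j] = local_cost(a[i], b[j])
        return c
    diff = a[:, None, :] - b[None, :, :]
    if local_cost == "euclidean":
        return np.sqrt((diff**2).sum(axis=2))
    if local_cost == "abs":
        return np.abs(diff).sum(axis=2)
    raise ValueError(f"unknown local cost {local_cost!r}")


def dtw_align(
    feat_a: np.ndarray,
    feat_b: np.ndarray,
    local_cost: str | Callable[[np.ndarray, np.ndarray], float] = "euclidean",
    band_radius: int | None = None,
) -> WarpPath:
    """Dynamic-time-warping alignment of two feature sequences.

    Minimizes the cumulative local cost over monotone paths with steps
    (1,0), (0,1), (1,1) from (0,0) to (n-1, m-1).  ``band_radius``
    optionally restricts the search to a Sakoe-Chiba band around the
    diagonal; the default searches the full plane (the sequences aligned
    here — 90 s of audio frames — are short).
    """
    c = _local_cost_matrix(feat_a, feat_b, local_cost)
    n, m = c.shape
    if n == 0 or m == 0:
        raise ValueError("sequences must be non-empty")
    inf = np.inf
    acc = np.full((n, m), inf)
    if band_radius is not None:
        band = np.abs(
            np.arange(n)[:, None] / max(n - 1, 1) - np.arange(m)[None, :] / max(m - 1, 1)
        ) * max(n, m) <= band_radius
    else:
        band = np.ones((n, m), bool)
    acc[0, 0] = c[0, 0]
    for i in range(n):
        for j in range(m):
            if (i, j) == (0, 0) or not band[i, j]:
                continue
            best = inf
            if i > 0:
                best = min(best, acc[i - 1, j])
            if j > 0:
                best = min(best, acc[i, j - 1])
            if i > 0 and j > 0:
                best = min(best, acc[i - 1, j - 1])
            acc[i, j] = c[i, j] + best
    # backtrace, preferring the diagonal step on ties
    i, j = n - 1, m - 1
    pairs = [(i, j)]
    while (i, j) != (0, 0):
        options = []
        if i > 0 and j > 0:
            options.append((acc[i - 1, j - 1], (i - 1, j - 1)))
        if i > 0:
            options.append((acc[i - 1, j], (i - 1, j)))
        if j > 0:
            options.append((acc[i, j - 1], (i, j - 1)))
        _, (i, j) = min(options, key=lambda o: o[0])
        pairs.append((i, j))
    pairs.reverse()
    return WarpPath(pairs=np.asarray(pairs), total_cost=float(acc[n - 1, m - 1]))


def map_phrase_boundaries(
    score_times_s: np.ndarray,
    score_frame_times: np.ndarray,
    audio_frame_times: np.ndarray,
    path: WarpPath,
) -> MarkerTrack:
    """Transfer score-annotated boundary times onto audio time via a warp path.

    Each score time is assigned the audio time of the path pair whose
    score frame is nearest (first such pair when a score frame maps to a
    run of audio frames); the output is sorted and deduplicated.
    """
    score_times_s = np.atleast_1d(np.asarray(score_times_s, float))
    score_frame_times = np.asarray(score_frame_times, float)
    audio_frame_times = np.asarray(audio_frame_times, float)
    if path.pairs[:, 0].max() >= len(score_frame_times) or path.pairs[:, 1].max() >= len(
        audio_frame_times
    ):
        raise ValueError("warp path indices exceed the frame grids")
    lo, hi = score_frame_times[0], score_frame_times[-1]
    out = []
    for t in score_times_s:
        if not lo <= t <= hi:
            raise ValueError(
                f"score time {t} s outside the score grid [{lo}, {hi}] s"
            )
        i = int(np.argmin(np.abs(score_frame_times - t)))
        hit = np.flatnonzero(path.pairs[:, 0] == i)
        j = int(path.pairs[hit[0], 1])
        out.append(audio_frame_times[j])
    times = np.unique(np.asarray(out))
    return MarkerTrack(times_s=times, kind="phrase_boundary")
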