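"""Peri-stimulus window segmentation, reference sampling, region
averaging and bootstrap resampling.

Windows span 200 ms before to 600 ms after each marker (205 samples at
256 Hz).  A matched set of "reference" windows of the same length is
sampled away from the note-onset windows to serve as the no-event
baseline condition, windows are averaged across channels within each
cortical subregion, and window counts are bootstrap-resampled to a common
size (200) before the statistical stage.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass

import numpy as np

from .containers import (
    ChannelWindowStack,
    ErpWindowSet,
    MarkerTrack,
    PRE_MS_DEFAULT,
    POST_MS_DEFAULT,
    Recording,
    relative_time_axis,
    window_sample_counts,
)

logger = logging.getLogger(__name__)


@dataclass
class SegmentationConfig:
    pre_ms: float = PRE_MS_DEFAULT
    post_ms: float = POST_MS_DEFAULT
    n_reference: int = 44
    resample_n: int = 200
    seed: int = 0
    # relaxation ceilings for reference sampling: overlap among reference
    # windows relaxes first (to max_ref_overlap), then overlap with the
    # note-onset windows (to max_note_overlap) — dense naturalistic music
    # leaves no marker-free 800 ms stretch, so the note ceiling defaults
    # open while reference windows stay mutually near-disjoint
    max_ref_overlap: float = 0.5
    max_note_overlap: float = 1.0
    overlap_step: float = 0.1
    max_attempts_per_level: int = 5000
    baseline_correct: bool = False  # subtract the prestimulus mean per window

    def validate(self) -> None:
        if self.pre_ms < 0 or self.post_ms < 0:
            raise ValueError("pre_ms and post_ms must be >= 0")
        if self.resample_n <= 0:
            raise ValueError("resample_n must be positive")


def segment_windows(
    rec: Recording, markers: MarkerTrack, cfg: SegmentationConfig | None = None
) -> ChannelWindowStack:
    """Cut per-channel peri-stimulus windows around every marker.

    For a marker at time t the centre index is ``round(t * fs)`` and the
    window spans ``[c - pre_samples, c + post_samples]`` inclusive, with
    pre/post sample counts floored from the millisecond bounds.  Markers
    whose window would run off either edge of the recording are dropped
    and counted in ``n_dropped_edge``.
    """
    cfg = cfg or SegmentationConfig()
    cfg.validate()
    pre, post = window_sample_counts(rec.fs, cfg.pre_ms, cfg.post_ms)
    centers = np.round(markers.times_s * rec.fs).astype(int)
    ok = (centers - pre >= 0) & (centers + post <= rec.n_samples - 1)
    n_dropped = int((~ok).sum())
    centers_ok = centers[ok]
    if len(centers_ok) == 0:
        raise ValueError(
            f"no {markers.kind} marker admits a full "
            f"[{-cfg.pre_ms}, {cfg.post_ms}] ms window"
        )
    idx = centers_ok[:, None] + np.arange(-pre, post + 1)[None, :]
    data = rec.data[:, idx]  # (channels, windows, samples)
    data = np.moveaxis(data, 0, 1)  # (windows, channels, samples)
    if cfg.baseline_correct and pre > 0:
        data = data - data[:, :, :pre].mean(axis=2, keepdims=True)
    return ChannelWindowStack(
        data=data,
        fs=rec.fs,
        rel_time_axis=relative_time_axis(rec.fs, cfg.pre_ms, cfg.post_ms),
        condition=markers.kind,
        source_marker_times=markers.times_s[ok],
        channel_labels=list(rec.channel_labels),
        channel_regions=list(rec.channel_regions),
        n_dropped_edge=n_dropped,
    )


def _overlap_with_intervals(
    start: float, end: float, starts: np.ndarray, ends: np.ndarray
) -> float:
    """Largest overlap (seconds) of [start, end] with any given interval."""
    if len(starts) == 0:
        return 0.0
    ov = np.minimum(end, ends) - np.maximum(start, starts)
    return float(max(0.0, ov.max()))


def sample_reference_windows(
    rec: Recording, note_onsets: MarkerTrack, cfg: SegmentationConfig | None = None
) -> ChannelWindowStack:
    """Randomly sample no-event reference windows of the peri-stimulus length.

    Candidate window centres are drawn uniformly over the recording
    (seeded).  A candidate is accepted when its window overlaps every
    note-onset peri-stimulus window and every previously accepted
    reference window by at most an allowed fraction of the window length.
    Both allowed fractions start at 0 — reference windows strictly
    disjoint from onset windows and from each other.  If the target count
    is not reached within the attempt budget, the reference-vs-reference
    fraction is relaxed in steps of ``overlap_step`` up to
    ``max_ref_overlap``, and only then the reference-vs-note fraction up
    to ``max_note_overlap`` ("as little overlapping as possible"); every
    relaxation is logged and the final levels recorded in the result's
    ``info``.
    """
    cfg = cfg or SegmentationConfig()
    cfg.validate()
    pre_s = cfg.pre_ms / 1000.0
    post_s = cfg.post_ms / 1000.0
    win_s = pre_s + post_s
    if rec.duration_s <= win_s:
        raise ValueError("recording shorter than one reference window")
    note_starts = note_onsets.times_s - pre_s
    note_ends = note_onsets.times_s + post_s
    rng = np.random.default_rng(cfg.seed)

    accepted: list[float] = []  # window centre times
    step = cfg.overlap_step
    ref_levels = np.arange(0.0, cfg.max_ref_overlap + 1e-9, step)
    note_levels = np.arange(step, cfg.max_note_overlap + 1e-9, step)
    schedule = [(f, 0.0) for f in ref_levels]
    schedule += [(float(ref_levels[-1]), float(f)) for f in note_levels]
    frac_ref = frac_note = 0.0
    for frac_ref, frac_note in schedule:
        attempts = 0
        while len(accepted) < cfg.n_reference and attempts < cfg.max_attempts_per_level:
            attempts += 1
            t = float(rng.uniform(pre_s, rec.duration_s - post_s))
            s, e = t - pre_s, t + post_s
            if _overlap_with_intervals(s, e, note_starts, note_ends) > frac_note * win_s:
                continue
            acc = np.asarray(accepted)
            if _overlap_with_intervals(s, e, acc - pre_s, acc + post_s) > frac_ref * win_s:
                continue
            accepted.append(t)
        if len(accepted) >= cfg.n_reference:
            break
        logger.info(
            "reference sampling: %d/%d accepted at overlap fractions "
            "ref=%.1f note=%.1f; relaxing",
            len(accepted), cfg.n_reference, frac_ref, frac_note,
        )
    if len(accepted) < 2:
        raise ValueError(
            f"only {len(accepted)} reference windows obtainable "
            f"(target {cfg.n_reference}) even at overlap fractions "
            f"ref={frac_ref:.1f} note={frac_note:.1f}"
        )
    track = MarkerTrack(times_s=np.sort(np.asarray(accepted)), kind="reference")
    stack = segment_windows(rec, track, cfg)
    stack.info["overlap_fraction_ref"] = float(frac_ref)
    stack.info["overlap_fraction_note"] = float(frac_note)
    stack.info["n_requested"] = cfg.n_reference
    return stack


def average_by_region(
    stack: ChannelWindowStack, regions: list[str] | None = None
) -> dict[str, ErpWindowSet]:
    """Average windows across channels within each cortical subregion.

    Returns one :class:`ErpWindowSet` per subregion present in the stack;
    a requested region with zero channels is omitted (and logged).
    """
    region_arr = np.asarray(stack.channel_regions)
    if regions is None:
        regions = list(dict.fromkeys(stack.channel_regions))
    out: dict[str, ErpWindowSet] = {}
    for region in regions:
        rows = np.flatnonzero(region_arr == region)
        if len(rows) == 0:
            logger.warning("region %r has no channels; omitted", region)
            continue
        out[region] = ErpWindowSet(
            windows=stack.data[:, rows, :].mean(axis=1),
            rel_time_axis=stack.rel_time_axis,
            condition=stack.condition,
            region=region,
            source_marker_times=stack.source_marker_times,
            fs=stack.fs,
        )
    return out


def resample_windows(ws: ErpWindowSet, n: int, seed: int = 0) -> ErpWindowSet:
    """Bootstrap-resample a window set to exactly ``n`` windows.

    Draws uniformly with replacement (the same rule whether up- or
    down-sampling); the drawn source indices are retained for audit.
    """
    if ws.n_windows == 0:
        raise ValueError("cannot resample an empty window set")
    if n <= 0:
        raise ValueError("n must be positive")
    idx = np.random.default_rng(seed).integers(0, ws.n_windows, size=n)
    return dataclasses.replace(
        ws,
        windows=ws.windows[idx],
        source_marker_times=ws.source_marker_times[idx],
        source_indices=idx,
    )
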