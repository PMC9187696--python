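"""End-to-end session and study orchestration.

``run_session`` composes the stages in the acquisition-analysis order:
bad-channel exclusion -> filtering/re-referencing/decimation ->
peri-stimulus segmentation and reference sampling -> IED rejection ->
region averaging -> bootstrap resampling -> cluster-level permutation
tests for the three comparisons (note onset vs reference, phrase
boundary vs reference, phrase boundary vs note onset) in every
subregion.  ``run_study`` repeats this per session and integrates the
results by counting significant sessions.
"""

from __future__ import annotations

import dataclasses
import logging
import zlib
from dataclasses import dataclass, field, fields

import numpy as np

from .cluster import ClusterTestConfig, ClusterTestResult, cluster_permutation_test
from .containers import MarkerTrack, Recording
from .ied import IedTemplate, detect_ieds, reject_windows
from .integrate import IntegrationResult, integrate_sessions
from .preprocess import PreprocessConfig, exclude_bad_channels, preprocess_recording
from .segmentation import (
    SegmentationConfig,
    average_by_region,
    resample_windows,
    sample_reference_windows,
    segment_windows,
)
from .synthetic import default_ied_template

logger = logging.getLogger(__name__)

COMPARISONS = (
    ("note_onset", "reference"),
    ("phrase_boundary", "reference"),
    ("phrase_boundary", "note_onset"),
)


@dataclass
class IedRejectConfig:
    enabled: bool = True
    r_threshold: float = 0.8
    two_sided: bool = False
    detection_highpass_hz: float | None = 12.0


@dataclass
class IntegrationConfig:
    n_light: int = 6
    n_dark: int = 10


@dataclass
class PipelineConfig:
    """Nested configuration for the full pipeline; JSON round-trippable."""

    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    segmentation: SegmentationConfig = field(default_factory=SegmentationConfig)
    ied: IedRejectConfig = field(default_factory=IedRejectConfig)
    stats: ClusterTestConfig = field(default_factory=ClusterTestConfig)
    integration: IntegrationConfig = field(default_factory=IntegrationConfig)
    seed: int = 0

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        def build(tp, payload, ctx):
            if not isinstance(payload, dict):
                raise ValueError(f"section {ctx!r} must be a mapping")
            names = {f.name: f for f in fields(tp)}
            unknown = set(payload) - set(names)
            if unknown:
                raise ValueError(f"unknown config key(s) in {ctx!r}: {sorted(unknown)}")
            return tp(**payload)

        names = {f.name for f in fields(cls)}
        unknown = set(d) - names
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        kwargs: dict = {}
        section_types = {
            "preprocess": PreprocessConfig,
            "segmentation": SegmentationConfig,
            "ied": IedRejectConfig,
            "stats": ClusterTestConfig,
            "integration": IntegrationConfig,
        }
        for k, v in d.items():
            if k in section_types:
                kwargs[k] = build(section_types[k], v, k)
            else:
                kwargs[k] = v
        return cls(**kwargs)


@dataclass
class SessionResult:
    session_id: str
    results: dict[tuple[str, str], dict[str, ClusterTestResult]]
    excluded_channels: list[str]
    window_counts: dict[str, dict[str, int]]
    n_ied_detections: int

    def to_dict(self) -> dict:
        return {
            "session_id": self.session_id,
            "excluded_channels": self.excluded_channels,
            "window_counts": self.window_counts,
            "n_ied_detections": self.n_ied_detections,
            "comparisons": {
                f"{a}_vs_{b}": {
                    region: r.to_dict() for region, r in by_region.items()
                }
                for (a, b), by_region in self.results.items()
            },
        }


def _subseed(base_seed: int, *tags: str) -> int:
    """Stable derived seed below 2^31 for a named pipeline stage."""
    h = np.random.SeedSequence(
        [base_seed] + [zlib.crc32(t.encode()) for t in tags]
    )
    return int(h.generate_state(1)[0] % (2**31))


def run_session(
    rec_raw: Recording,
    note_onsets: MarkerTrack,
    phrase_boundaries: MarkerTrack,
    config: PipelineConfig | None = None,
    ied_templates: list[IedTemplate] | None = None,
    session_id: str | None = None,
) -> SessionResult:
    """Run the full within-session analysis.

    Stages: exclude_bad_channels -> preprocess_recording ->
    segment_windows (+ reference sampling) -> reject_windows ->
    average_by_region -> resample_windows -> cluster_permutation_test for
    the three condition pairs per subregion.
    """
    config = config or PipelineConfig()
    config.preprocess.validate()
    config.segmentation.validate()
    config.stats.validate()
    session_id = session_id or rec_raw.session_id or "session"

    rec, excluded = exclude_bad_channels(rec_raw, config.preprocess.bad_channel_k)
    rec = preprocess_recording(rec, config.preprocess)

    seg_cfg = dataclasses.replace(
        config.segmentation, seed=_subseed(config.seed, session_id, "reference")
    )
    stacks = {
        "note_onset": segment_windows(rec, note_onsets, seg_cfg),
        "phrase_boundary": segment_windows(rec, phrase_boundaries, seg_cfg),
        "reference": sample_reference_windows(rec, note_onsets, seg_cfg),
    }

    n_dets = 0
    if config.ied.enabled:
        if ied_templates is None:
            ied_templates = [
                IedTemplate(waveform=default_ied_template(rec.fs), fs=rec.fs)
            ]
        dets = detect_ieds(
            rec, ied_templates, config.ied.r_threshold, config.ied.two_sided,
            config.ied.detection_highpass_hz,
        )
        n_dets = len(dets)
        if dets:
            for cond in stacks:
                stacks[cond], n_rej = reject_windows(stacks[cond], dets)
                logger.info(
                    "%s: rejected %d %s windows with IEDs", session_id, n_rej, cond
                )

    window_counts: dict[str, dict[str, int]] = {}
    region_sets: dict[str, dict[str, object]] = {}
    source_sets: dict[str, dict[str, object]] = {}
    for cond, stack in stacks.items():
        window_counts[cond] = {
            "segmented": stack.n_windows + stack.n_dropped_edge,
            "after_rejection": stack.n_windows,
            "resampled": config.segmentation.resample_n,
        }
        per_region = average_by_region(stack)
        source_sets[cond] = per_region
        region_sets[cond] = {
            region: resample_windows(
                ws,
                config.segmentation.resample_n,
                seed=_subseed(config.seed, session_id, "resample", cond, region),
            )
            for region, ws in per_region.items()
        }

    results: dict[tuple[str, str], dict[str, ClusterTestResult]] = {}
    for cond_a, cond_b in COMPARISONS:
        by_region: dict[str, ClusterTestResult] = {}
        for region in region_sets[cond_a]:
            if region not in region_sets[cond_b]:
                continue
            stats_cfg = dataclasses.replace(
                config.stats,
                seed=_subseed(config.seed, session_id, "perm", cond_a, cond_b, region),
            )
            by_region[region] = cluster_permutation_test(
                region_sets[cond_a][region],
                region_sets[cond_b][region],
                stats_cfg,
                source_a=source_sets[cond_a][region],
                source_b=source_sets[cond_b][region],
            )
        results[(cond_a, cond_b)] = by_region

    return SessionResult(
        session_id=session_id,
        results=results,
        excluded_channels=excluded,
        window_counts=window_counts,
        n_ied_detections=n_dets,
    )


@dataclass
class StudyResult:
    sessions: list[SessionResult]
    integrations: dict[tuple[str, str], IntegrationResult]
    failures: dict[str, str]


def run_study(
    sessions: list[tuple[Recording, MarkerTrack, MarkerTrack]],
    config: PipelineConfig | None = None,
    ied_templates: list[IedTemplate] | None = None,
) -> StudyResult:
    """Run every session and integrate the per-region results.

    Per-session failures are recorded and the study continues with the
    remaining sessions; an empty session list (or all sessions failing)
    raises.
    """
    if not sessions:
        raise ValueError("need at least one session")
    config = config or PipelineConfig()
    session_results: list[SessionResult] = []
    failures: dict[str, str] = {}
    for i, (rec, notes, phrases) in enumerate(sessions):
        sid = rec.session_id or f"session-{i}"
        try:
            session_results.append(
                run_session(rec, notes, phrases, config, ied_templates, sid)
            )
        except Exception as exc:  # noqa: BLE001 - reported to the caller
            logger.error("session %s failed: %s", sid, exc)
            failures[sid] = str(exc)
    if not session_results:
        raise ValueError(f"all sessions failed: {failures}")
    integrations = {}
    for pair in COMPARISONS:
        per_session = [s.results[pair] for s in session_results]
        integrations[pair] = integrate_sessions(
            per_session,
            pair[0],
            pair[1],
            n_light=config.integration.n_light,
            n_dark=config.integration.n_dark,
        )
    return StudyResult(
        sessions=session_results, integrations=integrations, failures=failures
    )
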