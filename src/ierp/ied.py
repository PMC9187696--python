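"""Interictal epileptiform discharge (IED) detection and window rejection.

Epileptic spike transients contaminate evoked-response estimates, so any
peri-stimulus window that contains at least one IED on at least one
channel is discarded.  Detection is sliding normalized cross-correlation
(Pearson r) against a bank of spike templates: local maxima of r above a
threshold are emitted, and detections closer than one template length are
merged keeping the higher score.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .containers import ChannelWindowStack, Recording


@dataclass
class IedTemplate:
    """Unit-RMS spike template at a given sampling rate."""

    waveform: np.ndarray
    fs: float
    name: str = "ied"

    def __post_init__(self) -> None:
        self.waveform = np.asarray(self.waveform, dtype=float)
        if not np.all(np.isfinite(self.waveform)):
            raise ValueError("template must be finite")
        rms = np.sqrt(np.mean(self.waveform**2))
        if rms == 0:
            raise ValueError("template must be nonzero")
        self.waveform = self.waveform / rms

    @property
    def duration_s(self) -> float:
        return len(self.waveform) / self.fs


@dataclass
class IedDetection:
    channel: str
    time_s: float  # template centre
    score: float  # normalized correlation
    half_width_s: float  # half the template extent


def _sliding_pearson(x: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Pearson r between ``w`` and every length-len(w) slice of ``x``."""
    L = len(w)
    wc = w - w.mean()
    sw = np.sqrt((wc**2).sum())
    num = signal.fftconvolve(x, wc[::-1], mode="valid")
    c1 = np.concatenate([[0.0], np.cumsum(x)])
    c2 = np.concatenate([[0.0], np.cumsum(x**2)])
    s = c1[L:] - c1[:-L]
    ss = c2[L:] - c2[:-L]
    var = ss - s**2 / L
    var = np.maximum(var, 0.0)
    denom = np.sqrt(var) * sw
    r = np.zeros_like(num)
    ok = denom > 1e-12 * max(1.0, float(np.abs(x).max())) * sw
    r[ok] = num[ok] / denom[ok]
    return np.clip(r, -1.0, 1.0)


def detect_ieds(
    rec: Recording,
    templates: list[IedTemplate],
    r_threshold: float = 0.8,
    two_sided: bool = False,
    detection_highpass_hz: float | None = 12.0,
) -> list[IedDetection]:
    """Template-matching spike detection on every channel.

    Matching runs in a spike-emphasizing band: signal and template are
    both high-passed (zero-phase, ``detection_highpass_hz``) before the
    sliding correlation, because the slow components of the intracranial
    background correlate with any short template by chance while the
    spike's sharp transient survives the high-pass.  A detection is a
    local maximum of the correlation exceeding ``r_threshold`` (matching
    the template's sign only, unless ``two_sided``).  Detections on the
    same channel closer than one template length are merged, keeping the
    higher score.
    """
    if not 0 < r_threshold <= 1:
        raise ValueError("r_threshold must be in (0, 1]")
    for tpl in templates:
        if abs(tpl.fs - rec.fs) > 1e-9:
            raise ValueError(f"template fs {tpl.fs} != recording fs {rec.fs}")
        if len(tpl.waveform) > rec.n_samples:
            raise ValueError("template longer than recording")
    data = rec.data
    if detection_highpass_hz is not None:
        sos = signal.butter(4, detection_highpass_hz, "high", fs=rec.fs,
                            output="sos")
        data = signal.sosfiltfilt(sos, data, axis=-1)
    out: list[IedDetection] = []
    for tpl in templates:
        L = len(tpl.waveform)
        half_s = (L / 2) / rec.fs
        wave = tpl.waveform
        if detection_highpass_hz is not None:
            wave = signal.sosfiltfilt(sos, wave)
            wave = wave / np.sqrt(np.mean(wave**2))
        for row, label in enumerate(rec.channel_labels):
            r = _sliding_pearson(data[row], wave)
            scores = np.abs(r) if two_sided else r
            peaks, _ = signal.find_peaks(scores, height=r_threshold)
            for p in peaks:
                out.append(
                    IedDetection(
                        channel=label,
                        time_s=(p + L // 2) / rec.fs,
                        score=float(scores[p]),
                        half_width_s=half_s,
                    )
                )
    return _merge_detections(out)


def _merge_detections(dets: list[IedDetection]) -> list[IedDetection]:
    merged: list[IedDetection] = []
    by_channel: dict[str, list[IedDetection]] = {}
    for d in dets:
        by_channel.setdefault(d.channel, []).append(d)
    for channel, ds in by_channel.items():
        ds.sort(key=lambda d: d.time_s)
        current: IedDetection | None = None
        for d in ds:
            if current is None or d.time_s - current.time_s >= 2 * d.half_width_s:
                if current is not None:
                    merged.append(current)
                current = d
            elif d.score > current.score:
                current = d
        if current is not None:
            merged.append(current)
    merged.sort(key=lambda d: (d.time_s, d.channel))
    return merged


def reject_windows(
    stack: ChannelWindowStack,
    detections: list[IedDetection],
    pre_ms: float | None = None,
    guard_s: float = 0.01,
) -> tuple[ChannelWindowStack, int]:
    """Drop every window whose absolute time span intersects a detection.

    A detection's extent is its centre time expanded by the template's
    half width plus a small guard (``guard_s``, default 10 ms) absorbing
    the correlation peak's timing jitter under noise; a window is
    rejected if that extent intersects the window's span on *any*
    channel.  Rejection runs on per-channel window stacks, before region
    averaging and before bootstrap resampling, so resampling can never
    reintroduce a rejected window.
    """
    if pre_ms is None:
        pre_s = -float(stack.rel_time_axis[0])
    else:
        pre_s = pre_ms / 1000.0
    spans = stack.window_spans(pre_s)
    bad = np.zeros(stack.n_windows, dtype=bool)
    for d in detections:
        half = d.half_width_s + guard_s
        lo, hi = d.time_s - half, d.time_s + half
        bad |= (spans[:, 0] <= hi) & (spans[:, 1] >= lo)
    if bad.all():
        raise ValueError(
            f"all {stack.n_windows} {stack.condition} windows rejected by "
            f"{len(detections)} IED detections"
        )
    keep = np.flatnonzero(~bad)
    return stack.select_windows(keep), int(bad.sum())
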