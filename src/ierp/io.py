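"""File formats.

Recordings are stored as a raw little-endian float32 matrix plus a JSON
header (shape, sampling rate, channel labels and subregions); marker
tracks and channel maps are tab-separated tables; window sets are a raw
float32 tensor with a JSON sidecar; configs and results are JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import ChannelWindowStack, ErpWindowSet, MarkerTrack, Recording
from .ied import IedDetection, IedTemplate


def save_recording(rec: Recording, path: str | Path) -> None:
    """Write ``<path>.f32`` (raw channels x samples float32) and ``<path>.json``."""
    path = Path(path)
    rec.data.astype("<f4").tofile(path.with_suffix(".f32"))
    header = {
        "format": "raw-float32-le",
        "shape": list(rec.data.shape),
        "fs_hz": rec.fs,
        "units": "uV",
        "channel_labels": rec.channel_labels,
        "channel_regions": rec.channel_regions,
        "session_id": rec.session_id,
        "subject_id": rec.subject_id,
    }
    path.with_suffix(".json").write_text(json.dumps(header, indent=1))


def load_recording(path: str | Path) -> Recording:
    path = Path(path)
    header = json.loads(path.with_suffix(".json").read_text())
    data = np.fromfile(path.with_suffix(".f32"), dtype="<f4").reshape(
        header["shape"]
    )
    return Recording(
        data=data.astype(float),
        fs=header["fs_hz"],
        channel_labels=header["channel_labels"],
        channel_regions=header["channel_regions"],
        session_id=header.get("session_id", ""),
        subject_id=header.get("subject_id", ""),
    )


def save_marker_track(track: MarkerTrack, path: str | Path) -> None:
    """Events TSV with columns onset_s, kind, strength."""
    df = pd.DataFrame(
        {
            "onset_s": track.times_s,
            "kind": track.kind,
            "strength": (
                track.strengths if track.strengths is not None
                else np.full(len(track), np.nan)
            ),
        }
    )
    df.to_csv(path, sep="\t", index=False)


def load_marker_tracks(path: str | Path) -> dict[str, MarkerTrack]:
    """Read an events TSV, returning one track per marker kind."""
    df = pd.read_csv(path, sep="\t")
    out: dict[str, MarkerTrack] = {}
    for kind, sub in df.groupby("kind"):
        sub = sub.sort_values("onset_s")
        strengths = sub["strength"].to_numpy()
        out[str(kind)] = MarkerTrack(
            times_s=sub["onset_s"].to_numpy(),
            kind=str(kind),
            strengths=None if np.all(np.isnan(strengths)) else strengths,
        )
    return out


def load_channel_map(path: str | Path) -> dict[str, str]:
    """TSV with columns label, region."""
    df = pd.read_csv(path, sep="\t")
    return dict(zip(df["label"].astype(str), df["region"].astype(str)))


def save_window_set(ws: ErpWindowSet, path: str | Path) -> None:
    path = Path(path)
    ws.windows.astype("<f4").tofile(path.with_suffix(".f32"))
    sidecar = {
        "format": "raw-float32-le",
        "shape": list(ws.windows.shape),
        "fs_hz": ws.fs,
        "condition": ws.condition,
        "region": ws.region,
        "rel_time_axis_s": ws.rel_time_axis.tolist(),
        "source_marker_times_s": ws.source_marker_times.tolist(),
        "source_indices": (
            ws.source_indices.tolist() if ws.source_indices is not None else None
        ),
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def load_window_set(path: str | Path) -> ErpWindowSet:
    path = Path(path)
    side = json.loads(path.with_suffix(".json").read_text())
    windows = np.fromfile(path.with_suffix(".f32"), dtype="<f4").reshape(
        side["shape"]
    )
    return ErpWindowSet(
        windows=windows.astype(float),
        rel_time_axis=np.asarray(side["rel_time_axis_s"]),
        condition=side["condition"],
        region=side["region"],
        source_marker_times=np.asarray(side["source_marker_times_s"]),
        fs=side["fs_hz"],
        source_indices=(
            np.asarray(side["source_indices"])
            if side.get("source_indices") is not None
            else None
        ),
    )


def save_detections(dets: list[IedDetection], path: str | Path) -> None:
    pd.DataFrame(
        {
            "channel": [d.channel for d in dets],
            "time_s": [d.time_s for d in dets],
            "score": [d.score for d in dets],
            "half_width_s": [d.half_width_s for d in dets],
        }
    ).to_csv(path, sep="\t", index=False)


def load_ied_templates(path: str | Path, fs: float) -> list[IedTemplate]:
    """Columnar numeric file: one template per column, TSV with header."""
    df = pd.read_csv(path, sep="\t")
    return [
        IedTemplate(waveform=df[c].dropna().to_numpy(), fs=fs, name=str(c))
        for c in df.columns
    ]


def save_ied_templates(templates: list[IedTemplate], path: str | Path) -> None:
    pd.DataFrame({t.name: pd.Series(t.waveform) for t in templates}).to_csv(
        path, sep="\t", index=False
    )
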