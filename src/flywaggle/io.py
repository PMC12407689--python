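"""Readers and writers for pose tracks, audio, and bout annotations.

On-disk conventions
-------------------
* Pose HDF5: datasets ``tracks`` (n_flies x 2 x n_nodes x n_frames, in
  pixels) and ``node_names``; recording metadata in root attributes.
  This mirrors the common analysis-export layout of pose trackers.
* Pose CSV: ``# key=value`` header lines carrying the metadata, then
  columns ``frame, fly_id, node, x_px, y_px`` (NaN/empty = missing).
* Audio: WAV, any PCM or float encoding, returned as float in [-1, 1].
* Bouts: CSV with columns ``recording_id, behavior, start_frame,
  end_frame, dominant_wing, provenance``.

Pixel coordinates live on disk; millimetres in memory.  The pixel->mm
conversion happens exactly once, at read, using ``meta.px_per_mm``.
"""

from __future__ import annotations

import os
from dataclasses import asdict

import h5py
import numpy as np
import pandas as pd
from scipy.io import wavfile

from .core import (
    BEHAVIORS,
    FLY_IDS,
    NODE_NAMES,
    BoutRecord,
    PoseTrack,
    RecordingMeta,
    normalize_behavior,
)

__all__ = [
    "FormatError",
    "read_pose",
    "write_pose",
    "read_audio",
    "write_audio",
    "read_bouts",
    "write_bouts",
]


class FormatError(ValueError):
    """Raised when an input file violates the declared on-disk layout."""


_META_FLOAT = {"fps", "px_per_mm"}
_META_INT = {"audio_sr", "n_frames", "n_flies"}


def _infer_format(path: str, format: str | None) -> str:
    if format is not None:
        if format not in ("hdf5", "csv"):
            raise ValueError(f"format must be 'hdf5' or 'csv', got {format!r}")
        return format
    ext = os.path.splitext(path)[1].lower()
    if ext in (".h5", ".hdf5"):
        return "hdf5"
    if ext == ".csv":
        return "csv"
    raise ValueError(f"cannot infer pose format from extension of {path!r}")


def read_pose(path: str, format: str | None = None) -> tuple[RecordingMeta, list[PoseTrack]]:
    """Read pose tracks; returns metadata and one :class:`PoseTrack` per fly.

    Coordinates are converted from pixels to mm via ``meta.px_per_mm``.
    Missing entries (NaN on disk) are flagged in the mask, never filled.
    """
    fmt = _infer_format(path, format)
    if fmt == "hdf5":
        return _read_pose_hdf5(path)
    return _read_pose_csv(path)


def _check_nodes(names: list[str]) -> None:
    for required in NODE_NAMES:
        if required not in names:
            raise FormatError(f"required node {required!r} missing from file")


def _read_pose_hdf5(path: str) -> tuple[RecordingMeta, list[PoseTrack]]:
    with h5py.File(path, "r") as f:
        if "tracks" not in f or "node_names" not in f:
            raise FormatError("pose HDF5 must contain 'tracks' and 'node_names'")
        tracks = np.asarray(f["tracks"], dtype=float)  # flies x 2 x nodes x frames
        node_names = [
            n.decode() if isinstance(n, bytes) else str(n) for n in f["node_names"][()]
        ]
        attrs = dict(f.attrs)
        fly_ids = [
            n.decode() if isinstance(n, bytes) else str(n)
            for n in attrs.pop("fly_ids", np.array(FLY_IDS[: tracks.shape[0]], dtype="S"))
        ]
    _check_nodes(node_names)
    if tracks.ndim != 4 or tracks.shape[1] != 2:
        raise FormatError(f"'tracks' must be (n_flies, 2, n_nodes, n_frames), got {tracks.shape}")
    meta = RecordingMeta(
        recording_id=str(attrs.get("recording_id", os.path.basename(path))),
        fps=float(attrs.get("fps", 150.0)),
        audio_sr=int(attrs.get("audio_sr", 10_000)),
        px_per_mm=float(attrs.get("px_per_mm", 30.3)),
        n_frames=int(tracks.shape[3]),
        n_flies=int(tracks.shape[0]),
        species_tag=str(attrs.get("species_tag", "synthetic")),
    )
    order = [node_names.index(n) for n in NODE_NAMES]
    out = []
    for i, fly in enumerate(fly_ids):
        # -> (n_frames, n_nodes, 2), mm
        coords = tracks[i][:, order, :].transpose(2, 1, 0) / meta.px_per_mm
        mask = np.isfinite(coords).all(axis=-1)
        coords = np.where(mask[..., None], coords, np.nan)
        out.append(PoseTrack(fly_id=fly, coords=coords, mask=mask))
    return meta, out


def _read_pose_csv(path: str) -> tuple[RecordingMeta, list[PoseTrack]]:
    header: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            key, _, value = line[1:].strip().partition("=")
            header[key.strip()] = value.strip()
    df = pd.read_csv(path, comment="#")
    required_cols = {"frame", "fly_id", "node", "x_px", "y_px"}
    if not required_cols.issubset(df.columns):
        raise FormatError(f"pose CSV must have columns {sorted(required_cols)}")
    nodes_present = sorted(df["node"].unique())
    _check_nodes(nodes_present)
    seen = list(dict.fromkeys(df["fly_id"]))
    # canonical male-before-female ordering regardless of row order
    fly_ids = [f for f in FLY_IDS if f in seen] + [f for f in seen if f not in FLY_IDS]
    n_frames = int(df["frame"].max()) + 1
    frames_seen = np.sort(df["frame"].unique())
    expected = np.arange(n_frames)
    if len(frames_seen) != n_frames or not np.array_equal(frames_seen, expected):
        missing = np.setdiff1d(expected, frames_seen)
        raise FormatError(f"frame index gap: first missing frame is {int(missing[0])}")
    meta = RecordingMeta(
        recording_id=header.get("recording_id", os.path.basename(path)),
        fps=float(header.get("fps", 150.0)),
        audio_sr=int(float(header.get("audio_sr", 10_000))),
        px_per_mm=float(header.get("px_per_mm", 30.3)),
        n_frames=n_frames,
        n_flies=len(fly_ids),
        species_tag=header.get("species_tag", "synthetic"),
    )
    out = []
    for fly in fly_ids:
        sub = df[df["fly_id"] == fly]
        coords = np.full((n_frames, len(NODE_NAMES), 2), np.nan)
        for j, node in enumerate(NODE_NAMES):
            rows = sub[sub["node"] == node]
            coords[rows["frame"].to_numpy(), j, 0] = rows["x_px"].to_numpy(dtype=float)
            coords[rows["frame"].to_numpy(), j, 1] = rows["y_px"].to_numpy(dtype=float)
        coords /= meta.px_per_mm
        mask = np.isfinite(coords).all(axis=-1)
        coords = np.where(mask[..., None], coords, np.nan)
        out.append(PoseTrack(fly_id=fly, coords=coords, mask=mask))
    return meta, out


def write_pose(
    meta: RecordingMeta,
    tracks: list[PoseTrack],
    path: str,
    format: str | None = None,
) -> str:
    """Write pose tracks; inverse of :func:`read_pose` to 1e-6 mm."""
    fmt = _infer_format(path, format)
    for t in tracks:
        if t.n_frames != meta.n_frames:
            raise ValueError("track frame count disagrees with meta.n_frames")
    if fmt == "hdf5":
        _write_pose_hdf5(meta, tracks, path)
    else:
        _write_pose_csv(meta, tracks, path)
    return path


def _meta_attr_dict(meta: RecordingMeta) -> dict:
    return asdict(meta)


def _write_pose_hdf5(meta: RecordingMeta, tracks: list[PoseTrack], path: str) -> None:
    arr = np.full((len(tracks), 2, len(NODE_NAMES), meta.n_frames), np.nan)
    for i, t in enumerate(tracks):
        px = t.coords * meta.px_per_mm  # (frames, nodes, 2)
        px = np.where(t.mask[..., None], px, np.nan)
        arr[i] = px.transpose(2, 1, 0)
    with h5py.File(path, "w") as f:
        f.create_dataset("tracks", data=arr)
        f.create_dataset("node_names", data=np.array(NODE_NAMES, dtype="S"))
        for key, value in _meta_attr_dict(meta).items():
            f.attrs[key] = value
        f.attrs["fly_ids"] = np.array([t.fly_id for t in tracks], dtype="S")


def _write_pose_csv(meta: RecordingMeta, tracks: list[PoseTrack], path: str) -> None:
    rows = []
    for t in tracks:
        px = t.coords * meta.px_per_mm
        px = np.where(t.mask[..., None], px, np.nan)
        for j, node in enumerate(NODE_NAMES):
            rows.append(
                pd.DataFrame(
                    {
                        "frame": np.arange(meta.n_frames),
                        "fly_id": t.fly_id,
                        "node": node,
                        "x_px": px[:, j, 0],
                        "y_px": px[:, j, 1],
                    }
                )
            )
    df = pd.concat(rows, ignore_index=True).sort_values(["frame", "fly_id", "node"])
    with open(path, "w") as fh:
        for key, value in _meta_attr_dict(meta).items():
            fh.write(f"# {key}={value}\n")
        df.to_csv(fh, index=False)


def read_audio(path: str) -> tuple[int, np.ndarray]:
    """Read a WAV file; returns ``(sample_rate, channels x samples)`` floats.

    Integer PCM encodings are rescaled to [-1, 1].
    """
    try:
        sr, data = wavfile.read(path)
    except Exception as exc:  # wavfile raises assorted ValueError subclasses
        raise FormatError(f"could not read WAV file {path!r}: {exc}") from exc
    data = np.atleast_2d(np.asarray(data))
    if data.shape[0] > data.shape[1]:  # (samples, channels) -> (channels, samples)
        data = data.T
    if np.issubdtype(data.dtype, np.integer):
        scale = float(np.iinfo(data.dtype).max)
        data = data.astype(float) / scale
    else:
        data = data.astype(float)
    return int(sr), data


def write_audio(path: str, audio_sr: int, channels: np.ndarray) -> str:
    """Write a (channels x samples) float array as a float32 WAV file."""
    channels = np.atleast_2d(np.asarray(channels, dtype=np.float32))
    wavfile.write(path, int(audio_sr), channels.T)
    return path


_BOUT_COLUMNS = [
    "recording_id",
    "behavior",
    "start_frame",
    "end_frame",
    "dominant_wing",
    "provenance",
]


def read_bouts(path: str) -> list[BoutRecord]:
    """Read bout annotations from CSV, normalising declared behavior aliases."""
    df = pd.read_csv(path)
    missing = set(_BOUT_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"bout CSV missing columns {sorted(missing)}")
    bouts = []
    for i, row in enumerate(df.itertuples(index=False)):
        start, end = int(row.start_frame), int(row.end_frame)
        if start >= end:
            raise FormatError(
                f"row {i + 1}: start_frame {start} must be < end_frame {end}"
            )
        try:
            behavior = normalize_behavior(str(row.behavior))
            bouts.append(
                BoutRecord(
                    recording_id=str(row.recording_id),
                    behavior=behavior,
                    start=start,
                    end=end,
                    dominant_wing=str(row.dominant_wing),
                    provenance=str(row.provenance),
                )
            )
        except ValueError as exc:
            raise FormatError(f"row {i + 1}: {exc}") from exc
    return bouts


def write_bouts(bouts: list[BoutRecord], path: str) -> str:
    """Write bouts as CSV (canonical labels only); inverse of :func:`read_bouts`."""
    df = pd.DataFrame(
        {
            "recording_id": [b.recording_id for b in bouts],
            "behavior": [b.behavior for b in bouts],
            "start_frame": [b.start for b in bouts],
            "end_frame": [b.end for b in bouts],
            "dominant_wing": [b.dominant_wing for b in bouts],
            "provenance": [b.provenance for b in bouts],
        }
    )
    df.to_csv(path, index=False)
    return path
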