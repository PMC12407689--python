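"""Per-frame kinematic and relational features from two-fly pose tracks.

Conventions
-----------
* The body axis is the unit vector thorax -> head ("heading").
* Wing angles are unsigned, in degrees, measured between the thorax ->
  wing-tip vector and the *tail* direction (heading reversed), so 0 deg
  means a wing folded against the body and 90 deg full extension.
* Forward speed is the signed projection of the per-frame thorax
  displacement onto the heading, in mm/s; consumers that need a
  magnitude (e.g. stillness classification) take ``abs(speed)``.
* Inter-fly geometry (distance, body angle, target angle) uses unsigned
  angles in [0, 180] degrees.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.signal import medfilt, savgol_filter

from .core import BoutRecord, PoseTrack

logger = logging.getLogger(__name__)

__all__ = [
    "KinematicSeries",
    "interpolate_wing_tips",
    "smooth_thorax",
    "wing_angles",
    "heading",
    "forward_speed",
    "zscore_per_recording",
    "relative_geometry",
    "female_centric_maps",
    "FemaleCentricMaps",
    "dominant_wing",
    "event_triggered_average",
    "TriggeredAverage",
    "compute_kinematics",
]


@dataclass
class KinematicSeries:
    """Bundle of per-frame derived signals for one recording."""

    fps: float
    wing_angle_l: np.ndarray
    wing_angle_r: np.ndarray
    speed_male: np.ndarray
    speed_female: np.ndarray | None = None
    distance: np.ndarray | None = None
    body_angle: np.ndarray | None = None
    target_angle: np.ndarray | None = None


def interpolate_wing_tips(track: PoseTrack) -> PoseTrack:
    """Fill missing wing-tip frames by temporal nearest-neighbour copy.

    Each missing value is replaced by the value at the temporally nearest
    tracked frame; at an exact tie the earlier frame wins.  Only the two
    wing-tip nodes are touched.  Raises if a wing tip is missing on every
    frame.
    """
    out = track.copy()
    n = out.n_frames
    for name in ("wing_l", "wing_r"):
        j = out.node_index(name)
        present = np.flatnonzero(out.mask[:, j])
        if present.size == 0:
            raise ValueError(f"wing-tip node {name!r} is missing on every frame")
        if present.size == n:
            continue
        frames = np.arange(n)
        # nearest present frame; searchsorted midpoints give the boundary,
        # ties resolve to the earlier frame via side="right" on midpoints*2
        idx = np.searchsorted(present, frames)
        idx = np.clip(idx, 1, present.size - 1)
        left = present[idx - 1]
        right = present[idx]
        # distance tie -> earlier (left) frame
        choose_right = (right - frames) < (frames - left)
        nearest = np.where(choose_right, right, left)
        nearest[frames <= present[0]] = present[0]
        nearest[frames >= present[-1]] = present[-1]
        out.coords[:, j, :] = out.coords[nearest, j, :]
        out.mask[:, j] = True
    return out


def _moving_average_3(x: np.ndarray) -> np.ndarray:
    """Centred 3-point moving average with symmetric shrink at the edges."""
    out = x.copy()
    out[1:-1] = (x[:-2] + x[1:-1] + x[2:]) / 3.0
    return out


def smooth_thorax(track: PoseTrack, sg_window: int = 7, sg_order: int = 3) -> PoseTrack:
    """Denoise the thorax trajectory: 3-frame moving average, then Savitzky-Golay.

    Only the thorax node is modified.  The moving-average window shrinks
    symmetrically at the edges (to a single sample at the first/last
    frame); the Savitzky-Golay filter uses mirror padding.
    """
    if sg_window % 2 == 0 or sg_window <= sg_order:
        raise ValueError("sg_window must be odd and greater than sg_order")
    if track.n_frames < sg_window:
        raise ValueError(f"recording shorter ({track.n_frames}) than sg_window ({sg_window})")
    out = track.copy()
    j = out.node_index("thorax")
    for axis in range(2):
        x = _moving_average_3(out.coords[:, j, axis])
        out.coords[:, j, axis] = savgol_filter(x, sg_window, sg_order, mode="mirror")
    return out


def heading(track: PoseTrack) -> np.ndarray:
    """Unit body-axis vectors thorax -> head, shape (n_frames, 2).

    Frames with a zero-length body axis yield NaN.
    """
    vec = track.node("head") - track.node("thorax")
    norm = np.linalg.norm(vec, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        unit = vec / norm[:, None]
    unit[norm == 0] = np.nan
    return unit


def _unsigned_angle_deg(u: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Unsigned angle between row vectors of u and v, degrees in [0, 180]."""
    nu = np.linalg.norm(u, axis=1)
    nv = np.linalg.norm(v, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        cos = np.einsum("ij,ij->i", u, v) / (nu * nv)
    cos = np.clip(cos, -1.0, 1.0)
    ang = np.degrees(np.arccos(cos))
    ang[(nu == 0) | (nv == 0)] = np.nan
    return ang


def wing_angles(track: PoseTrack) -> tuple[np.ndarray, np.ndarray]:
    """Unsigned wing angles in degrees, 0 = folded, 90 = full extension.

    The angle is taken between the thorax -> wing-tip vector and the tail
    direction (body axis reversed), so a wing tip directly behind the fly
    gives 0 deg.  Frames with a degenerate body axis give NaN; their count
    is reported via a single warning.
    """
    thorax = track.node("thorax")
    tail = -(track.node("head") - thorax)
    out = []
    for name in ("wing_l", "wing_r"):
        tip = track.node(name) - thorax
        out.append(_unsigned_angle_deg(tip, tail))
    n_bad = int(np.sum(np.linalg.norm(tail, axis=1) == 0))
    if n_bad:
        warnings.warn(f"{n_bad} frame(s) with zero-length body axis -> NaN wing angles")
    return out[0], out[1]


def forward_speed(track: PoseTrack, fps: float, median_window: int = 5) -> np.ndarray:
    """Signed forward speed in mm/s: thorax displacement projected on heading.

    ``speed[t] = (thorax[t] - thorax[t-1]) . heading[t] * fps``, with
    ``speed[0] = 0``, then median-filtered (default 5-frame window).
    """
    if median_window % 2 == 0:
        raise ValueError("median_window must be odd")
    thorax = track.node("thorax")
    h = heading(track)
    disp = np.diff(thorax, axis=0)
    speed = np.zeros(track.n_frames)
    speed[1:] = np.einsum("ij,ij->i", disp, h[1:]) * fps
    if median_window > 1:
        speed = medfilt(speed, kernel_size=median_window)
    return speed


def zscore_per_recording(series: np.ndarray) -> np.ndarray:
    """Z-score a series over the whole recording (NaNs ignored).

    A zero-variance series yields all zeros with a warning.
    """
    series = np.asarray(series, dtype=float)
    mu = np.nanmean(series)
    sd = np.nanstd(series)
    if sd <= 1e-12 * max(1.0, abs(mu)) or not np.isfinite(sd):
        warnings.warn("zero-variance series: z-score returned as zeros")
        return np.where(np.isnan(series), np.nan, 0.0)
    return (series - mu) / sd


def relative_geometry(
    male: PoseTrack, female: PoseTrack
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Inter-fly geometry: thorax distance (mm), body angle, target angle (deg).

    The body angle is the unsigned angle between the two body axes; the
    target angle is between the male body axis and the male -> female
    thorax vector (0 deg = male facing the female).
    """
    mt, ft = male.node("thorax"), female.node("thorax")
    to_female = ft - mt
    distance = np.linalg.norm(to_female, axis=1)
    hm, hf = heading(male), heading(female)
    body_angle = _unsigned_angle_deg(hm, hf)
    target_angle = _unsigned_angle_deg(hm, to_female)
    return distance, body_angle, target_angle


@dataclass
class FemaleCentricMaps:
    """Spatial summaries of male position/orientation in the female's frame.

    ``hex_counts`` maps pointy-top axial hex coordinates (q, r) to visit
    counts (hexagon edge ``hex_edge_mm``).  The quiver arrays are
    ``grid_n x grid_n``: per-cell observation count, mean male position
    (mm, female frame) and circular-mean relative body orientation (rad).
    """

    hex_edge_mm: float
    hex_counts: dict[tuple[int, int], int]
    quiver_count: np.ndarray
    quiver_mean_x: np.ndarray
    quiver_mean_y: np.ndarray
    quiver_mean_angle: np.ndarray
    grid_edges_mm: np.ndarray


def _to_female_frame(male: PoseTrack, female: PoseTrack):
    """Male thorax position and heading expressed in the female's frame.

    The female thorax is the origin and her heading points along +y.
    Returns (positions (n,2), male heading angle (rad), valid mask).
    """
    hf = heading(female)
    right = np.stack([hf[:, 1], -hf[:, 0]], axis=1)  # heading rotated -90 deg
    rel = male.node("thorax") - female.node("thorax")
    pos = np.stack(
        [np.einsum("ij,ij->i", rel, right), np.einsum("ij,ij->i", rel, hf)], axis=1
    )
    hm = heading(male)
    ang = np.arctan2(np.einsum("ij,ij->i", hm, right), np.einsum("ij,ij->i", hm, hf))
    valid = np.isfinite(pos).all(axis=1) & np.isfinite(ang)
    return pos, ang, valid


def _axial_round(qf: np.ndarray, rf: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Cube-coordinate rounding of fractional axial hex coordinates."""
    xf, zf = qf, rf
    yf = -xf - zf
    rx, ry, rz = np.round(xf), np.round(yf), np.round(zf)
    dx, dy, dz = np.abs(rx - xf), np.abs(ry - yf), np.abs(rz - zf)
    fix_x = (dx > dy) & (dx > dz)
    fix_z = ~fix_x & (dz > dy)
    rx = np.where(fix_x, -ry - rz, rx)
    rz = np.where(fix_z, -rx - ry, rz)
    return rx.astype(int), rz.astype(int)


def female_centric_maps(
    male: PoseTrack,
    female: PoseTrack,
    hex_edge_mm: float = 0.10,
    grid_n: int = 14,
    grid_bin_mm: float = 0.86,
) -> FemaleCentricMaps:
    """Bin male positions around the female into hex and square grids.

    The location map uses a pointy-top hexagonal grid with 0.10 mm edges;
    the orientation map groups observations into ``grid_n x grid_n``
    square bins (default 14 x 14 at ~0.86 mm), recording per-cell counts,
    mean position, and circular-mean relative body orientation.  Both
    maps are invariant to global rotation/translation of the arena.
    """
    pos, ang, valid = _to_female_frame(male, female)
    pos, ang = pos[valid], ang[valid]

    s = hex_edge_mm
    qf = (np.sqrt(3) / 3 * pos[:, 0] - pos[:, 1] / 3) / s
    rf = (2.0 / 3.0 * pos[:, 1]) / s
    q, r = _axial_round(qf, rf)
    hex_counts: dict[tuple[int, int], int] = {}
    for key in zip(q.tolist(), r.tolist()):
        hex_counts[key] = hex_counts.get(key, 0) + 1

    half = grid_n * grid_bin_mm / 2.0
    edges = np.linspace(-half, half, grid_n + 1)
    ix = np.digitize(pos[:, 0], edges) - 1
    iy = np.digitize(pos[:, 1], edges) - 1
    inside = (ix >= 0) & (ix < grid_n) & (iy >= 0) & (iy < grid_n)
    count = np.zeros((grid_n, grid_n))
    sx = np.zeros((grid_n, grid_n))
    sy = np.zeros((grid_n, grid_n))
    sc = np.zeros((grid_n, grid_n))
    ss = np.zeros((grid_n, grid_n))
    np.add.at(count, (iy[inside], ix[inside]), 1)
    np.add.at(sx, (iy[inside], ix[inside]), pos[inside, 0])
    np.add.at(sy, (iy[inside], ix[inside]), pos[inside, 1])
    np.add.at(sc, (iy[inside], ix[inside]), np.cos(ang[inside]))
    np.add.at(ss, (iy[inside], ix[inside]), np.sin(ang[inside]))
    with np.errstate(invalid="ignore", divide="ignore"):
        mean_x = np.where(count > 0, sx / count, np.nan)
        mean_y = np.where(count > 0, sy / count, np.nan)
    mean_ang = np.where(count > 0, np.arctan2(ss, sc), np.nan)
    return FemaleCentricMaps(
        hex_edge_mm=hex_edge_mm,
        hex_counts=hex_counts,
        quiver_count=count,
        quiver_mean_x=mean_x,
        quiver_mean_y=mean_y,
        quiver_mean_angle=mean_ang,
        grid_edges_mm=edges,
    )


def dominant_wing(bout: BoutRecord, wing_angle_l: np.ndarray, wing_angle_r: np.ndarray) -> str:
    """The wing with the greater mean extension angle over the bout.

    An exact tie resolves to ``"left"`` (logged).
    """
    ml = float(np.nanmean(wing_angle_l[bout.start : bout.end]))
    mr = float(np.nanmean(wing_angle_r[bout.start : bout.end]))
    if ml == mr:
        logger.info(
            "dominant_wing tie (%.6g deg) in bout [%d, %d); resolving to left",
            ml, bout.start, bout.end,
        )
        return "left"
    return "left" if ml > mr else "right"


@dataclass
class TriggeredAverage:
    """Event-triggered average of a series: per-lag mean, SEM, and count."""

    lags_s: np.ndarray
    mean: np.ndarray
    sem: np.ndarray
    n: np.ndarray
    snippets: np.ndarray  # events x lags, NaN-padded at recording edges


def event_triggered_average(
    series: np.ndarray,
    events: np.ndarray,
    window_s: tuple[float, float],
    fps: float,
) -> TriggeredAverage:
    """Align snippets of ``series`` to event frames and average across events.

    ``window_s = (before, after)`` in seconds.  Snippets extending past
    the recording edges are NaN-padded; SEM = SD / sqrt(n) with n the
    per-lag non-NaN count (SEM is 0 where n == 1).
    """
    series = np.asarray(series, dtype=float)
    events = np.asarray(events, dtype=int)
    before, after = window_s
    lags = np.arange(-int(round(before * fps)), int(round(after * fps)) + 1)
    idx = events[:, None] + lags[None, :]
    valid = (idx >= 0) & (idx < series.size)
    snippets = np.full(idx.shape, np.nan)
    snippets[valid] = series[idx[valid]]
    n = np.sum(~np.isnan(snippets), axis=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean = np.nanmean(snippets, axis=0)
        sd = np.nanstd(snippets, axis=0, ddof=1)
    sem = np.where(n > 1, sd / np.sqrt(np.maximum(n, 1)), 0.0)
    sem[n == 0] = np.nan
    return TriggeredAverage(lags_s=lags / fps, mean=mean, sem=sem, n=n, snippets=snippets)


def compute_kinematics(
    male: PoseTrack,
    female: PoseTrack | None,
    fps: float,
    sg_window: int = 7,
    sg_order: int = 3,
    median_window: int = 5,
) -> KinematicSeries:
    """Standard preprocessing + feature extraction for one recording.

    Wing tips are gap-filled by nearest-neighbour interpolation and the
    thorax smoothed before wing angles, speeds, and (for two flies) the
    inter-fly geometry are computed.
    """
    male = smooth_thorax(interpolate_wing_tips(male), sg_window, sg_order)
    wl, wr = wing_angles(male)
    speed_m = forward_speed(male, fps, median_window)
    if female is None:
        return KinematicSeries(fps=fps, wing_angle_l=wl, wing_angle_r=wr, speed_male=speed_m)
    female = smooth_thorax(interpolate_wing_tips(female), sg_window, sg_order)
    speed_f = forward_speed(female, fps, median_window)
    distance, body_angle, target_angle = relative_geometry(male, female)
    return KinematicSeries(
        fps=fps,
        wing_angle_l=wl,
        wing_angle_r=wr,
        speed_male=speed_m,
        speed_female=speed_f,
        distance=distance,
        body_angle=body_angle,
        target_angle=target_angle,
    )
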