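"""Waggle and song bout detection and validation.

Waggling is a rhythmic anti-phase oscillation of both wings around
10.6 Hz at reduced extension angles, producing no audible signal.  The
detector band-pass filters the two wing-angle series (8-18 Hz), applies
the Hilbert transform to obtain instantaneous phase and envelope, and
marks frames where both envelopes rise sufficiently above baseline while
the phases stay anti-phase; contiguous runs lasting at least three
oscillation cycles become bouts.

Courtship song is unilateral wing extension accompanied by elevated
microphone amplitude; the song detector is a conjunction of a wing-angle
threshold and an RMS threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import butter, get_window, hilbert, sosfiltfilt
from scipy.signal import detrend as _detrend

from .core import BoutRecord

__all__ = [
    "WaggleParams",
    "SongParams",
    "SpectralSummary",
    "MatchResult",
    "detect_waggle",
    "detect_song",
    "waggle_spectrum",
    "match_bouts",
]


@dataclass
class WaggleParams:
    """Tunable parameters of the anti-phase waggle detector.

    ``band`` and ``min_cycles`` follow the published detector (8-18 Hz,
    at least 3 cycles); the anti-phase tolerance and envelope threshold
    quantify "in anti-phase with sufficient amplitude above baseline".
    """

    band: tuple[float, float] = (8.0, 18.0)
    min_cycles: float = 3.0
    antiphase_tol_rad: float = np.pi / 4
    amp_thresh_deg: float = 5.0  # above per-recording baseline envelope median
    merge_gap_s: float = 0.1
    filter_order: int = 4
    smooth_phase: bool = False

    def __post_init__(self) -> None:
        if self.min_cycles < 1:
            raise ValueError("min_cycles must be >= 1")


@dataclass
class SongParams:
    """Parameters of the wing-extension + acoustic-amplitude song detector."""

    wing_ext_thresh_deg: float = 45.0
    rms_mult: float = 3.0  # times the per-recording baseline (median) RMS
    min_dur_s: float = 0.1


@dataclass
class SpectralSummary:
    """Per-bout wing oscillation spectrum and phase relationship."""

    freqs: np.ndarray
    power_l: np.ndarray
    power_r: np.ndarray
    peak_freq_l: float
    peak_freq_r: float
    mean_abs_phase_diff_rad: float

    @property
    def peak_freqs(self) -> tuple[float, float]:
        return self.peak_freq_l, self.peak_freq_r


def _fill_nan(x: np.ndarray) -> np.ndarray:
    """Linearly interpolate interior NaNs (edges hold the nearest value)."""
    x = np.asarray(x, dtype=float)
    bad = ~np.isfinite(x)
    if not bad.any():
        return x
    good = np.flatnonzero(~bad)
    if good.size == 0:
        raise ValueError("series is all-NaN")
    out = x.copy()
    out[bad] = np.interp(np.flatnonzero(bad), good, x[good])
    return out


def _bandpassed_analytic(x: np.ndarray, fps: float, band, order: int):
    if band[1] >= fps / 2:
        raise ValueError(f"band {band} reaches the Nyquist frequency at {fps} fps")
    sos = butter(order, band, btype="bandpass", fs=fps, output="sos")
    filtered = sosfiltfilt(sos, _fill_nan(x))
    analytic = hilbert(filtered)
    return filtered, np.angle(analytic), np.abs(analytic)


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Half-open [start, end) runs of True."""
    idx = np.flatnonzero(np.diff(np.concatenate([[0], mask.astype(int), [0]])))
    return list(zip(idx[::2].tolist(), idx[1::2].tolist()))


def _merge_runs(runs: list[tuple[int, int]], max_gap: int) -> list[tuple[int, int]]:
    if not runs:
        return []
    merged = [list(runs[0])]
    for s, e in runs[1:]:
        if s - merged[-1][1] < max_gap:
            merged[-1][1] = e
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def detect_waggle(
    wing_angle_l: np.ndarray,
    wing_angle_r: np.ndarray,
    fps: float,
    params: WaggleParams | None = None,
    recording_id: str = "",
) -> list[BoutRecord]:
    """Detect anti-phase wing-oscillation (waggle) bouts.

    Pipeline: zero-phase Butterworth band-pass of both wing-angle series;
    Hilbert phases/envelopes; candidate frames where both envelopes
    exceed the per-recording baseline (envelope median) by
    ``amp_thresh_deg`` while the wrapped phase difference is within
    ``antiphase_tol_rad`` of pi; candidate runs merged across gaps below
    ``merge_gap_s``; a run is kept iff the unwrapped phase of the
    dominant wing spans at least ``min_cycles`` full cycles.  Detection
    is invariant to constant offsets of either series.
    """
    params = params or WaggleParams()
    wl = np.asarray(wing_angle_l, dtype=float)
    wr = np.asarray(wing_angle_r, dtype=float)
    _, phase_l, env_l = _bandpassed_analytic(wl, fps, params.band, params.filter_order)
    _, phase_r, env_r = _bandpassed_analytic(wr, fps, params.band, params.filter_order)

    thresh_l = np.median(env_l) + params.amp_thresh_deg
    thresh_r = np.median(env_r) + params.amp_thresh_deg
    dphi = np.angle(np.exp(1j * (phase_l - phase_r)))
    anti = np.pi - np.abs(dphi)
    if params.smooth_phase:
        from scipy.signal import medfilt

        anti = medfilt(anti, kernel_size=5)
    candidates = (env_l > thresh_l) & (env_r > thresh_r) & (anti <= params.antiphase_tol_rad)

    runs = _merge_runs(_runs(candidates), max(1, int(params.merge_gap_s * fps)))
    bouts = []
    for s, e in runs:
        mean_l = np.nanmean(wl[s:e])
        mean_r = np.nanmean(wr[s:e])
        phase_dom = phase_l if mean_l >= mean_r else phase_r
        span = np.ptp(np.unwrap(phase_dom[s:e])) if e - s > 1 else 0.0
        if span < params.min_cycles * 2 * np.pi:
            continue
        bouts.append(
            BoutRecord(
                recording_id=recording_id,
                behavior="waggle",
                start=int(s),
                end=int(e),
                dominant_wing="left" if mean_l >= mean_r else "right",
                provenance="detected",
            )
        )
    return bouts


def detect_song(
    wing_angle_l: np.ndarray,
    wing_angle_r: np.ndarray,
    rms_per_frame: np.ndarray,
    fps: float,
    params: SongParams | None = None,
    recording_id: str = "",
) -> list[BoutRecord]:
    """Detect song bouts: wing extension coincident with elevated audio RMS.

    Core frames satisfy ``max(wing angles) > wing_ext_thresh_deg`` AND
    ``rms > rms_mult * baseline`` (baseline = per-recording median RMS).
    Core runs of at least ``min_dur_s`` become bouts; bout boundaries are
    widened to the surrounding wing-angle threshold crossings.  The
    dominant wing is the extended (greater mean) one.
    """
    params = params or SongParams()
    wl = np.asarray(wing_angle_l, dtype=float)
    wr = np.asarray(wing_angle_r, dtype=float)
    rms = np.asarray(rms_per_frame, dtype=float)
    wmax = np.fmax(wl, wr)
    extended = wmax > params.wing_ext_thresh_deg
    baseline = np.median(rms)
    loud = rms > params.rms_mult * baseline
    core = extended & loud

    ext_runs = _runs(extended)
    min_frames = max(1, int(round(params.min_dur_s * fps)))
    bouts: list[tuple[int, int]] = []
    for s, e in _runs(core):
        if e - s < min_frames:
            continue
        # widen to the enclosing wing-extension run
        for es, ee in ext_runs:
            if es <= s and e <= ee:
                s, e = es, ee
                break
        if bouts and s <= bouts[-1][1]:
            bouts[-1] = (bouts[-1][0], max(bouts[-1][1], e))
        else:
            bouts.append((s, e))
    out = []
    for s, e in bouts:
        out.append(
            BoutRecord(
                recording_id=recording_id,
                behavior="song",
                start=int(s),
                end=int(e),
                dominant_wing="left" if np.nanmean(wl[s:e]) >= np.nanmean(wr[s:e]) else "right",
                provenance="detected",
            )
        )
    return out


def waggle_spectrum(
    bout: BoutRecord,
    wing_angle_l: np.ndarray,
    wing_angle_r: np.ndarray,
    fps: float,
    band: tuple[float, float] = (8.0, 18.0),
    resolution_hz: float = 0.05,
) -> SpectralSummary:
    """Spectral summary of one waggle bout.

    Each wing's bout segment is linearly detrended, Hann-windowed, and
    zero-padded to at least ``resolution_hz`` frequency resolution; the
    peak frequency is the power argmax within ``band``.  The phase
    relation is the mean absolute wrapped Hilbert phase difference
    between the two (detrended) segments — pi for ideal anti-phase
    motion, 0 for in-phase motion.
    """
    seg_l = _fill_nan(wing_angle_l[bout.start : bout.end])
    seg_r = _fill_nan(wing_angle_r[bout.start : bout.end])
    n = seg_l.size
    if n < 4:
        raise ValueError("bout too short for spectral analysis")
    nfft = max(int(np.ceil(fps / resolution_hz)), n)
    window = get_window("hann", n)

    def _spectrum(seg):
        d = _detrend(seg, type="linear")
        spec = np.fft.rfft(d * window, n=nfft)
        power = np.abs(spec) ** 2
        freqs = np.fft.rfftfreq(nfft, d=1.0 / fps)
        return freqs, power

    freqs, power_l = _spectrum(seg_l)
    _, power_r = _spectrum(seg_r)
    in_band = (freqs >= band[0]) & (freqs <= band[1])
    if not in_band.any():
        raise ValueError(f"no frequency bins inside band {band}")
    peak_l = float(freqs[in_band][np.argmax(power_l[in_band])])
    peak_r = float(freqs[in_band][np.argmax(power_r[in_band])])

    phase_l = np.angle(hilbert(_detrend(seg_l, type="linear")))
    phase_r = np.angle(hilbert(_detrend(seg_r, type="linear")))
    dphi = np.angle(np.exp(1j * (phase_l - phase_r)))
    mean_abs = float(np.mean(np.abs(dphi)))

    return SpectralSummary(
        freqs=freqs[in_band],
        power_l=power_l[in_band],
        power_r=power_r[in_band],
        peak_freq_l=peak_l,
        peak_freq_r=peak_r,
        mean_abs_phase_diff_rad=mean_abs,
    )


@dataclass
class MatchResult:
    """Greedy one-to-one interval matching of detected vs. truth bouts."""

    precision: float
    recall: float
    pairs: list[tuple[int, int, float]]  # (detected index, truth index, IoU)
    n_detected: int
    n_truth: int

    @property
    def n_matched(self) -> int:
        return len(self.pairs)


def match_bouts(
    detected: list[BoutRecord],
    truth: list[BoutRecord],
    iou_min: float = 0.3,
) -> MatchResult:
    """Score detected bouts against ground truth by greedy IoU matching.

    Candidate pairs are ranked by descending temporal IoU and matched
    one-to-one; a pair counts iff IoU >= ``iou_min``.  Precision is
    matched/|detected| (NaN when nothing was detected), recall is
    matched/|truth| (0 when truth is empty only if detected is too).
    """
    pairs = []
    for i, d in enumerate(detected):
        for j, t in enumerate(truth):
            iou = d.iou(t)
            if iou >= iou_min:
                pairs.append((iou, i, j))
    pairs.sort(key=lambda p: (-p[0], p[1], p[2]))
    used_d: set[int] = set()
    used_t: set[int] = set()
    matched = []
    for iou, i, j in pairs:
        if i in used_d or j in used_t:
            continue
        used_d.add(i)
        used_t.add(j)
        matched.append((i, j, iou))
    precision = len(matched) / len(detected) if detected else float("nan")
    recall = len(matched) / len(truth) if truth else 0.0
    return MatchResult(
        precision=precision,
        recall=recall,
        pairs=matched,
        n_detected=len(detected),
        n_truth=len(truth),
    )
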