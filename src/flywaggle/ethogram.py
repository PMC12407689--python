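"""Ethogram construction and transition statistics.

Four mutually exclusive behavioral states — stillness, waggle, song,
other — are assigned per frame by a hierarchical scheme: stillness
frames first (both flies below their sex-specific speed thresholds),
then waggle and song bouts overwrite stillness, and everything else is
"other".  Runs of equal labels become bouts; stillness and "other"
bouts below knee-point-derived duration thresholds are excluded from
the bout sequence (their frames keep their labels), while waggle and
song bouts retain their detection-based durations.

Transition statistics pool bout-to-bout counts across recordings and
test each transition for enrichment against a within-recording
label-shuffle permutation null with Benjamini-Hochberg FDR correction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .core import BEHAVIORS, BoutRecord, Ethogram

STATE_INDEX = {s: i for i, s in enumerate(BEHAVIORS)}

__all__ = [
    "StillnessThresholds",
    "DurationThresholds",
    "TransitionResult",
    "knee_point",
    "knee_point_from_cdf",
    "classify_stillness",
    "build_ethogram",
    "transition_matrix",
    "permutation_test",
    "bh_fdr",
    "three_grams",
]


@dataclass(frozen=True)
class StillnessThresholds:
    """Sex-specific speed thresholds (mm/s) below which a fly is stationary.

    Defaults are the knee-point values derived from the study's pooled
    speed distributions: 0.67 mm/s (male) and 0.30 mm/s (female).
    """

    male_mm_s: float = 0.67
    female_mm_s: float = 0.30


@dataclass(frozen=True)
class DurationThresholds:
    """Minimum bout durations (s) for stillness and "other" bouts.

    Defaults are the knee-point values from the study's bout-duration
    distributions: 0.71 s (stillness) and 0.72 s (other).
    """

    stillness_s: float = 0.71
    other_s: float = 0.72


def knee_point(values: np.ndarray) -> float:
    """Knee of the empirical CDF: the point farthest from the endpoint chord.

    The empirical CDF is evaluated at the sorted unique values, both
    axes are min-max normalized to [0, 1], and the returned threshold is
    the (un-normalized) x maximizing the perpendicular distance to the
    chord from (0, 0) to (1, 1).  Ties resolve to the smaller x; a
    degenerate (straight-line) CDF warns and returns the smallest x.
    """
    values = np.asarray(values, dtype=float)
    values = values[np.isfinite(values)]
    x = np.unique(values)
    if x.size < 3:
        raise ValueError("knee_point requires at least 3 distinct values")
    counts = np.searchsorted(np.sort(values), x, side="right")
    y = counts / values.size
    return knee_point_from_cdf(x, y)


def knee_point_from_cdf(x: np.ndarray, y: np.ndarray) -> float:
    """Knee of an explicit CDF given as points ``(x, y)`` (see :func:`knee_point`)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3:
        raise ValueError("knee_point requires at least 3 CDF points")
    xn = (x - x[0]) / (x[-1] - x[0])
    yn = (y - y[0]) / (y[-1] - y[0])
    # perpendicular distance to the y = x chord is |y - x| / sqrt(2)
    dist = np.abs(yn - xn)
    if np.allclose(dist, 0.0, atol=1e-12):
        warnings.warn("degenerate CDF (straight line); knee_point returns the smallest value")
        return float(x[0])
    return float(x[int(np.argmax(dist))])


def classify_stillness(
    male_speed: np.ndarray,
    female_speed: np.ndarray,
    thresholds: StillnessThresholds | None = None,
) -> np.ndarray:
    """Per-frame stillness: both flies simultaneously below threshold.

    Speeds are compared by magnitude.  Frames where either speed is NaN
    are classified as not-still (their count is warned about).
    """
    thresholds = thresholds or StillnessThresholds()
    ms = np.abs(np.asarray(male_speed, dtype=float))
    fs = np.abs(np.asarray(female_speed, dtype=float))
    n_nan = int(np.sum(~np.isfinite(ms) | ~np.isfinite(fs)))
    if n_nan:
        warnings.warn(f"{n_nan} frame(s) with NaN speed treated as not-still")
    with np.errstate(invalid="ignore"):
        return (ms < thresholds.male_mm_s) & (fs < thresholds.female_mm_s)


def _resolve_overlaps(bouts: list[BoutRecord]) -> list[BoutRecord]:
    """Truncate the later-starting of any overlapping pair (with a warning)."""
    bouts = sorted(bouts, key=lambda b: (b.start, b.end))
    out: list[BoutRecord] = []
    for b in bouts:
        if out and b.start < out[-1].end:
            warnings.warn(
                f"overlapping {out[-1].behavior}/{b.behavior} bouts at frame {b.start}; "
                "truncating the later-starting bout"
            )
            if out[-1].end >= b.end:
                continue
            b = b.with_(start=out[-1].end)
        out.append(b)
    return out


def build_ethogram(
    stillness_series: np.ndarray,
    waggle_bouts: list[BoutRecord],
    song_bouts: list[BoutRecord],
    duration_thresholds: DurationThresholds | None = None,
    fps: float = 150.0,
    recording_id: str = "",
) -> Ethogram:
    """Assemble the four-state ethogram for one recording.

    Stillness frames are labelled first, waggle/song bouts overwrite
    them, and the remainder is "other".  Stillness/"other" bouts shorter
    than their duration thresholds are excluded from the bout sequence
    (their frames stay labelled); waggle/song bouts keep their detected
    boundaries.  Overlapping waggle/song bouts are resolved by
    truncating the later-starting one.
    """
    duration_thresholds = duration_thresholds or DurationThresholds()
    stillness_series = np.asarray(stillness_series, dtype=bool)
    n_frames = stillness_series.size

    detected = _resolve_overlaps(list(waggle_bouts) + list(song_bouts))
    detected = [b for b in detected if b.end > b.start]

    labels = np.where(stillness_series, STATE_INDEX["stillness"], STATE_INDEX["other"])
    for b in detected:
        labels[b.start : min(b.end, n_frames)] = STATE_INDEX[b.behavior]

    min_frames = {
        "stillness": int(np.ceil(duration_thresholds.stillness_s * fps)),
        "other": int(np.ceil(duration_thresholds.other_s * fps)),
    }
    bouts: list[BoutRecord] = []
    n_excluded = 0
    boundaries = np.flatnonzero(np.diff(labels)) + 1
    starts = np.concatenate([[0], boundaries])
    ends = np.concatenate([boundaries, [n_frames]])
    det_iter = iter(detected)
    current_det = next(det_iter, None)
    for s, e in zip(starts.tolist(), ends.tolist()):
        behavior = BEHAVIORS[labels[s]]
        if behavior in ("waggle", "song"):
            # recover the detected bout(s) covering this run to keep wings
            while current_det is not None and current_det.end <= s:
                current_det = next(det_iter, None)
            run_dets = []
            d = current_det
            while d is not None and d.start < e:
                run_dets.append(d)
                d = next(det_iter, None)
            current_det = d
            for det in run_dets:
                bouts.append(
                    det.with_(
                        recording_id=recording_id or det.recording_id,
                        start=max(det.start, s),
                        end=min(det.end, e),
                    )
                )
        else:
            if e - s < min_frames[behavior]:
                n_excluded += 1
                continue
            bouts.append(
                BoutRecord(
                    recording_id=recording_id,
                    behavior=behavior,
                    start=s,
                    end=e,
                    dominant_wing="none",
                    provenance="detected",
                )
            )
    bouts.sort(key=lambda b: b.start)
    return Ethogram(
        recording_id=recording_id,
        fps=fps,
        n_frames=n_frames,
        bouts=bouts,
        frame_labels=labels,
        n_excluded=n_excluded,
    )


@dataclass
class TransitionResult:
    """Pooled bout-to-bout transition counts, probabilities, and test results.

    ``probs`` are row-normalized over all four states; the published
    3x3 stillness/waggle/song submatrix is a slice of the full matrix,
    so its rows sum to <= 1.
    """

    states: tuple[str, ...]
    counts: np.ndarray
    probs: np.ndarray
    pvals: np.ndarray | None = None
    qvals: np.ndarray | None = None
    n_perm: int | None = None
    seed: int | None = None

    def submatrix(self, states=("stillness", "waggle", "song")) -> np.ndarray:
        idx = [self.states.index(s) for s in states]
        return self.probs[np.ix_(idx, idx)]


def _label_codes(ethogram: Ethogram) -> np.ndarray:
    return np.array([STATE_INDEX[b.behavior] for b in ethogram.bouts], dtype=int)


def _pooled_counts(seqs: list[np.ndarray]) -> np.ndarray:
    counts = np.zeros((4, 4))
    for seq in seqs:
        if seq.size < 2:
            continue
        np.add.at(counts, (seq[:-1], seq[1:]), 1)
    return counts


def _row_normalize(counts: np.ndarray) -> np.ndarray:
    rowsum = counts.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        probs = np.where(rowsum > 0, counts / np.where(rowsum == 0, 1, rowsum), 0.0)
    return probs


def transition_matrix(ethograms: list[Ethogram]) -> TransitionResult:
    """Tally bout-to-bout transitions pooled across recordings.

    Transitions never cross recording boundaries.  Probabilities are
    counts row-normalized over all four states.
    """
    counts = _pooled_counts([_label_codes(e) for e in ethograms])
    return TransitionResult(states=BEHAVIORS, counts=counts, probs=_row_normalize(counts))


def permutation_test(
    ethograms: list[Ethogram],
    n_perm: int = 10_000,
    seed: int = 0,
    tested_cells: str = "offdiag4",
) -> TransitionResult:
    """One-tailed enrichment test of transition probabilities.

    Each permutation independently shuffles the bout order within every
    recording (each bout keeps its label and duration), transition
    probabilities are recomputed from the pooled shuffled sequences, and
    the p-value of a cell is the add-one exceedance estimate
    ``(1 + #{perm >= observed}) / (1 + n_perm)``.  BH-FDR q-values are
    computed over the tested cells (all 12 off-diagonal cells of the
    4x4 matrix, or the 9 cells of the 3x3 submatrix with
    ``tested_cells="offdiag3"``).
    """
    rng = np.random.default_rng(seed)
    seqs = [_label_codes(e) for e in ethograms]
    observed_counts = _pooled_counts(seqs)
    observed = _row_normalize(observed_counts)

    perm_counts = np.zeros((n_perm, 16))
    for seq in seqs:
        L = seq.size
        if L < 2:
            continue
        order = np.argsort(rng.random((n_perm, L)), axis=1)
        shuffled = seq[order]
        cells = 4 * shuffled[:, :-1] + shuffled[:, 1:]
        flat = cells + 16 * np.arange(n_perm)[:, None]
        perm_counts += np.bincount(flat.ravel(), minlength=16 * n_perm).reshape(n_perm, 16)
    perm_counts = perm_counts.reshape(n_perm, 4, 4)
    rowsum = perm_counts.sum(axis=2, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        perm_probs = np.where(rowsum > 0, perm_counts / np.where(rowsum == 0, 1, rowsum), 0.0)

    exceed = (perm_probs >= observed[None] - 1e-12).sum(axis=0)
    pvals = (1.0 + exceed) / (1.0 + n_perm)

    if tested_cells == "offdiag4":
        mask = ~np.eye(4, dtype=bool)
    elif tested_cells == "offdiag3":
        mask = np.zeros((4, 4), dtype=bool)
        idx = [STATE_INDEX[s] for s in ("stillness", "waggle", "song")]
        for a in idx:
            for b in idx:
                if a != b:
                    mask[a, b] = True
    else:
        raise ValueError("tested_cells must be 'offdiag4' or 'offdiag3'")
    qvals = np.full((4, 4), np.nan)
    qvals[mask] = bh_fdr(pvals[mask])
    pvals_out = np.where(mask, pvals, np.nan)
    return TransitionResult(
        states=BEHAVIORS,
        counts=observed_counts,
        probs=observed,
        pvals=pvals_out,
        qvals=qvals,
        n_perm=n_perm,
        seed=seed,
    )


def bh_fdr(pvals: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (monotone, clipped to [0, 1])."""
    p = np.asarray(pvals, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.clip(q_sorted, 0.0, 1.0)
    return q


def three_grams(ethograms: list[Ethogram]) -> list[tuple[tuple[str, str, str], int, float]]:
    """Ranked frequencies of ordered bout triples.

    All windows of three consecutive retained bouts are enumerated per
    recording; windows containing the "other" state or a self-transition
    are excluded.  Probability is count / total retained windows; the
    result is sorted by descending count.
    """
    counts: dict[tuple[str, str, str], int] = {}
    total = 0
    for e in ethograms:
        labels = e.labels
        for i in range(len(labels) - 2):
            tri = tuple(labels[i : i + 3])
            if "other" in tri or tri[0] == tri[1] or tri[1] == tri[2]:
                continue
            counts[tri] = counts.get(tri, 0) + 1
            total += 1
    ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    return [(tri, c, c / total) for tri, c in ranked]
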