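"""Waggle -> song temporal coupling and dominant-wing persistence.

Every waggle bout is paired with the earliest subsequent song bout in
the same recording; the gap (waggle offset to song onset, seconds) is
classified as "linked" or "unlinked" by exact two-cluster k-means on
log gaps.  Wing persistence is the fraction of pairs in which the
song's dominant wing matches the preceding waggle's, computed overall,
per fly/recording, per linked class, and in logarithmic gap bins.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import BoutRecord

__all__ = [
    "WaggleSongPair",
    "waggle_song_gaps",
    "classify_linked",
    "wing_match_fraction",
    "binned_match",
    "DEFAULT_GAP_BIN_EDGES_S",
]

#: logarithmic gap-bin edges (seconds) used for the wing-persistence decay
DEFAULT_GAP_BIN_EDGES_S = (0.007, 0.046, 0.312, 2.138, 14.630, 100.133)


@dataclass(frozen=True)
class WaggleSongPair:
    waggle: BoutRecord
    song: BoutRecord
    gap_s: float

    @property
    def wing_match(self) -> bool:
        return self.waggle.dominant_wing == self.song.dominant_wing


def waggle_song_gaps(
    waggle_bouts: list[BoutRecord],
    song_bouts: list[BoutRecord],
    fps: float,
) -> list[WaggleSongPair]:
    """Pair each waggle with the earliest song starting at or after its offset.

    Waggles not followed by any song within the recording are excluded.
    Pairing is done per recording_id.
    """
    pairs = []
    songs_by_rec: dict[str, list[BoutRecord]] = {}
    for s in song_bouts:
        songs_by_rec.setdefault(s.recording_id, []).append(s)
    for rec in songs_by_rec:
        songs_by_rec[rec].sort(key=lambda b: b.start)
    for w in sorted(waggle_bouts, key=lambda b: (b.recording_id, b.start)):
        songs = songs_by_rec.get(w.recording_id, [])
        starts = np.array([s.start for s in songs])
        idx = np.searchsorted(starts, w.end, side="left")
        if idx >= len(songs):
            continue
        song = songs[idx]
        pairs.append(WaggleSongPair(waggle=w, song=song, gap_s=(song.start - w.end) / fps))
    return pairs


def classify_linked(
    gaps_s: np.ndarray,
    seed: int | None = None,
    min_gap_s: float = 1.0 / 300.0,
) -> tuple[float, np.ndarray]:
    """Split gaps into linked/unlinked by exact 1-D 2-means on log gaps.

    The globally optimal two-cluster partition of the sorted log-gaps is
    found by scanning all split points (deterministic; no random
    initialization, so ``seed`` is accepted only for API symmetry).  The
    dividing threshold is the log-space midpoint of the two centroids;
    gaps below it are "linked".  Zero gaps are floored at half a frame
    (``min_gap_s``) before the log transform.  Scale-equivariant:
    scaling all gaps by c scales the threshold by c.
    """
    gaps = np.asarray(gaps_s, dtype=float)
    if gaps.size < 2:
        raise ValueError("classify_linked requires at least 2 gaps")
    logs = np.log(np.maximum(gaps, min_gap_s))
    if np.allclose(logs, logs[0]):
        raise ValueError("all gaps identical: no two-cluster structure")
    order = np.argsort(logs)
    s = logs[order]
    n = s.size
    csum = np.concatenate([[0.0], np.cumsum(s)])
    csum2 = np.concatenate([[0.0], np.cumsum(s**2)])

    def wcss(lo, hi):  # half-open index range into s
        k = hi - lo
        tot = csum[hi] - csum[lo]
        return (csum2[hi] - csum2[lo]) - tot**2 / k

    best_k, best_cost = 1, np.inf
    for k in range(1, n):
        cost = wcss(0, k) + wcss(k, n)
        if cost < best_cost - 1e-15:
            best_cost, best_k = cost, k
    c_low = csum[best_k] / best_k
    c_high = (csum[n] - csum[best_k]) / (n - best_k)
    threshold = float(np.exp((c_low + c_high) / 2.0))
    labels = np.maximum(gaps, min_gap_s) < threshold
    return threshold, labels


@dataclass
class WingMatchSummary:
    overall: float
    n: int
    linked: float | None = None
    n_linked: int = 0
    unlinked: float | None = None
    n_unlinked: int = 0
    per_fly: dict[str, float] | None = None


def wing_match_fraction(
    pairs: list[WaggleSongPair],
    linked_labels: np.ndarray | None = None,
) -> WingMatchSummary:
    """Fraction of pairs whose song wing matches the preceding waggle wing.

    Reported overall, per recording (a recording is one male), and —
    when ``linked_labels`` is given — per linked/unlinked class.
    """
    if not pairs:
        raise ValueError("no waggle-song pairs")
    match = np.array([p.wing_match for p in pairs], dtype=bool)
    summary = WingMatchSummary(overall=float(match.mean()), n=len(pairs))
    recs = np.array([p.waggle.recording_id for p in pairs])
    summary.per_fly = {
        rec: float(match[recs == rec].mean()) for rec in dict.fromkeys(recs.tolist())
    }
    if linked_labels is not None:
        linked_labels = np.asarray(linked_labels, dtype=bool)
        if linked_labels.size != match.size:
            raise ValueError("linked_labels length must equal number of pairs")
        summary.n_linked = int(linked_labels.sum())
        summary.n_unlinked = int((~linked_labels).sum())
        summary.linked = float(match[linked_labels].mean()) if summary.n_linked else None
        summary.unlinked = float(match[~linked_labels].mean()) if summary.n_unlinked else None
    return summary


def binned_match(
    pairs: list[WaggleSongPair],
    bin_edges_s: tuple[float, ...] = DEFAULT_GAP_BIN_EDGES_S,
) -> list[dict]:
    """Wing-match fraction in logarithmic gap bins.

    Returns one record per bin: ``{"lo_s", "hi_s", "n", "fraction"}``
    (fraction is NaN for empty bins).  Pairs outside the outermost edges
    are ignored.
    """
    edges = np.asarray(bin_edges_s, dtype=float)
    gaps = np.array([p.gap_s for p in pairs])
    match = np.array([p.wing_match for p in pairs], dtype=bool)
    out = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        sel = (gaps >= lo) & (gaps < hi)
        out.append(
            {
                "lo_s": float(lo),
                "hi_s": float(hi),
                "n": int(sel.sum()),
                "fraction": float(match[sel].mean()) if sel.any() else float("nan"),
            }
        )
    return out
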