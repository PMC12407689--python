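"""Self-contained evaluation experiments on the synthetic generator.

These routines regenerate synthetic recordings from scratch and measure
detector performance, spectral accuracy, and parameter recovery.  They
back both the test suite and ``scripts/acceptance.py``.
"""

from __future__ import annotations

import numpy as np

from . import detect, ethogram as etho, kinematics, linkage as lk, synth
from .core import BoutRecord

__all__ = [
    "waggle_detection_benchmark",
    "waggle_frequency_benchmark",
    "transition_recovery",
    "wing_match_recovery",
]


def _detect_on_recording(config: synth.SynthConfig, seed: int):
    """Sample + render one recording and run the waggle detector on it."""
    truth = synth.sample_ethogram(config, seed=seed)
    meta, tracks, _, truth = synth.render_recording(config, truth, seed=seed, with_audio=False)
    male = kinematics.interpolate_wing_tips(tracks[0])
    wl, wr = kinematics.wing_angles(male)
    detected = detect.detect_waggle(wl, wr, config.fps, recording_id=meta.recording_id)
    truth_waggles = [b for b in truth if b.behavior == "waggle"]
    return detected, truth_waggles


def waggle_detection_benchmark(
    n_recordings: int = 30,
    duration_s: float = 300.0,
    base_seed: int = 1,
    iou_min: float = 0.3,
    config: synth.SynthConfig | None = None,
) -> dict:
    """Precision/recall of the waggle detector against generator ground truth.

    Renders ``n_recordings`` seeded recordings with default tracking
    noise and wing-tip dropout, detects waggle bouts from the extracted
    wing angles, and pools greedy IoU matches across recordings.
    """
    base = config or synth.SynthConfig(duration_s=duration_s)
    matched = n_det = n_truth = 0
    for k in range(n_recordings):
        seed = base_seed + k
        cfg = synth.SynthConfig.from_dict({**base.to_dict(), "seed": seed})
        detected, truth = _detect_on_recording(cfg, seed)
        res = detect.match_bouts(detected, truth, iou_min=iou_min)
        matched += res.n_matched
        n_det += res.n_detected
        n_truth += res.n_truth
    return {
        "precision": matched / n_det if n_det else float("nan"),
        "recall": matched / n_truth if n_truth else float("nan"),
        "n_detected": n_det,
        "n_truth": n_truth,
        "n_matched": matched,
        "n_recordings": n_recordings,
    }


def waggle_frequency_benchmark(
    n_bouts: int = 200,
    duration_s: float = 1.0,
    fps: float = 150.0,
    freq_hz: float = 10.6,
    amp_range: tuple[float, float] = (20.0, 40.0),
    noise_deg: float = 2.0,
    seed: int = 0,
) -> dict:
    """Median per-bout peak frequency recovered by the spectral analyzer.

    Generates ``n_bouts`` stand-alone anti-phase waggle bouts at a fixed
    frequency with random amplitudes and white angle noise, runs
    :func:`flywaggle.detect.waggle_spectrum` on each, and reports the
    median dominant-wing peak frequency.
    """
    rng = np.random.default_rng(seed)
    peaks = []
    n = int(round(duration_s * fps))
    for _ in range(n_bouts):
        amp = float(rng.uniform(*amp_range))
        wl, wr = synth.synth_waggle_bout(
            duration_s, fps, freq_hz, amp, noise_deg=noise_deg, rng=rng
        )
        bout = BoutRecord("bench", "waggle", 0, n, "left", "truth")
        spec = detect.waggle_spectrum(bout, wl, wr, fps)
        peaks.append(spec.peak_freq_l)  # left wing is dominant by construction
    peaks = np.asarray(peaks)
    return {
        "median_peak_hz": float(np.median(peaks)),
        "mean_peak_hz": float(np.mean(peaks)),
        "n_bouts": n_bouts,
    }


def _truth_ethogram(config: synth.SynthConfig, seed: int) -> etho.Ethogram:
    """Ethogram from ground-truth bouts with the default duration filtering."""
    bouts = synth.sample_ethogram(config, seed=seed)
    thresholds = etho.DurationThresholds()
    fps = config.fps
    kept = []
    n_excluded = 0
    for b in bouts:
        if b.behavior == "stillness" and b.duration_s(fps) < thresholds.stillness_s:
            n_excluded += 1
            continue
        if b.behavior == "other" and b.duration_s(fps) < thresholds.other_s:
            n_excluded += 1
            continue
        kept.append(b)
    return etho.Ethogram(
        recording_id=bouts[0].recording_id if bouts else f"synth-{seed}",
        fps=fps,
        n_frames=config.n_frames,
        bouts=kept,
        n_excluded=n_excluded,
    )


def transition_recovery(
    n_recordings: int = 100,
    duration_s: float = 60.0,
    base_seed: int = 0,
    config: synth.SynthConfig | None = None,
) -> dict:
    """Recover the generator transition matrix from sampled bout sequences.

    Estimates pooled transition probabilities from ``n_recordings``
    ground-truth ethograms (with standard duration filtering, which
    bridges the sub-threshold linked-gap bouts) and compares each entry
    to the configured matrix in units of its binomial standard error.
    """
    base = config or synth.SynthConfig(duration_s=duration_s)
    ethos = []
    for k in range(n_recordings):
        cfg = synth.SynthConfig.from_dict({**base.to_dict(), "seed": base_seed + k})
        ethos.append(_truth_ethogram(cfg, base_seed + k))
    result = etho.transition_matrix(ethos)
    target = base.resolved_transition()
    rows = result.counts.sum(axis=1)
    se = np.sqrt(np.maximum(target * (1 - target), 1e-12) / np.maximum(rows[:, None], 1))
    z = (result.probs - target) / se
    off = ~np.eye(4, dtype=bool)
    return {
        "estimated": result.probs,
        "target": target,
        "z": z,
        "max_abs_z": float(np.max(np.abs(z[off]))),
        "n_transitions": int(result.counts.sum()),
    }


def wing_match_recovery(
    n_recordings: int = 100,
    duration_s: float = 60.0,
    base_seed: int = 0,
    config: synth.SynthConfig | None = None,
) -> dict:
    """Recover the linked-pair wing-match probability from ground truth.

    Pools waggle->song pairs across recordings, classifies them with the
    exact 1-D k-means gap split, and compares the linked-stratum match
    fraction to the configured ``wing_match_prob_linked`` in standard
    errors.
    """
    base = config or synth.SynthConfig(duration_s=duration_s)
    waggles: list[BoutRecord] = []
    songs: list[BoutRecord] = []
    for k in range(n_recordings):
        cfg = synth.SynthConfig.from_dict({**base.to_dict(), "seed": base_seed + k})
        bouts = synth.sample_ethogram(cfg, seed=base_seed + k)
        waggles += [b for b in bouts if b.behavior == "waggle"]
        songs += [b for b in bouts if b.behavior == "song"]
    pairs = lk.waggle_song_gaps(waggles, songs, base.fps)
    gaps = np.array([p.gap_s for p in pairs])
    threshold, labels = lk.classify_linked(gaps)
    summary = lk.wing_match_fraction(pairs, labels)
    p = base.wing_match_prob_linked
    se = np.sqrt(p * (1 - p) / max(summary.n_linked, 1))
    return {
        "threshold_s": threshold,
        "linked_fraction_observed": summary.n_linked / summary.n,
        "linked_match": summary.linked,
        "unlinked_match": summary.unlinked,
        "target": p,
        "abs_z": abs((summary.linked - p) / se) if summary.linked is not None else np.inf,
        "n_pairs": summary.n,
        "n_linked": summary.n_linked,
    }
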