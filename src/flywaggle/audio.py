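"""Multichannel microphone preprocessing and amplitude measures.

The recording chamber carries up to nine floor microphones.  The raw
channels are reduced to a single trace by baseline (median) subtraction,
a zero-phase 50-1000 Hz band-pass, and per-sample averaging of the three
channels with the largest instantaneous absolute amplitude.
"""

from __future__ import annotations

import numpy as np
from scipy.signal import butter, sosfiltfilt

__all__ = ["preprocess_audio", "rms_amplitude", "audio_frame_align"]


def bandpass_sos(band: tuple[float, float], fs: float, order: int = 4):
    low, high = band
    if not 0 < low < high:
        raise ValueError(f"invalid band {band}")
    if fs <= 2 * high:
        raise ValueError(
            f"sample rate {fs} Hz cannot realize a band-pass up to {high} Hz"
        )
    return butter(order, [low, high], btype="bandpass", fs=fs, output="sos")


def preprocess_audio(
    channels: np.ndarray,
    audio_sr: float,
    band: tuple[float, float] = (50.0, 1000.0),
    top_k: int = 3,
    order: int = 4,
) -> np.ndarray:
    """Reduce (channels x samples) microphone data to a single trace.

    Per channel: subtract the channel median (baseline), then apply a
    zero-phase Butterworth band-pass (default 50-1000 Hz, order 4,
    forward-backward).  Per sample: rank channels by absolute filtered
    amplitude and average the signed values of the top ``top_k`` (all
    channels if fewer are available).  Channel order does not matter.
    """
    channels = np.atleast_2d(np.asarray(channels, dtype=float))
    sos = bandpass_sos(band, audio_sr, order)
    filtered = sosfiltfilt(sos, channels - np.median(channels, axis=1, keepdims=True), axis=1)
    k = min(top_k, filtered.shape[0])
    if filtered.shape[0] == k:
        return filtered.mean(axis=0)
    # indices of the k largest |amplitude| per sample
    top = np.argpartition(-np.abs(filtered), k - 1, axis=0)[:k]
    picked = np.take_along_axis(filtered, top, axis=0)
    return picked.mean(axis=0)


def rms_amplitude(trace: np.ndarray, audio_sr: float, window_s: float = 0.05) -> np.ndarray:
    """Sliding root-mean-square amplitude with a centred window.

    The window shrinks symmetrically near the trace edges.
    """
    trace = np.asarray(trace, dtype=float)
    n = trace.size
    half = max(1, int(round(window_s * audio_sr / 2)))
    csum = np.concatenate([[0.0], np.cumsum(trace**2)])
    idx = np.arange(n)
    lo = np.maximum(idx - half, 0)
    hi = np.minimum(idx + half + 1, n)
    return np.sqrt((csum[hi] - csum[lo]) / (hi - lo))


def audio_frame_align(
    trace: np.ndarray,
    audio_sr: float,
    fps: float,
    n_frames: int,
    reducer=None,
) -> np.ndarray:
    """Reduce an audio trace to one value per video frame.

    Frame ``t`` owns the sample span ``[round(t*sr/fps), round((t+1)*sr/fps))``;
    the spans partition the first ``n_frames/fps`` seconds of the trace.
    The default reducer is RMS.
    """
    trace = np.asarray(trace, dtype=float)
    bounds = np.round(np.arange(n_frames + 1) * audio_sr / fps).astype(int)
    bounds = np.minimum(bounds, trace.size)
    out = np.empty(n_frames)
    if reducer is None:
        csum = np.concatenate([[0.0], np.cumsum(trace**2)])
        lo, hi = bounds[:-1], bounds[1:]
        width = np.maximum(hi - lo, 1)
        out = np.sqrt((csum[hi] - csum[lo]) / width)
        out[hi <= lo] = 0.0
        return out
    for t in range(n_frames):
        seg = trace[bounds[t] : bounds[t + 1]]
        out[t] = reducer(seg) if seg.size else 0.0
    return out
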