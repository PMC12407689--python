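"""Synthetic two-fly courtship recordings with known ground truth.

A semi-Markov generator produces an alternating sequence of behavioral
bouts (stillness, waggle, song, other) with log-normal durations, then
renders it into pose tracks and a multichannel audio trace carrying the
kinematic signatures the analysis pipeline looks for:

* waggle bouts: both wings oscillate in anti-phase at a per-bout
  frequency drawn around 10.6 Hz, at reduced extension angles, with no
  audio signature, while both flies stay essentially stationary;
* song bouts: one (dominant) wing holds a large extension angle and the
  audio gains an amplitude-modulated carrier;
* stillness: both flies' speeds stay below the sex-specific thresholds,
  and the male decelerates over ~1 s before each waggle onset;
* tracker imperfections last: temporally correlated positional jitter,
  white wing-angle noise, and random wing-tip dropout.

Identical ``(config, seed)`` gives bit-identical output.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict

import numpy as np
import yaml

from .core import BEHAVIORS, BoutRecord, PoseTrack, RecordingMeta

logger = logging.getLogger(__name__)

__all__ = ["SynthConfig", "ConfigError", "sample_ethogram", "render_recording",
           "synth_waggle_bout"]

STATE_INDEX = {s: i for i, s in enumerate(BEHAVIORS)}


class ConfigError(ValueError):
    """Raised for an invalid generator configuration."""


def _default_transition() -> list[list[float]]:
    # rows/cols ordered stillness, waggle, song, other; zero diagonal
    return [
        [0.00, 0.60, 0.20, 0.20],
        [0.25, 0.00, 0.60, 0.15],
        [0.55, 0.25, 0.00, 0.20],
        [0.50, 0.30, 0.20, 0.00],
    ]


@dataclass
class SynthConfig:
    """Full parameterization of the synthetic recording generator.

    Defaults reproduce the study's recording conditions (150 fps,
    30.3 px/mm, 10 kHz audio, 10.6 Hz mean waggle frequency) with
    generator-specific choices (amplitudes, speeds, noise) documented in
    the methods note.
    """

    seed: int = 0
    duration_s: float = 300.0
    fps: float = 150.0
    px_per_mm: float = 30.3
    audio_sr: int = 10_000
    n_audio_channels: int = 9
    species_tag: str = "synthetic"

    # semi-Markov structure
    state_transition: list[list[float]] = field(default_factory=_default_transition)
    duration_median_s: dict[str, float] = field(
        default_factory=lambda: {"stillness": 2.5, "waggle": 0.8, "song": 1.2, "other": 2.5}
    )
    duration_log_sd: dict[str, float] = field(
        default_factory=lambda: {"stillness": 0.5, "waggle": 0.4, "song": 0.4, "other": 0.5}
    )

    # waggle kinematics
    waggle_freq_mean_hz: float = 10.6
    waggle_freq_sd_hz: float = 1.0
    waggle_amp_deg: tuple[float, float] = (20.0, 40.0)
    nondominant_amp_ratio: float = 0.8
    waggle_min_cycles: float = 3.5

    # song
    song_wing_deg: tuple[float, float] = (60.0, 90.0)
    song_carrier_hz: float = 220.0
    song_mod_hz: float = 4.0
    song_carrier_amp: float = 0.4
    audio_noise: float = 0.005

    # baseline wings and locomotion
    baseline_wing_deg: float = 3.0
    baseline_wing_deg_sd: float = 2.0
    speed_mm_s: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "stillness": (0.08, 0.05),
            "waggle": (0.08, 0.05),
            "song": (6.0, 1.5),
            "other": (4.0, 3.0),
        }
    )
    decel_ramp_s: float = 1.0

    # tracker imperfections
    track_noise_mm: float = 0.066
    noise_corr_frames: float = 20.0
    wing_noise_deg: float = 2.0
    wingtip_dropout: float = 0.02

    # waggle->song linkage
    linked_fraction: float | None = 0.6
    linked_gap_max_s: float = 0.15
    wing_match_prob_linked: float = 0.9
    wing_match_prob_unlinked: float = 0.6

    # morphology / arena
    arena_mm: float = 30.0
    body_length_mm: float = 1.5
    wing_length_mm: float = 2.2

    def __post_init__(self) -> None:
        self.validate()

    @property
    def n_frames(self) -> int:
        return int(round(self.duration_s * self.fps))

    def validate(self) -> None:
        T = np.asarray(self.state_transition, dtype=float)
        if T.shape != (4, 4):
            raise ConfigError("state_transition must be 4x4")
        if (T < 0).any():
            raise ConfigError("state_transition entries must be non-negative")
        if np.diag(T).any():
            raise ConfigError("state_transition diagonal must be zero (no self-transitions)")
        rowsums = T.sum(axis=1)
        if (rowsums == 0).any():
            dead = BEHAVIORS[int(np.argmax(rowsums == 0))]
            raise ConfigError(f"degenerate transition row (all zero) for state {dead!r}")
        if not np.allclose(rowsums, 1.0, atol=1e-8):
            raise ConfigError("state_transition rows must each sum to 1")
        for name, prob in [
            ("wingtip_dropout", self.wingtip_dropout),
            ("wing_match_prob_linked", self.wing_match_prob_linked),
            ("wing_match_prob_unlinked", self.wing_match_prob_unlinked),
        ]:
            if not 0.0 <= prob <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1]")
        if self.linked_fraction is not None and not 0.0 <= self.linked_fraction <= 1.0:
            raise ConfigError("linked_fraction must be in [0, 1]")
        for name, sd in [
            ("waggle_freq_sd_hz", self.waggle_freq_sd_hz),
            ("baseline_wing_deg_sd", self.baseline_wing_deg_sd),
            ("track_noise_mm", self.track_noise_mm),
            ("wing_noise_deg", self.wing_noise_deg),
        ]:
            if sd < 0:
                raise ConfigError(f"{name} must be >= 0")

    def resolved_transition(self) -> np.ndarray:
        """Transition matrix with ``linked_fraction`` folded into the waggle row.

        ``linked_fraction`` is the probability that a waggle bout is
        directly followed by song (a "linked" pair with a short gap); it
        overrides the waggle->song entry, rescaling the rest of the row.
        """
        T = np.asarray(self.state_transition, dtype=float).copy()
        if self.linked_fraction is None:
            return T
        w, s = STATE_INDEX["waggle"], STATE_INDEX["song"]
        rest = T[w].sum() - T[w, s]
        if rest == 0 and self.linked_fraction < 1:
            raise ConfigError("waggle row has no non-song mass to rescale")
        T[w, s] = self.linked_fraction
        if rest > 0:
            scale = (1.0 - self.linked_fraction) / rest
            for j in range(4):
                if j != s:
                    T[w, j] *= scale
        return T

    def meta(self, recording_id: str) -> RecordingMeta:
        return RecordingMeta(
            recording_id=recording_id,
            fps=self.fps,
            audio_sr=self.audio_sr,
            px_per_mm=self.px_per_mm,
            n_frames=self.n_frames,
            n_flies=2,
            species_tag=self.species_tag,
        )

    # -- serialization --------------------------------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        d["waggle_amp_deg"] = list(self.waggle_amp_deg)
        d["song_wing_deg"] = list(self.song_wing_deg)
        d["speed_mm_s"] = {k: list(v) for k, v in self.speed_mm_s.items()}
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SynthConfig":
        d = dict(d)
        for key in ("waggle_amp_deg", "song_wing_deg"):
            if key in d:
                d[key] = tuple(d[key])
        if "speed_mm_s" in d:
            d["speed_mm_s"] = {k: tuple(v) for k, v in d["speed_mm_s"].items()}
        unknown = set(d) - set(cls.__dataclass_fields__)
        if unknown:
            raise ConfigError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**d)

    def to_yaml(self, path: str) -> str:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)
        return path

    @classmethod
    def from_yaml(cls, path: str) -> "SynthConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


# ---------------------------------------------------------------------------
# bout sequence sampling
# ---------------------------------------------------------------------------

def _lognormal_frames(rng, median_s: float, log_sd: float, fps: float) -> int:
    dur = median_s * np.exp(log_sd * rng.standard_normal())
    return max(1, int(round(dur * fps)))


def sample_ethogram(config: SynthConfig, seed: int | None = None) -> list[BoutRecord]:
    """Sample a ground-truth bout sequence tiling ``[0, n_frames)``.

    States follow :meth:`SynthConfig.resolved_transition` with log-normal
    per-state durations; no two consecutive bouts share a label.  Every
    direct waggle->song transition is a "linked" pair: a gap shorter than
    ``linked_gap_max_s`` is inserted as (sub-threshold) "other" frames.
    Dominant wings are assigned so that the song wing matches the
    preceding waggle's wing with probability ``wing_match_prob_linked``
    for linked pairs and ``wing_match_prob_unlinked`` otherwise.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    T = config.resolved_transition()
    n_frames = config.n_frames
    rec_id = f"synth-{config.seed if seed is None else seed}"
    max_gap = int(config.linked_gap_max_s * config.fps)
    min_waggle_frames = int(
        np.ceil(
            config.waggle_min_cycles
            / max(config.waggle_freq_mean_hz - 2 * config.waggle_freq_sd_hz, 1.0)
            * config.fps
        )
    )

    bouts: list[dict] = []
    state = int(rng.integers(0, 4))
    last_waggle_wing: str | None = None
    cursor = 0
    prev_was_linked_waggle = False
    while cursor < n_frames:
        label = BEHAVIORS[state]
        frames = _lognormal_frames(
            rng, config.duration_median_s[label], config.duration_log_sd[label], config.fps
        )
        wing = "none"
        if label == "waggle":
            frames = max(frames, min_waggle_frames)
            wing = "left" if rng.random() < 0.5 else "right"
        elif label == "song":
            if prev_was_linked_waggle:
                p = config.wing_match_prob_linked
            elif last_waggle_wing is not None:
                p = config.wing_match_prob_unlinked
            else:
                p = 0.5
            ref = last_waggle_wing or ("left" if rng.random() < 0.5 else "right")
            if rng.random() < p:
                wing = ref
            else:
                wing = "right" if ref == "left" else "left"
        end = min(cursor + frames, n_frames)
        bouts.append({"behavior": label, "start": cursor, "end": end, "wing": wing})
        if label == "waggle":
            last_waggle_wing = wing
        cursor = end
        if cursor >= n_frames:
            break
        nxt = int(rng.choice(4, p=T[state]))
        prev_was_linked_waggle = False
        if label == "waggle" and BEHAVIORS[nxt] == "song":
            gap = int(rng.integers(0, max_gap + 1)) if max_gap > 0 else 0
            gap = min(gap, n_frames - cursor)
            if gap > 0:
                bouts.append(
                    {"behavior": "other", "start": cursor, "end": cursor + gap, "wing": "none"}
                )
                cursor += gap
            prev_was_linked_waggle = True
        state = nxt

    # a truncated tail waggle too short to oscillate is left as "other"
    if bouts and bouts[-1]["behavior"] == "waggle" and (
        bouts[-1]["end"] - bouts[-1]["start"] < min_waggle_frames
    ):
        bouts[-1]["behavior"] = "other"
        bouts[-1]["wing"] = "none"
        if len(bouts) > 1 and bouts[-2]["behavior"] == "other":
            bouts[-2]["end"] = bouts[-1]["end"]
            bouts.pop()

    return [
        BoutRecord(
            recording_id=rec_id,
            behavior=b["behavior"],
            start=b["start"],
            end=b["end"],
            dominant_wing=b["wing"],
            provenance="truth",
        )
        for b in bouts
    ]


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

def _correlated_noise(rng, n: int, sd: float, corr_frames: float) -> np.ndarray:
    """Gaussian noise with ~``corr_frames`` correlation length and SD ``sd``."""
    white = rng.standard_normal(n)
    if corr_frames <= 0:
        return sd * white
    half = int(np.ceil(4 * corr_frames))
    t = np.arange(-half, half + 1)
    kernel = np.exp(-0.5 * (t / corr_frames) ** 2)
    kernel /= np.sqrt(np.sum(kernel**2))  # unit output variance
    padded = np.concatenate([white[:half][::-1], white, white[-half:][::-1]])
    return sd * np.convolve(padded, kernel, mode="valid")


def _smooth(x: np.ndarray, sigma: float) -> np.ndarray:
    half = int(np.ceil(3 * sigma))
    t = np.arange(-half, half + 1)
    k = np.exp(-0.5 * (t / sigma) ** 2)
    k /= k.sum()
    padded = np.concatenate([np.full(half, x[0]), x, np.full(half, x[-1])])
    return np.convolve(padded, k, mode="valid")


def _taper(n: int, ramp: int) -> np.ndarray:
    """Unit plateau with half-cosine on/off ramps of ``ramp`` samples."""
    env = np.ones(n)
    r = min(ramp, n // 2)
    if r > 0:
        edge = 0.5 * (1 - np.cos(np.linspace(0, np.pi, r)))
        env[:r] = edge
        env[-r:] = edge[::-1]
    return env


def _waggle_angles(n: int, fps: float, freq: float, amp: float, nd_ratio: float
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Anti-phase wing-angle oscillations for one bout (dominant, non-dominant).

    The dominant wing sweeps 0..amp as ``(amp/2)(1 - cos)``; the
    non-dominant sweeps in exact anti-phase at ``nd_ratio`` amplitude.
    Short half-cosine ramps keep onset/offset transients small.
    """
    t = np.arange(n) / fps
    env = _taper(n, int(0.05 * fps))
    dom = (amp / 2.0) * (1.0 - np.cos(2 * np.pi * freq * t)) * env
    nond = (nd_ratio * amp / 2.0) * (1.0 + np.cos(2 * np.pi * freq * t)) * env
    return dom, nond


def synth_waggle_bout(
    duration_s: float,
    fps: float,
    freq_hz: float,
    amp_deg: float,
    noise_deg: float = 0.0,
    rng: np.random.Generator | None = None,
    nd_ratio: float = 0.8,
    baseline_deg: float = 3.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Stand-alone anti-phase waggle bout; returns (left, right) wing angles.

    The left wing is dominant.  Used for spectral benchmarking and in
    tests; :func:`render_recording` uses the same construction.
    """
    rng = rng or np.random.default_rng(0)
    n = int(round(duration_s * fps))
    dom, nond = _waggle_angles(n, fps, freq_hz, amp_deg, nd_ratio)
    wl = baseline_deg + dom
    wr = baseline_deg + nond
    if noise_deg > 0:
        wl = wl + rng.normal(0, noise_deg, n)
        wr = wr + rng.normal(0, noise_deg, n)
    return np.clip(wl, 0, 180), np.clip(wr, 0, 180)


def _integrate_locomotion(rng, config, speed, n):
    """Integrate a smooth heading random walk at the given per-frame speed."""
    center = config.arena_mm / 2.0
    pos = np.empty((n, 2))
    pos[0] = center + (rng.random(2) - 0.5) * config.arena_mm / 3.0
    psi = rng.random() * 2 * np.pi
    headings = np.empty((n, 2))
    turn_noise = rng.standard_normal(n)
    for t in range(n):
        headings[t] = (np.cos(psi), np.sin(psi))
        if t + 1 < n:
            step = speed[t] / config.fps
            nxt = pos[t] + step * headings[t]
            # steer back toward the arena centre when close to the wall
            r = np.hypot(nxt[0] - center, nxt[1] - center)
            margin = config.arena_mm / 2.0 - 4.0
            if r > margin:
                desired = np.arctan2(center - nxt[1], center - nxt[0])
                dpsi = np.angle(np.exp(1j * (desired - psi)))
                psi += np.clip(dpsi, -0.08, 0.08) * min((r - margin), 4.0)
            psi += (0.002 + 0.004 * min(speed[t], 6.0)) * turn_noise[t]
            pos[t + 1] = nxt
    return pos, headings


def render_recording(
    config: SynthConfig,
    ethogram: list[BoutRecord],
    seed: int | None = None,
    with_audio: bool = True,
) -> tuple[RecordingMeta, list[PoseTrack], np.ndarray | None, list[BoutRecord]]:
    """Render a bout sequence into pose tracks (and optionally audio).

    Returns ``(meta, [male, female], audio, truth)`` where ``truth`` is
    the ground-truth bout list, adjusted only if a waggle bout was too
    short for three cycles at its drawn frequency (it is then extended to
    the floor duration, nibbling frames from its successors; logged).
    Noise and dropout are applied last and never alter the ground truth.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n = config.n_frames
    fps = config.fps
    rec_id = ethogram[0].recording_id if ethogram else f"synth-{config.seed}"
    meta = config.meta(rec_id)

    # --- waggle parameters and duration-floor adjustment -----------------
    work = [
        {"behavior": b.behavior, "start": b.start, "end": b.end, "wing": b.dominant_wing}
        for b in sorted(ethogram, key=lambda b: b.start)
    ]
    for i, b in enumerate(work):
        if b["behavior"] != "waggle":
            continue
        freq = max(float(rng.normal(config.waggle_freq_mean_hz, config.waggle_freq_sd_hz)), 0.5)
        amp = float(rng.uniform(*config.waggle_amp_deg))
        b["freq"], b["amp"] = freq, amp
        need = int(np.ceil(config.waggle_min_cycles / freq * fps))
        if b["end"] - b["start"] < need:
            new_end = min(b["start"] + need, n)
            logger.info(
                "waggle bout [%d, %d) shorter than %.1f cycles at %.2f Hz; "
                "extending to %d frames",
                b["start"], b["end"], config.waggle_min_cycles, freq, new_end - b["start"],
            )
            b["end"] = new_end
            for nxt in work[i + 1 :]:
                if nxt["start"] < new_end:
                    nxt["start"] = min(new_end, nxt["end"])
    work = [b for b in work if b["end"] > b["start"]]
    truth = [
        BoutRecord(rec_id, b["behavior"], b["start"], b["end"], b["wing"], "truth")
        for b in work
    ]

    labels = np.full(n, STATE_INDEX["other"], dtype=int)
    for b in work:
        labels[b["start"] : b["end"]] = STATE_INDEX[b["behavior"]]

    # --- locomotion -------------------------------------------------------
    tracks = []
    for sex, col in (("male", 0), ("female", 1)):
        speed = np.array([config.speed_mm_s[BEHAVIORS[s]][col] for s in labels], dtype=float)
        still = config.speed_mm_s["stillness"][col]
        ramp_frames = int(config.decel_ramp_s * fps)
        for b in work:
            if b["behavior"] != "waggle":
                continue
            o = b["start"]
            lo = max(0, o - ramp_frames)
            if o > lo:
                ramp = np.linspace(speed[lo], still, o - lo)
                speed[lo:o] = np.minimum(speed[lo:o], ramp)
        speed = _smooth(speed, sigma=0.1 * fps)
        pos, headings = _integrate_locomotion(rng, config, speed, n)

        # --- wing angles --------------------------------------------------
        base_l = np.clip(
            config.baseline_wing_deg
            + _correlated_noise(rng, n, config.baseline_wing_deg_sd, 10.0),
            0.0, None,
        )
        base_r = np.clip(
            config.baseline_wing_deg
            + _correlated_noise(rng, n, config.baseline_wing_deg_sd, 10.0),
            0.0, None,
        )
        wl, wr = base_l, base_r
        if sex == "male":
            for b in work:
                s, e = b["start"], b["end"]
                seg = e - s
                if b["behavior"] == "waggle":
                    dom, nond = _waggle_angles(
                        seg, fps, b["freq"], b["amp"], config.nondominant_amp_ratio
                    )
                    if b["wing"] == "left":
                        wl[s:e] += dom
                        wr[s:e] += nond
                    else:
                        wr[s:e] += dom
                        wl[s:e] += nond
                elif b["behavior"] == "song":
                    ext = rng.uniform(*config.song_wing_deg)
                    env = _taper(seg, int(0.05 * fps)) * ext
                    if b["wing"] == "left":
                        wl[s:e] += env
                    else:
                        wr[s:e] += env
        if config.wing_noise_deg > 0:
            wl = wl + rng.normal(0, config.wing_noise_deg, n)
            wr = wr + rng.normal(0, config.wing_noise_deg, n)
        wl = np.clip(wl, 0.0, 175.0)
        wr = np.clip(wr, 0.0, 175.0)

        # --- assemble nodes ----------------------------------------------
        tail = -headings
        coords = np.empty((n, 4, 2))
        coords[:, 1, :] = pos
        coords[:, 0, :] = pos + config.body_length_mm * headings
        for j, (ang, sign) in ((2, (wl, +1.0)), (3, (wr, -1.0))):
            theta = sign * np.radians(ang)
            cos, sin = np.cos(theta), np.sin(theta)
            rx = cos * tail[:, 0] - sin * tail[:, 1]
            ry = sin * tail[:, 0] + cos * tail[:, 1]
            coords[:, j, 0] = pos[:, 0] + config.wing_length_mm * rx
            coords[:, j, 1] = pos[:, 1] + config.wing_length_mm * ry

        # --- tracker noise and dropout ------------------------------------
        if config.track_noise_mm > 0:
            for j in range(4):
                for a in range(2):
                    coords[:, j, a] += _correlated_noise(
                        rng, n, config.track_noise_mm, config.noise_corr_frames
                    )
        mask = np.ones((n, 4), dtype=bool)
        if config.wingtip_dropout > 0:
            drop = rng.random((n, 2)) < config.wingtip_dropout
            mask[:, 2:] = ~drop
            coords[:, 2:, :][drop] = np.nan
        tracks.append(PoseTrack(fly_id=sex, coords=coords, mask=mask))

    # --- audio ------------------------------------------------------------
    audio = None
    if with_audio:
        n_samples = int(round(n / fps * config.audio_sr))
        audio = rng.standard_normal(
            (config.n_audio_channels, n_samples), dtype=np.float32
        ) * np.float32(config.audio_noise)
        gains = rng.uniform(0.5, 1.0, config.n_audio_channels).astype(np.float32)
        for b in work:
            if b["behavior"] != "song":
                continue
            s0 = int(round(b["start"] / fps * config.audio_sr))
            s1 = min(int(round(b["end"] / fps * config.audio_sr)), n_samples)
            if s1 <= s0:
                continue
            t = np.arange(s0, s1) / config.audio_sr
            carrier = (
                config.song_carrier_amp
                * (0.6 + 0.4 * np.sin(2 * np.pi * config.song_mod_hz * t))
                * np.sin(2 * np.pi * config.song_carrier_hz * t)
            ).astype(np.float32)
            carrier *= _taper(s1 - s0, int(0.01 * config.audio_sr)).astype(np.float32)
            audio[:, s0:s1] += gains[:, None] * carrier
        np.clip(audio, -1.0, 1.0, out=audio)

    return meta, tracks, audio, truth
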