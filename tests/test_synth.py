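"""The synthetic recording generator: determinism, construction guarantees."""

import numpy as np
import pytest
from scipy.signal import butter, hilbert, sosfiltfilt

from flywaggle import kinematics as kin
from flywaggle import synth
from flywaggle.core import BoutRecord
from flywaggle.synth import ConfigError, SynthConfig


def test_deterministic_given_seed(small_config):
    a = synth.sample_ethogram(small_config)
    b = synth.sample_ethogram(small_config)
    assert a == b
    _, ta, aud_a, tr_a = synth.render_recording(small_config, a)
    _, tb, aud_b, tr_b = synth.render_recording(small_config, b)
    assert tr_a == tr_b
    for x, y in zip(ta, tb):
        assert np.array_equal(x.coords, y.coords, equal_nan=True)
    assert np.array_equal(aud_a, aud_b)


def test_deterministic_cycle_chain():
    cycle = [
        [0, 1, 0, 0],  # stillness -> waggle
        [0, 0, 1, 0],  # waggle -> song
        [1, 0, 0, 0],  # song -> stillness
        [1, 0, 0, 0],  # other -> stillness
    ]
    cfg = SynthConfig(
        duration_s=60,
        seed=2,
        state_transition=cycle,
        linked_fraction=None,
        linked_gap_max_s=0.0,
    )
    labels = [b.behavior for b in synth.sample_ethogram(cfg)]
    nxt = {"stillness": "waggle", "waggle": "song", "song": "stillness", "other": "stillness"}
    for a, b in zip(labels[:-1], labels[1:]):
        assert b == nxt[a]


def test_degenerate_transition_row_rejected():
    bad = [[0, 1, 0, 0], [0, 0, 0, 0], [1, 0, 0, 0], [1, 0, 0, 0]]
    with pytest.raises(ConfigError, match="waggle"):
        SynthConfig(state_transition=bad, linked_fraction=None)


def test_linked_fraction_resolves_waggle_row():
    cfg = SynthConfig(linked_fraction=0.8)
    T = cfg.resolved_transition()
    w, s = 1, 2
    assert np.isclose(T[w, s], 0.8)
    assert np.allclose(T.sum(axis=1), 1.0)


def test_ethogram_tiles_recording(small_config):
    bouts = synth.sample_ethogram(small_config)
    assert bouts[0].start == 0
    assert bouts[-1].end == small_config.n_frames
    for a, b in zip(bouts[:-1], bouts[1:]):
        assert a.end == b.start
        assert a.behavior != b.behavior


def test_linked_gaps_below_threshold(small_config):
    """Every waggle directly followed by song has a gap under 0.15 s."""
    bouts = synth.sample_ethogram(small_config)
    fps = small_config.fps
    n_linked = 0
    for i, b in enumerate(bouts):
        if b.behavior != "waggle":
            continue
        for nxt in bouts[i + 1 :]:
            if nxt.behavior == "song":
                gap = (nxt.start - b.end) / fps
                if gap < 0.15:
                    n_linked += 1
                break
            if nxt.behavior != "other" or (nxt.end - nxt.start) / fps >= 0.15:
                break
    assert n_linked > 0


def test_rendered_waggle_is_antiphase(clean_config):
    """Noise-free rendering: Hilbert phase difference ~ pi inside the bout."""
    cfg = SynthConfig.from_dict(
        {**clean_config.to_dict(), "waggle_freq_mean_hz": 12.0, "waggle_freq_sd_hz": 0.0}
    )
    n = cfg.n_frames
    rec = f"synth-{cfg.seed}"
    truth = [
        BoutRecord(rec, "other", 0, 3000, "none", "truth"),
        BoutRecord(rec, "waggle", 3000, 3600, "left", "truth"),
        BoutRecord(rec, "other", 3600, n, "none", "truth"),
    ]
    _, tracks, _, truth2 = synth.render_recording(cfg, truth, with_audio=False)
    wl, wr = kin.wing_angles(tracks[0])
    sos = butter(4, (8, 18), btype="bandpass", fs=cfg.fps, output="sos")
    pl = np.angle(hilbert(sosfiltfilt(sos, wl)))
    pr = np.angle(hilbert(sosfiltfilt(sos, wr)))
    dphi = np.abs(np.angle(np.exp(1j * (pl - pr))))
    inside = slice(3000 + 40, 3600 - 40)
    assert np.all(np.abs(dphi[inside] - np.pi) < 0.05)


def test_stillness_only_speeds(clean_config):
    cfg = clean_config
    truth = [BoutRecord("r", "stillness", 0, cfg.n_frames, "none", "truth")]
    _, tracks, _, _ = synth.render_recording(cfg, truth, with_audio=False)
    for track, limit in zip(tracks, (0.2, 0.1)):
        speed = np.abs(kin.forward_speed(track, cfg.fps))
        assert np.nanmax(speed) <= limit + 1e-6


def test_song_audio_rms_margin(clean_config):
    cfg = clean_config
    n = cfg.n_frames
    truth = [
        BoutRecord("r", "other", 0, 4000, "none", "truth"),
        BoutRecord("r", "song", 4000, 5000, "left", "truth"),
        BoutRecord("r", "other", 5000, n, "none", "truth"),
    ]
    _, _, audio_data, _ = synth.render_recording(cfg, truth)
    sr = cfg.audio_sr
    trace = audio_data.mean(axis=0)
    in_song = trace[int(4050 / cfg.fps * sr) : int(4950 / cfg.fps * sr)]
    outside = trace[: int(3900 / cfg.fps * sr)]
    rms = lambda x: np.sqrt(np.mean(x**2))
    assert rms(in_song) >= 5 * rms(outside)


def test_short_waggle_extended_to_min_cycles(clean_config):
    cfg = SynthConfig.from_dict(
        {**clean_config.to_dict(), "waggle_freq_mean_hz": 10.0, "waggle_freq_sd_hz": 0.0}
    )
    n = cfg.n_frames
    truth = [
        BoutRecord("r", "other", 0, 1000, "none", "truth"),
        BoutRecord("r", "waggle", 1000, 1010, "left", "truth"),  # far below 3.5 cycles
        BoutRecord("r", "other", 1010, n, "none", "truth"),
    ]
    _, _, _, adjusted = synth.render_recording(cfg, truth, with_audio=False)
    waggle = [b for b in adjusted if b.behavior == "waggle"][0]
    assert waggle.n_frames >= int(np.ceil(cfg.waggle_min_cycles / 10.0 * cfg.fps))


def test_detector_oracle_coupling_noise_free(clean_config):
    """Every rendered waggle passes the anti-phase detector when noise = 0."""
    from flywaggle import detect

    truth = synth.sample_ethogram(clean_config)
    _, tracks, _, truth = synth.render_recording(clean_config, truth, with_audio=False)
    wl, wr = kin.wing_angles(tracks[0])
    detected = detect.detect_waggle(wl, wr, clean_config.fps)
    waggles = [b for b in truth if b.behavior == "waggle"]
    res = detect.match_bouts(detected, waggles)
    assert res.precision == 1.0 and res.recall == 1.0


def test_config_yaml_round_trip(tmp_path, small_config):
    path = str(tmp_path / "cfg.yaml")
    small_config.to_yaml(path)
    back = synth.SynthConfig.from_yaml(path)
    assert back.to_dict() == small_config.to_dict()


def test_unknown_config_key_rejected():
    with pytest.raises(ConfigError, match="wrong_key"):
        SynthConfig.from_dict({"wrong_key": 1})
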