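"""Kinematic feature extraction: hand-computed cases and vector oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from flywaggle import kinematics as kin
from flywaggle.core import BoutRecord, PoseTrack


def _track(coords_by_node, n=None):
    """Build a PoseTrack from per-node coordinate arrays/constants."""
    n = n or max(np.atleast_2d(v).shape[0] for v in coords_by_node.values())
    coords = np.zeros((n, 4, 2))
    for j, name in enumerate(("head", "thorax", "wing_l", "wing_r")):
        v = np.asarray(coords_by_node.get(name, (0.0, 0.0)), dtype=float)
        coords[:, j, :] = v if v.ndim == 2 else np.broadcast_to(v, (n, 2))
    return PoseTrack("male", coords, np.ones((n, 4), dtype=bool))


# --- interpolation ----------------------------------------------------------

def test_wing_tip_nearest_neighbour_with_tie_to_earlier():
    t = _track({"head": (0, -1)}, n=11)
    t.coords[:, 2, :] = np.arange(11)[:, None]  # wing_l value = frame index
    t.mask[1:10, 2] = False
    t.coords[1:10, 2, :] = np.nan
    out = kin.interpolate_wing_tips(t)
    filled = out.coords[:, 2, 0]
    assert np.array_equal(filled[:6], [0, 0, 0, 0, 0, 0])  # tie at 5 -> earlier
    assert np.array_equal(filled[6:], [10, 10, 10, 10, 10])
    assert out.mask.all()


def test_interpolation_is_identity_without_missing(small_recording):
    _, tracks, _, _ = small_recording
    full = tracks[0].copy()
    full.mask[:] = True
    full.coords[:] = np.nan_to_num(full.coords)
    out = kin.interpolate_wing_tips(full)
    assert np.array_equal(out.coords, full.coords)


def test_all_missing_wing_raises():
    t = _track({"head": (0, -1)}, n=5)
    t.mask[:, 2] = False
    t.coords[:, 2, :] = np.nan
    with pytest.raises(ValueError, match="wing_l"):
        kin.interpolate_wing_tips(t)


# --- thorax smoothing -------------------------------------------------------

def test_smooth_thorax_preserves_constant_and_linear():
    n = 50
    t = _track({"head": (0, -1)}, n=n)
    t.coords[:, 1, 0] = 0.02 * np.arange(n)  # linear
    t.coords[:, 1, 1] = 3.0  # constant
    out = kin.smooth_thorax(t)
    interior = slice(5, n - 5)
    assert np.allclose(out.coords[interior, 1, 0], t.coords[interior, 1, 0], atol=1e-9)
    assert np.allclose(out.coords[:, 1, 1], 3.0, atol=1e-9)


def test_smooth_thorax_leaves_other_nodes_untouched(rng):
    n = 40
    t = _track({"head": (0, -1)}, n=n)
    t.coords[:, 0, :] += rng.normal(0, 1, (n, 2))
    before = t.coords[:, 0, :].copy()
    out = kin.smooth_thorax(t)
    assert np.array_equal(out.coords[:, 0, :], before)


def test_smooth_thorax_window_validation():
    t = _track({"head": (0, -1)}, n=5)
    with pytest.raises(ValueError):
        kin.smooth_thorax(t, sg_window=7, sg_order=3)


# --- wing angles ------------------------------------------------------------

@pytest.mark.parametrize(
    "tip,expected",
    [((0.0, 1.0), 0.0), ((1.0, 0.0), 90.0), ((1.0, 1.0), 45.0)],
)
def test_wing_angle_hand_cases(tip, expected):
    # thorax at origin, head at (0, -1): tail direction is (0, 1)
    t = _track({"head": (0, -1), "thorax": (0, 0), "wing_l": tip, "wing_r": (0, 1)}, n=3)
    wl, _ = kin.wing_angles(t)
    assert np.allclose(wl, expected, atol=1e-9)


def test_wing_angles_match_brute_force_oracle(rng):
    """1,000 random geometries vs an independent atan2-based computation."""
    n = 1000
    coords = rng.normal(0, 5, (n, 4, 2))
    t = PoseTrack("male", coords, np.ones((n, 4), dtype=bool))
    wl, wr = kin.wing_angles(t)
    for i in range(n):
        thorax = coords[i, 1]
        tail = thorax - coords[i, 0]
        for series, j in ((wl, 2), (wr, 3)):
            v = coords[i, j] - thorax
            ang = np.arctan2(v[1], v[0]) - np.arctan2(tail[1], tail[0])
            ang = abs(np.degrees(np.arctan2(np.sin(ang), np.cos(ang))))
            assert abs(series[i] - ang) < 1e-9


def test_zero_body_axis_warns_and_nans():
    t = _track({"head": (0, 0), "thorax": (0, 0), "wing_l": (1, 0)}, n=3)
    with pytest.warns(UserWarning, match="zero-length body axis"):
        wl, _ = kin.wing_angles(t)
    assert np.isnan(wl).all()


# --- forward speed ----------------------------------------------------------

def test_forward_speed_along_heading():
    n = 30
    t = _track({}, n=n)
    t.coords[:, 1, 1] = -0.02 * np.arange(n)  # thorax moves toward head
    t.coords[:, 0, 1] = t.coords[:, 1, 1] - 1.0  # head 1 mm further along -y
    speed = kin.forward_speed(t, fps=150.0)
    assert np.allclose(speed[3:-3], 3.0, atol=1e-9)  # 0.02 mm/frame * 150


def test_forward_speed_stationary_and_perpendicular():
    n = 20
    t = _track({"head": (0, -1)}, n=n)
    assert np.allclose(kin.forward_speed(t, 150.0), 0.0)
    t.coords[:, 1, 0] = 0.05 * np.arange(n)  # x motion, heading along -y
    t.coords[:, 0, 0] = t.coords[:, 1, 0]
    assert np.allclose(kin.forward_speed(t, 150.0), 0.0, atol=1e-9)


# --- z-scoring --------------------------------------------------------------

def test_zscore_moments(rng):
    x = rng.normal(3, 7, 500)
    z = kin.zscore_per_recording(x)
    assert abs(np.mean(z)) < 1e-9 and abs(np.std(z) - 1) < 1e-9


def test_zscore_constant_warns():
    with pytest.warns(UserWarning, match="zero-variance"):
        z = kin.zscore_per_recording(np.full(10, 4.2))
    assert np.array_equal(z, np.zeros(10))


@settings(max_examples=25, deadline=None)
@given(
    a=st.floats(min_value=0.1, max_value=50),
    b=st.floats(min_value=-100, max_value=100),
)
def test_zscore_affine_invariance(a, b):
    x = np.sin(np.arange(200) * 0.1)
    assert np.allclose(kin.zscore_per_recording(a * x + b), kin.zscore_per_recording(x), atol=1e-9)


# --- relative geometry ------------------------------------------------------

def test_relative_geometry_hand_cases():
    male = _track({"head": (0, 1), "thorax": (0, 0)}, n=3)
    female = _track({"head": (0, 4), "thorax": (0, 3)}, n=3)
    d, body, target = kin.relative_geometry(male, female)
    assert np.allclose(d, 3.0) and np.allclose(body, 0.0) and np.allclose(target, 0.0)

    female_rev = _track({"head": (0, 2), "thorax": (0, 3)}, n=3)
    _, body, target = kin.relative_geometry(male, female_rev)
    assert np.allclose(body, 180.0) and np.allclose(target, 0.0)

    female_side = _track({"head": (3, 1), "thorax": (3, 0)}, n=3)
    _, _, target = kin.relative_geometry(male, female_side)
    assert np.allclose(target, 90.0)


# --- female-centric maps ----------------------------------------------------

def test_maps_single_hex_behind_female():
    female = _track({"head": (0, 1), "thorax": (0, 0)}, n=50)
    male = _track({"head": (0, -1), "thorax": (0, -2)}, n=50)
    maps = kin.female_centric_maps(male, female)
    assert len(maps.hex_counts) == 1
    assert sum(maps.hex_counts.values()) == 50


def test_maps_conserve_observations(small_recording):
    _, tracks, _, _ = small_recording
    male, female = tracks
    maps = kin.female_centric_maps(male, female)
    pos, _, valid = kin._to_female_frame(male, female)
    assert sum(maps.hex_counts.values()) == int(valid.sum())


def test_maps_invariant_to_rigid_motion(small_recording):
    _, tracks, _, _ = small_recording
    male, female = tracks
    theta, shift = 0.7, np.array([12.3, -4.5])
    R = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
    male2, female2 = male.copy(), female.copy()
    for t in (male2, female2):
        t.coords[:] = t.coords @ R.T + shift
    m1 = kin.female_centric_maps(male, female)
    m2 = kin.female_centric_maps(male2, female2)
    assert m1.hex_counts == m2.hex_counts
    assert np.array_equal(m1.quiver_count, m2.quiver_count)
    assert np.allclose(m1.quiver_mean_x, m2.quiver_mean_x, atol=1e-9, equal_nan=True)
    assert np.allclose(m1.quiver_mean_angle, m2.quiver_mean_angle, atol=1e-9, equal_nan=True)


# --- dominant wing ----------------------------------------------------------

def test_dominant_wing_cases(caplog):
    bout = BoutRecord("r", "waggle", 0, 100, "left", "truth")
    t = np.arange(100) / 150.0
    assert kin.dominant_wing(bout, np.full(100, 40.0), np.full(100, 10.0)) == "left"
    # equal-amplitude anti-phase sinusoids: exact tie -> left
    s = 20 + 10 * np.sin(2 * np.pi * 10 * t)
    a = 20 - 10 * np.sin(2 * np.pi * 10 * t)
    assert kin.dominant_wing(bout, s, a) == "left"
    # amplitude 25 vs 20 anti-phase: mean |sin| scales with amplitude
    big = np.abs(25 * np.sin(2 * np.pi * 10 * t))
    small = np.abs(20 * np.sin(2 * np.pi * 10 * t + np.pi))
    assert kin.dominant_wing(bout, big, small) == "left"


# --- event-triggered averaging ----------------------------------------------

def test_eta_constant_series():
    res = kin.event_triggered_average(np.full(100, 5.0), [30, 60], (0.1, 0.1), 150.0)
    assert np.allclose(res.mean, 5.0) and np.allclose(res.sem, 0.0)


def test_eta_single_event_sem_zero():
    res = kin.event_triggered_average(np.arange(100.0), [50], (0.05, 0.05), 150.0)
    assert np.allclose(res.sem, 0.0)
    assert np.all(res.n == 1)


def test_eta_two_snippets_hand_value():
    series = np.zeros(100)
    series[20], series[70] = 1.0, 3.0
    res = kin.event_triggered_average(series, [20, 70], (0.0, 0.0), 150.0)
    assert res.mean[0] == 2.0 and res.sem[0] == 1.0  # SD=sqrt(2), SEM=SD/sqrt(2)


def test_eta_nan_padding_at_edges():
    res = kin.event_triggered_average(np.arange(10.0), [1], (0.02, 0.0), 150.0)
    # lag -3 falls before frame 0
    assert np.isnan(res.snippets[0, 0])
    assert res.n[0] == 0
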