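"""Thresholds, ethogram assembly, transitions, permutation null, n-grams."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from flywaggle import ethogram as eth
from flywaggle.core import BoutRecord, Ethogram


# --- knee point -------------------------------------------------------------

def test_knee_point_hand_cdf():
    # distances |0.8 - 1/3|/sqrt(2) ~ 0.330 > |0.9 - 2/3|/sqrt(2) ~ 0.165
    assert eth.knee_point_from_cdf([0, 1, 2, 3], [0, 0.8, 0.9, 1.0]) == 1.0


def test_knee_point_straight_line_warns():
    with pytest.warns(UserWarning, match="degenerate"):
        out = eth.knee_point_from_cdf([0, 1, 2, 3], [0, 1 / 3, 2 / 3, 1.0])
    assert out == 0.0


def test_knee_point_requires_distinct_values():
    with pytest.raises(ValueError):
        eth.knee_point([1.0, 1.0, 2.0])


@settings(max_examples=20, deadline=None)
@given(scale=st.floats(min_value=0.01, max_value=100))
def test_knee_point_scale_equivariance(scale):
    rng = np.random.default_rng(42)
    values = rng.lognormal(0, 1, 200)
    assert np.isclose(eth.knee_point(values * scale), scale * eth.knee_point(values), rtol=1e-12)


def brute_force_knee(values):
    """Independent oracle: explicit point-to-chord distance, argmax."""
    x = np.unique(np.asarray(values, dtype=float))
    y = np.searchsorted(np.sort(values), x, side="right") / len(values)
    xn = (x - x[0]) / (x[-1] - x[0])
    yn = (y - y[0]) / (y[-1] - y[0])
    # chord from (0,0) to (1,1): |a*x + b*y + c| / sqrt(a^2+b^2) with a=1, b=-1, c=0
    best_i, best_d = 0, -1.0
    for i in range(len(xn)):
        d = abs(xn[i] - yn[i]) / np.sqrt(2)
        if d > best_d + 1e-15:
            best_d, best_i = d, i
    return float(x[best_i])


def test_knee_point_matches_brute_force(rng):
    for _ in range(100):
        values = rng.lognormal(rng.normal(), rng.uniform(0.3, 1.5), rng.integers(10, 200))
        assert eth.knee_point(values) == brute_force_knee(values)


# --- stillness --------------------------------------------------------------

def test_classify_stillness_cases():
    th = eth.StillnessThresholds()
    out = eth.classify_stillness([0.5, 0.5, -0.5], [0.2, 0.4, 0.2], th)
    assert out.tolist() == [True, False, True]
    with pytest.warns(UserWarning, match="NaN"):
        out = eth.classify_stillness([np.nan], [0.1], th)
    assert out.tolist() == [False]


# --- ethogram assembly ------------------------------------------------------

def test_build_ethogram_waggle_overwrites_stillness():
    still = np.zeros(300, dtype=bool)
    still[:150] = True
    waggle = [BoutRecord("r", "waggle", 100, 200, "left", "detected")]
    e = eth.build_ethogram(still, waggle, [], eth.DurationThresholds(0, 0), fps=150.0)
    assert [(b.behavior, b.start, b.end) for b in e.bouts] == [
        ("stillness", 0, 100),
        ("waggle", 100, 200),
        ("other", 200, 300),
    ]


def test_build_ethogram_short_stillness_excluded():
    still = np.zeros(600, dtype=bool)
    still[100:175] = True  # 0.5 s at 150 fps
    e = eth.build_ethogram(still, [], [], eth.DurationThresholds(0.71, 0.0), fps=150.0)
    assert "stillness" not in [b.behavior for b in e.bouts]
    assert e.n_excluded == 1
    # frames stay labelled even though the bout is excluded
    assert (e.frame_labels[100:175] == eth.STATE_INDEX["stillness"]).all()


def test_build_ethogram_empty_input_single_other_bout():
    e = eth.build_ethogram(np.zeros(300, dtype=bool), [], [], eth.DurationThresholds(0, 0), 150.0)
    assert [(b.behavior, b.start, b.end) for b in e.bouts] == [("other", 0, 300)]


def test_build_ethogram_overlap_truncates_later_bout():
    still = np.zeros(600, dtype=bool)
    waggle = [BoutRecord("r", "waggle", 100, 250, "left", "detected")]
    song = [BoutRecord("r", "song", 200, 400, "right", "detected")]
    with pytest.warns(UserWarning, match="overlap"):
        e = eth.build_ethogram(still, waggle, song, eth.DurationThresholds(0, 0), 150.0)
    kinds = [(b.behavior, b.start, b.end) for b in e.bouts]
    assert ("waggle", 100, 250) in kinds
    assert ("song", 250, 400) in kinds


# --- transitions ------------------------------------------------------------

def _seq_ethogram(labels, rec="r"):
    bouts = []
    for i, lab in enumerate(labels):
        wing = "none" if lab in ("stillness", "other") else "left"
        bouts.append(BoutRecord(rec, lab, i * 10, (i + 1) * 10, wing, "detected"))
    return Ethogram(rec, 150.0, len(labels) * 10, bouts)


def test_transition_hand_tally():
    e = _seq_ethogram(["stillness", "waggle", "song", "stillness", "waggle", "song"])
    res = eth.transition_matrix([e])
    S, W, G = (eth.STATE_INDEX[s] for s in ("stillness", "waggle", "song"))
    assert res.counts[S, W] == 2 and res.counts[W, G] == 2 and res.counts[G, S] == 1
    assert res.probs[S, W] == 1.0


def test_single_bout_recordings_give_zero_counts():
    res = eth.transition_matrix([_seq_ethogram(["waggle"]), _seq_ethogram(["song"])])
    assert res.counts.sum() == 0


def test_no_cross_recording_transitions():
    pooled = eth.transition_matrix(
        [_seq_ethogram(["stillness", "waggle"]), _seq_ethogram(["song", "stillness"])]
    )
    concat = eth.transition_matrix(
        [_seq_ethogram(["stillness", "waggle", "song", "stillness"])]
    )
    assert pooled.counts.sum() == 2
    assert concat.counts.sum() == 3


def test_probs_rows_sum_to_one(small_config):
    from flywaggle import benchmarks

    e = benchmarks._truth_ethogram(small_config, small_config.seed)
    res = eth.transition_matrix([e])
    rows = res.counts.sum(axis=1)
    sums = res.probs.sum(axis=1)
    assert np.allclose(sums[rows > 0], 1.0, atol=1e-12)
    sub = res.submatrix()
    assert (sub.sum(axis=1) <= 1.0 + 1e-12).all()


# --- permutation test -------------------------------------------------------

def exhaustive_exceedance(labels, cell):
    """Enumerate all orderings; fraction with P(cell) >= observed P(cell)."""
    def prob(seq):
        counts = np.zeros((4, 4))
        for a, b in zip(seq[:-1], seq[1:]):
            counts[a, b] += 1
        row = counts[cell[0]].sum()
        return counts[cell] / row if row else 0.0

    codes = [eth.STATE_INDEX[l] for l in labels]
    observed = prob(codes)
    perms = list(itertools.permutations(codes))
    hits = sum(prob(p) >= observed - 1e-12 for p in perms)
    return hits / len(perms)


@pytest.mark.parametrize(
    "labels", [["stillness", "waggle", "song"], ["stillness", "waggle", "song", "waggle"]]
)
def test_permutation_matches_exhaustive_enumeration(labels):
    e = _seq_ethogram(labels)
    cell = (eth.STATE_INDEX["waggle"], eth.STATE_INDEX["song"])
    n_perm = 6000
    res = eth.permutation_test([e], n_perm=n_perm, seed=1)
    expected = exhaustive_exceedance(labels, cell)
    se = np.sqrt(expected * (1 - expected) / n_perm)
    assert abs(res.pvals[cell] - expected) <= 3 * se + 2 / n_perm


def test_permutation_seed_determinism_and_order_invariance():
    e1 = _seq_ethogram(["stillness", "waggle", "song", "stillness", "other"], "a")
    e2 = _seq_ethogram(["waggle", "song", "waggle", "stillness"], "b")
    r1 = eth.permutation_test([e1, e2], n_perm=500, seed=7)
    r2 = eth.permutation_test([e1, e2], n_perm=500, seed=7)
    assert np.array_equal(r1.pvals, r2.pvals, equal_nan=True)
    # shifting a recording's frames does not change bout-order statistics
    shifted = [b.with_(start=b.start + 1000, end=b.end + 1000) for b in e2.bouts]
    e2s = Ethogram("b", 150.0, e2.n_frames + 1000, shifted)
    r3 = eth.permutation_test([e1, e2s], n_perm=500, seed=7)
    assert np.array_equal(r1.pvals, r3.pvals, equal_nan=True)


# --- BH-FDR -----------------------------------------------------------------

def test_bh_hand_case():
    q = eth.bh_fdr(np.array([0.01, 0.02, 0.03, 0.04]))
    assert np.allclose(q, 0.04)


def test_bh_edges():
    assert eth.bh_fdr(np.array([0.2])) == pytest.approx([0.2])
    assert np.allclose(eth.bh_fdr(np.ones(5)), 1.0)


def test_bh_matches_statsmodels(rng):
    from statsmodels.stats.multitest import multipletests

    p = rng.uniform(0, 1, 40)
    _, q_ref, _, _ = multipletests(p, method="fdr_bh")
    assert np.allclose(eth.bh_fdr(p), q_ref, atol=1e-12)


# --- three-grams ------------------------------------------------------------

def test_three_grams_hand_count():
    e = _seq_ethogram(["stillness", "waggle", "song", "stillness", "waggle", "song"])
    grams = eth.three_grams([e])
    top = grams[0]
    assert top[0] == ("stillness", "waggle", "song")
    assert top[1] == 2 and top[2] == 0.5


def test_three_grams_other_excluded():
    e = _seq_ethogram(["stillness", "other", "waggle"])
    assert eth.three_grams([e]) == []


def test_three_grams_too_short():
    assert eth.three_grams([_seq_ethogram(["stillness", "waggle"])]) == []
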