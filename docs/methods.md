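# Methods

## Conventions

Frame intervals are half-open, 0-based `[start, end)`; durations are
`(end − start)/fps`. Coordinates are stored in pixels on disk and converted
to millimetres exactly once, on read, via the recording's `px_per_mm`
(default 30.3). The image convention is x right, y down; all angle
operations are built from dot/cross products and are therefore independent
of that choice. Recording defaults: 150 fps video, 10 kHz audio.

## Kinematic features

The body axis is the unit vector thorax → head. Wing angles are unsigned
angles between the thorax → wing-tip vector and the *tail* direction (body
axis reversed), so 0° is a wing folded against the body and 90° full
extension. Missing wing-tip frames are filled by temporal nearest-neighbour
copy (ties go to the earlier frame); the thorax is denoised by a 3-frame
moving average followed by a Savitzky–Golay filter (window 7, order 3 —
chosen to preserve 10–12 Hz wing-relevant motion at 150 fps while removing
jitter; the moving average shrinks symmetrically at edges and the SG filter
uses mirror padding). Forward speed is the signed projection of the
per-frame thorax displacement onto the heading, times fps, median-filtered
over 5 frames; stillness classification and plots use its magnitude. The
sign is kept because it carries backward-walking information.

Inter-fly geometry uses unsigned angles in [0°, 180°]: distance between
thoraxes, angle between body axes, and the target angle between the male
body axis and the male → female vector. Female-centric maps express the
male's position and heading in the female's frame (her thorax at the
origin, heading along +y): a pointy-top hexagonal location histogram with
0.10 mm edges and a 14 × 14 orientation grid (0.86 mm bins) holding per-cell
counts, mean position, and circular-mean relative orientation. Both maps
are exactly invariant to global rigid motions because they are built from
dot products with the female's frame vectors.

## Waggle detection

Both wing-angle series are band-pass filtered 8–18 Hz (4th-order
Butterworth, forward–backward so bout boundaries are not phase-shifted) and
the Hilbert transform provides instantaneous phase and envelope per wing.
Candidate frames require (a) both envelopes above the per-recording
baseline — the envelope median — by `amp_thresh_deg` (default 5°), and
(b) the wrapped phase difference within `antiphase_tol_rad` (default π/4)
of π. Candidate runs are merged across gaps shorter than 0.1 s, and a run
is retained only if the unwrapped phase of the dominant wing spans at least
3 full cycles. The envelope threshold and the anti-phase tolerance are the
detector's two free parameters; both are exposed in `WaggleParams`. The
detector is invariant to constant offsets of either series (the band-pass
removes DC). The dominant wing of any bout is the wing with the greater
mean angle over the bout; an exact tie resolves to left and is logged.

Song detection is the conjunction of wing extension (max of the two angles
above 45°) and acoustic amplitude (per-frame RMS above 3× the recording's
median RMS) lasting at least 0.1 s, with boundaries widened to the
enclosing wing-extension run, since wing-angle threshold crossings define
the bout edges.

Per-bout spectra use a linearly detrended, Hann-windowed periodogram
zero-padded to 0.05 Hz resolution, with the peak taken inside the 8–18 Hz
band; the phase relation is the mean absolute wrapped Hilbert phase
difference of the detrended segments (π for ideal anti-phase motion).

Detector scoring uses greedy one-to-one matching by descending temporal
IoU with a 0.3 minimum — a deliberate, conventional choice for interval
detection tasks. Precision is undefined (NaN) when nothing is detected.

## Audio

Channels are baseline-subtracted (per-channel median), band-passed
50–1000 Hz (4th-order zero-phase Butterworth), and reduced per sample to
the mean of the three channels with the largest instantaneous absolute
amplitude ("instantaneous" rather than a short-window envelope; with fewer
than three channels, all are used). Per-video-frame values reduce each
frame's sample span (RMS by default); spans partition the trace.

## Ethogram and transition statistics

The knee-point rule builds the empirical CDF at the sorted unique values,
min–max normalizes both axes, and returns the x maximizing the
perpendicular distance to the (0,0)–(1,1) chord (equivalently |y − x|;
ties to the smaller x; a straight-line CDF warns and returns the smallest
value). It supplies the default stillness speed thresholds (0.67 mm/s
male, 0.30 mm/s female) and bout-duration thresholds (0.71 s stillness,
0.72 s other); both can be re-derived from data (`thresholds: auto`).

Frames are labelled hierarchically: stillness where both flies are below
threshold, overwritten by waggle and song bouts (overlaps resolved by
truncating the later-starting bout, with a warning), remainder "other".
Stillness/other runs below their duration thresholds are excluded from the
bout sequence but keep their frame labels; excluded bouts do not merge
their neighbours — the transition is counted across them, which can in
principle leave equal labels adjacent (rare at the defaults, < 1% of
bouts). Waggle/song bouts keep their detection-based durations.

Transition counts pool ordered pairs of consecutive retained bouts across
recordings (never across recording boundaries); probabilities are
row-normalized over all four states, so the reported 3 × 3
stillness/waggle/song submatrix rows sum to ≤ 1. The permutation null
shuffles each recording's bout order uniformly (each bout keeps its label
and duration — with transitions depending only on label order, this is
identical to reassigning labels to fixed slots), recomputes pooled
probabilities, and estimates one-tailed enrichment p-values with the
add-one rule (1 + #{perm ≥ obs})/(1 + n_perm), avoiding p = 0; default
10,000 permutations, seeded. BH-FDR is applied over the 12 off-diagonal
cells (configurable to the 9 of the 3 × 3). The first/last bout identity
is not constrained during shuffling. Three-grams slide a window of three
consecutive retained bouts, dropping windows containing "other" or a
self-transition; probabilities are counts over retained windows.

Waggle→song linkage pairs each waggle with the earliest song starting at
or after its offset (waggles with no later song are excluded). The
linked/unlinked split is the globally optimal two-cluster 1-D k-means on
natural-log gaps, found exactly by scanning contiguous splits of the
sorted values (deterministic; identical optimum to converged Lloyd's),
with the threshold at the log-space centroid midpoint. Zero-frame gaps
are floored at half a frame (≈3.3 ms) before the log. The split is
scale-equivariant. The log base is immaterial to the clustering.

## Synthetic recording generator

The generator is a semi-Markov chain over the four states with explicit
log-normal duration distributions — the bout, not the frame, is the unit
of analysis. Defaults reproduce the study conditions where stated (150 fps,
30.3 px/mm, 10 kHz audio, 10.6 Hz mean waggle frequency, 0.15 s linked-gap
bound) and otherwise use realistic values chosen once:

- transition matrix biased toward the stereotyped
  stillness → waggle → song cycle, zero diagonal;
  `linked_fraction` (0.6) sets the waggle-row song entry, with the rest of
  the row rescaled, so every direct waggle → song transition is a "linked"
  pair whose gap is drawn uniformly over 0–0.15 s and realized as
  sub-threshold "other" frames (unlinked pairs arise via intervening bouts);
- durations: log-normal medians 2.5 s (stillness), 0.8 s (waggle), 1.2 s
  (song), 2.5 s (other), log-SDs 0.4–0.5 — second-scale courtship bouts
  that also keep sub-threshold exclusions rare, so transition-matrix
  recovery from the bout sequence targets the configured matrix;
- waggle rendering: per-bout frequency ~ N(10.6, 1.0) Hz, dominant-wing
  amplitude ~ U(20°, 40°) sweeping 0–A as (A/2)(1 − cos 2πft), the
  non-dominant wing in exact anti-phase at 0.8× amplitude, half-cosine
  0.05 s edge ramps; bouts shorter than 3.5 cycles at their drawn
  frequency are extended to that floor (nibbling frames from successors;
  logged, and the adjusted truth is returned);
- song: one wing held at U(60°, 90°), audio gains a 220 Hz carrier
  (inside the 50–1000 Hz analysis band) with 4 Hz amplitude modulation at
  0.4 peak amplitude over N(0, 0.005) channel noise — an amplitude
  signature, not a biophysical pulse-song model, because the detector only
  requires elevated RMS. Waggling emits no audio;
- locomotion: per-state mean forward speeds (male/female) of 0.08/0.05
  (stillness and waggle), 6/1.5 (song), 4/3 (other) mm/s, integrated along
  a smooth heading random walk with wall-avoiding steering in a 30 mm
  arena; the male ramps down over 1 s before each waggle onset, emulating
  the characteristic pre-waggle deceleration, and both flies share
  stillness states (the stillness definition requires both below
  threshold);
- tracker imperfections applied last, never altering the ground truth:
  positional jitter with 0.066 mm SD and a 20-frame (0.13 s) correlation
  length, white 2° wing-angle noise, and 2% per-frame wing-tip dropout.
  The correlation length matters: white per-frame jitter of this amplitude
  at 150 fps would give a still fly an apparent speed of ~1 mm/s,
  contradicting the sub-0.67/0.30 mm/s speeds that proofread tracking
  yields for stationary flies; correlated jitter keeps the measured
  stillness floor at ~0.25 mm/s while leaving the 8–18 Hz waggle band
  untouched (the jitter spectrum lies below ~1.2 Hz).

Identical (config, seed) yields bit-identical output; all draws come from
one seeded generator.

What the generator does *not* emulate: pose-estimation failure modes other
than Gaussian jitter and dropout (identity swaps, limb confusions),
pulse/sine song microstructure, interaction-driven locomotion (chasing,
circling), chamber acoustics, or gradual within-bout frequency drift.
Passing tests therefore demonstrate the correctness and calibration of the
analysis machinery under the declared generative assumptions, not detector
performance on real video, which must be validated against manual
annotation as in any tracking study.

## Validation experiments

`scripts/acceptance.py` and `tests/test_acceptance.py` regenerate all
inputs from scratch:

- detector performance: 30 five-minute recordings at default noise and
  dropout (seeds derived from the run seed), pooled greedy IoU ≥ 0.3
  matching;
- frequency recovery: 200 one-second bouts at fixed 10.6 Hz with 2° angle
  noise, median periodogram peak of the dominant wing;
- oracle equivalence: the knee point against an explicit
  point-to-chord-distance search, permutation p-values against exhaustive
  enumeration on 3–4-bout toy recordings, transition tallies against hand
  counts, BH-FDR against statsmodels, the 1-D k-means split against
  multi-start Lloyd's;
- calibration: under a label-exchangeable null (iid bout labels), the
  p-value of a designated transition cell is tested for uniformity as the
  fraction below 0.05 across 200 independent replicates (999 permutations
  each) against the binomial 95% interval — one cell per replicate so the
  binomial reference is exact;
- parameter recovery: transition probabilities from 100 one-minute
  sampled bout sequences within 3 binomial SEs of the configured matrix;
  the linked-stratum wing-match fraction within 3 SEs of the configured
  0.9;
- geometry: all angle operations against a brute-force atan2 oracle on
  1,000 random configurations at 1e-9° tolerance, and rigid-motion
  invariance of the female-centric maps.

Problem sizes (30 × 5 min for detection, 100 × 1 min for recovery, 200
replicates for calibration) were chosen to give the binomial checks
adequate power while keeping a full validation run in the minutes range
on a single core.

## Known limitations

- The stillness classifier at the fixed default thresholds is
  conservative on noisy synthetic data (the female threshold of 0.30 mm/s
  sits close to the measured jitter floor), fragmenting stillness runs;
  `thresholds: auto` re-derives thresholds from the data at hand.
- Precision/recall figures on synthetic data reflect the generator's
  assumptions and should be read as validation of the machinery, not as
  expected field performance.
- The permutation test conditions on bout composition per recording;
  recordings contribute jointly to the pooled statistic, so per-recording
  heterogeneity is not modelled.
- Unsigned target/body angles discard left/right asymmetry by design.
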