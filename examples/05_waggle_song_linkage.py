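"""Quantify waggle -> song coupling and dominant-wing persistence.

Each waggle is paired with the next song; exact 1-D k-means on log gap
durations splits pairs into "linked" (short-gap) and "unlinked". In the
generator — as in real courtship — the song's dominant wing matches the
preceding waggle's far more often for linked transitions, decaying
toward chance as the gap grows.
"""

import numpy as np

from flywaggle import SynthConfig, classify_linked, sample_ethogram, waggle_song_gaps
from flywaggle.linkage import binned_match, wing_match_fraction

base = SynthConfig(duration_s=60.0)
waggles, songs = [], []
for seed in range(60):
    bouts = sample_ethogram(SynthConfig.from_dict({**base.to_dict(), "seed": seed}), seed)
    waggles += [b for b in bouts if b.behavior == "waggle"]
    songs += [b for b in bouts if b.behavior == "song"]

pairs = waggle_song_gaps(waggles, songs, base.fps)
gaps = np.array([p.gap_s for p in pairs])
threshold, linked = classify_linked(gaps)
summary = wing_match_fraction(pairs, linked)

print(f"{len(pairs)} waggle->song pairs; k-means gap threshold = {threshold:.3f} s")
print(f"wing match: linked {summary.linked:.3f} (n={summary.n_linked}), "
      f"unlinked {summary.unlinked:.3f} (n={summary.n_unlinked})")
print("match fraction by gap bin (log-scale edges):")
for row in binned_match(pairs):
    frac = "  --" if row["n"] == 0 else f"{row['fraction']:.3f}"
    print(f"  {row['lo_s']:8.3f}-{row['hi_s']:8.3f} s  n={row['n']:4d}  match={frac}")
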