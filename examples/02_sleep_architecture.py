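"""Microarousals, NREM episodes and bout statistics from a hypnogram.

A microarousal (MA) is a wake intrusion of at most 20 s flanked by NREM;
its rate indexes sleep fragmentation. NREM episodes are MA-bridged spans.
"""

import numpy as np

from murisleep import (
    SimConfig,
    bout_duration_distribution,
    consolidate_nrem,
    detect_bouts,
    detect_microarousals,
    microarousal_rate_per_h,
    simulate_hypnogram,
    state_percentages,
)

cfg = SimConfig(duration_s=4 * 3600.0, seed=3)
hyp, _ = simulate_hypnogram(cfg, 3)

pct = state_percentages(hyp)
mas = detect_microarousals(hyp)
episodes = consolidate_nrem(hyp, min_span_s=0.0)
consolidated = consolidate_nrem(hyp)  # >= 120 s, used for infraslow analysis
bouts = detect_bouts(hyp)
dist = bout_duration_distribution(bouts, "N", [0, 32, 64, 128, 256, np.inf])

print(f"state occupancy: W {pct['W']:.1f} %  N {pct['N']:.1f} %  R {pct['R']:.1f} %")
print(f"microarousals: {len(mas)} ({microarousal_rate_per_h(hyp, mas):.1f} per h of NREM)")
print(f"NREM episodes (MA-bridged): {len(episodes)}, "
      f"mean span {np.mean([e.span_s for e in episodes]):.0f} s")
print(f"consolidated NREM bouts (>= 120 s): {len(consolidated)}")
print("NREM bout-duration distribution (fractions per bin):", np.round(dist, 2))
# A fragmented sleeper shifts this distribution toward the short bins.
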