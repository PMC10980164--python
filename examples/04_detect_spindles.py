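"""Detect sleep spindles with the bin-wise two-criterion detector.

Spindles are 10-16.7 Hz bursts during NREM. The detector scans 600 ms
windows every 100 ms, flags bins whose σ-band spectral peak exceeds the
96th percentile and half the 0-10 Hz peak, then merges/fuses bins into
events. Here it runs on the pink-noise benchmark with known burst times.
"""

import numpy as np

from murisleep import detect_spindles, match_events
from murisleep.simulate import synthesize_spindle_benchmark

eeg, truth = synthesize_spindle_benchmark(duration_s=600.0, rng=0)
events = detect_spindles(eeg, fs=1000.0)
_, precision, recall = match_events(events, list(zip(truth.time_s, truth.duration_s)),
                                    tol_s=0.3)

durations = [e.duration_ms for e in events]
print(f"injected bursts: {len(truth)}, detected spindles: {len(events)}")
print(f"precision {precision:.2f}, recall {recall:.2f} (matching tolerance 300 ms)")
print(f"spindle durations: {np.mean(durations):.0f} ms mean "
      f"({np.min(durations):.0f}-{np.max(durations):.0f} ms)")
print(f"density: {len(events) / 10.0:.1f} per min")
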