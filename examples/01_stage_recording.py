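"""Score a synthetic EEG/EMG recording into Wake/NREM/REM epochs.

Generates one hour of simulated mouse polysomnography with known
ground-truth states, stages it with the threshold classifier, and
reports the epoch-wise agreement.
"""

import numpy as np

from murisleep import SimConfig, simulate_hypnogram, stage_recording, synthesize_signals

cfg = SimConfig(duration_s=3600.0, seed=1)
truth, _ = simulate_hypnogram(cfg, 1)
recording, _ = synthesize_signals(truth, cfg, 2)

staged = stage_recording(recording)
n = len(staged)
accuracy = np.mean(staged.states == truth.states[:n])

print(f"epochs scored: {n} (2.5 s each)")
for s, name in [("W", "wake"), ("N", "NREM"), ("R", "REM")]:
    print(f"  {name:5s}: {np.mean(staged.states == s) * 100:5.1f} % of epochs")
print(f"agreement with ground truth: {accuracy * 100:.1f} %")
# ~97 %: misclassifications cluster at state transitions, where the 5 s
# analysis window mixes two states.
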