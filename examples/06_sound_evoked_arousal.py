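"""Sound-evoked arousal trials and the pre-tone σ-power signature.

Tones (20 s) presented during eligible NREM (> 120 s preceding, MAs
bridged) either wake the animal or not. When awakenings couple to the
descending phase of the infraslow σ rhythm, the mean σ power falls
before arousal tones and rises before sleep-through tones.
"""

from murisleep import (
    SimConfig,
    apply_sound_evoked_arousals,
    arousal_percentage,
    classify_tone_trials,
    compute_spectrogram,
    normalize_spectrogram,
    peri_tone_sigma,
    schedule_tones,
    sigma_timecourse,
    simulate_hypnogram,
    synthesize_signals,
)
from murisleep.arousal import pre_tone_slope

cfg = SimConfig(duration_s=6 * 3600.0, seed=5, ma_rate_per_min_nrem=0.0,
                spindle_rate_per_min=1.0,
                dwell_mean_s={"W": 120.0, "N": 900.0, "R": 60.0})
hyp0, _ = simulate_hypnogram(cfg, 5)
tones = schedule_tones(cfg.duration_s, min_gap_s=120.0, max_gap_s=360.0, rng=6)
hyp, _ = apply_sound_evoked_arousals(hyp0, tones, cfg, rng=7,
                                     p_descending=1.0, p_ascending=0.0)
rec, _ = synthesize_signals(hyp, cfg, 8)

tc = sigma_timecourse(normalize_spectrogram(compute_spectrogram(rec.eeg, rec.fs)))
trials = classify_tone_trials(hyp, tones)
avgs = peri_tone_sigma(tc, trials)

print(f"tones: {len(tones)}, eligible trials: {sum(t.eligible for t in trials)}")
print(f"arousal percentage: {arousal_percentage(trials):.0f} %")
for klass, avg in avgs.items():
    print(f"  {klass:13s}: n={avg.n_trials:3d}  "
          f"pre-tone σ slope {pre_tone_slope(avg):+.4f} per s")
# Negative slope before arousals, positive before sleep-throughs: the
# phase-tuning signature of the infraslow rhythm.
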