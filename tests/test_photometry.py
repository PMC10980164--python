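"""ΔF/F correction, calcium-transient detection and state-resolved activity."""

import math

import numpy as np
import pytest

from murisleep import (
    Hypnogram,
    PhotometryTrace,
    SimConfig,
    compute_dff,
    detect_transients,
    simulate_hypnogram,
    state_activity,
    synthesize_photometry,
    transient_event_overlap,
)
from murisleep.architecture import MAEvent


def smooth_positive(n, fs, rng, base=5.0):
    """Slowly varying strictly positive signal (survives the 2 Hz filter)."""
    t = np.arange(n) / fs
    return base + 0.5 * np.sin(2 * np.pi * 0.05 * t) + 0.1 * np.sin(2 * np.pi * 0.11 * t + 1.0)


class TestComputeDff:
    def test_exact_affine_relation_gives_zero(self, rng):
        fs = 100.0
        s405 = smooth_positive(int(60 * fs), fs, rng)
        trace = PhotometryTrace(sig465=2.0 * s405 + 1.0, sig405=s405, fs=fs)
        out = compute_dff(trace)
        np.testing.assert_allclose(out.dff, 0.0, atol=1e-9)

    def test_fractional_deviation_recovered(self, rng):
        # deviation must be brief relative to the recording or the global
        # affine fit partially absorbs it
        fs = 100.0
        n = int(600 * fs)
        s405 = smooth_positive(n, fs, rng)
        s465 = 2.0 * s405.copy()
        s465[30000:31000] *= 1.1  # +10% on [300, 310) s
        out = compute_dff(PhotometryTrace(sig465=s465, sig405=s405, fs=fs))
        assert np.median(out.dff[30300:30700]) == pytest.approx(0.1, abs=0.01)
        assert np.median(np.abs(out.dff[:20000])) < 0.005

    def test_shared_bleach_removed_transients_survive(self):
        cfg = SimConfig(duration_s=900.0, seed=3, photo_noise=0.0, motion_amp=0.0,
                        p_transient_given_ma=1.0)
        hyp, mas = simulate_hypnogram(cfg, 3)
        trace, truth = synthesize_photometry(hyp, mas, cfg, 4)
        out = compute_dff(trace)
        # bleaching is a 900/7200 exp decay; after correction the ΔF/F at
        # recording start and end (same state) must agree
        n_idx = np.repeat(hyp.states == "N", int(2.5 * out.fs))[: out.dff.size]
        first, last = np.flatnonzero(n_idx)[:2000], np.flatnonzero(n_idx)[-2000:]
        assert abs(out.dff[first].mean() - out.dff[last].mean()) < 0.05
        # transients survive: ΔF/F near a true peak well above NREM baseline
        if len(truth):
            k = int(truth.time_s.iloc[0] * out.fs)
            assert out.dff[k] > np.median(out.dff[n_idx]) + 0.05

    def test_constant_reference_rejected(self):
        with pytest.raises(ValueError, match="405"):
            compute_dff(PhotometryTrace(sig465=np.ones(2000) + np.arange(2000) * 1e-4,
                                        sig405=np.ones(2000), fs=100.0))

    def test_nonpositive_fit_rejected(self, rng):
        fs = 100.0
        s405 = smooth_positive(int(30 * fs), fs, rng)
        trace = PhotometryTrace(sig465=-2.0 * s405, sig405=s405, fs=fs)
        with pytest.raises(ValueError, match="positive"):
            compute_dff(trace)


def bump_signal(fs=20.0, dur=300.0, center=150.0, width=8.0, height=0.5):
    t = np.arange(int(dur * fs)) / fs
    return height * np.exp(-0.5 * ((t - center) / width) ** 2), fs


class TestDetectTransients:
    def test_flat_signal_no_transients(self):
        assert detect_transients(np.zeros(10_000), 20.0) == []

    def test_single_bump_detected_at_peak(self):
        x, fs = bump_signal()
        events = detect_transients(x, fs)
        assert len(events) == 1
        assert events[0].time_s == pytest.approx(150.0, abs=1.0)

    def test_affine_invariance(self, rng):
        fs = 20.0
        x = np.cumsum(rng.standard_normal(int(600 * fs))) / 50.0
        t1 = [e.time_s for e in detect_transients(x, fs)]
        t2 = [e.time_s for e in detect_transients(3.7 * x - 0.2, fs)]
        assert t1 == t2


class TestStateActivity:
    def test_two_level_signal_z_scores(self):
        hyp = Hypnogram(states=np.array(["W"] * 4 + ["N"] * 4))
        fs = 20.0
        dff = np.repeat([1.0, -1.0], int(4 * 2.5 * fs))
        act = state_activity(dff, fs, hyp)
        # two equal halves at ±1: z-scores are exactly ±1
        assert act["W"] == pytest.approx(1.0)
        assert act["N"] == pytest.approx(-1.0)
        assert math.isnan(act["R"])

    def test_constant_signal_gives_zero(self):
        hyp = Hypnogram(states=np.array(["W", "N"]))
        act = state_activity(np.ones(100), 20.0, hyp)
        assert act["W"] == 0.0 and act["N"] == 0.0


class TestTransientOverlap:
    def test_interval_membership(self):
        from murisleep.photometry import TransientEvent

        transients = [TransientEvent(10.0, 1.0), TransientEvent(100.0, 1.0)]
        mas = [MAEvent(start_s=95.0, duration_s=10.0)]
        res = transient_event_overlap(transients, mas, window_s=0.0)
        assert res.proportion == pytest.approx(0.5)
        assert res.n_coincident == 1

    def test_no_mas_gives_zero(self):
        from murisleep.photometry import TransientEvent

        res = transient_event_overlap([TransientEvent(5.0, 1.0)], [], window_s=10.0)
        assert res.proportion == 0.0

    def test_matches_brute_force(self, rng):
        from murisleep.photometry import TransientEvent

        for _ in range(50):
            tr = [TransientEvent(float(t), 1.0) for t in np.sort(rng.uniform(0, 1000, 15))]
            mas = [MAEvent(float(s), float(d))
                   for s, d in zip(np.sort(rng.uniform(0, 1000, 8)), rng.uniform(2.5, 20, 8))]
            w = float(rng.uniform(0, 20))
            res = transient_event_overlap(tr, mas, window_s=w)
            expected = sum(
                any(m.start_s - w <= e.time_s <= m.start_s + m.duration_s + w for m in mas)
                for e in tr
            )
            assert res.n_coincident == expected


class TestRecoveryLight:
    def test_injected_counts_recovered(self):
        """Light version of the 20-seed recovery: 5 seeds, pooled +-15 %."""
        tot_det = tot_true = 0
        for seed in range(5):
            cfg = SimConfig(duration_s=1200.0, seed=seed)
            hyp, mas = simulate_hypnogram(cfg, seed)
            trace, truth = synthesize_photometry(hyp, mas, cfg, seed + 50)
            out = compute_dff(trace)
            det = detect_transients(out.dff, out.fs, hypnogram=hyp)
            tot_det += len(det)
            tot_true += len(truth)
        assert tot_true > 0
        assert 0.85 <= tot_det / tot_true <= 1.15
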