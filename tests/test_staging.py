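"""Feature extraction, thresholding and the rule-based sleep classifier."""

import numpy as np
import pytest

from murisleep import (
    FeatureSeries,
    Spectrogram,
    ThresholdSet,
    classify_epochs,
    compute_thresholds,
    extract_features,
)


def spectrogram_with_density(density_fn, n_times=4, fmax=150.0, df=0.5):
    freqs = np.arange(0, fmax + df / 2, df)
    power = np.tile([density_fn(f) for f in freqs], (n_times, 1)).astype(float)
    return Spectrogram(times=2.5 * np.arange(n_times), freqs=freqs, power=power)


def features(delta=0.0, theta=0.0, sigma=0.0, gamma=0.0, emg=0.0, n=1):
    return FeatureSeries(
        delta=[delta] * n, theta=[theta] * n, sigma=[sigma] * n,
        gamma=[gamma] * n, emg_power=[emg] * n,
    )


UNIT_THRESHOLDS = ThresholdSet(
    delta=1.0, theta=1.0, sigma=1.0, gamma=1.0, emg_power=1.0, theta_delta_ratio=1.0
)


class TestExtractFeatures:
    def test_delta_only_power_gives_zero_theta_and_ratio(self):
        eeg = spectrogram_with_density(lambda f: 1.0 if 0.5 <= f <= 4 else 0.0)
        emg = spectrogram_with_density(lambda f: 0.0, fmax=500.0)
        fs = extract_features(eeg, emg)
        assert np.all(fs.theta == 0)
        assert np.all(fs.theta_delta_ratio == 0)
        assert np.all(fs.delta > 0)

    def test_equal_band_powers_give_ratio_one(self):
        # δ spans 8 bins on the 0.5 Hz grid, θ spans 15: equalize the powers
        def density(f):
            if 0.5 <= f <= 4:
                return 15.0
            if 5 <= f <= 12:
                return 8.0
            return 0.0

        eeg = spectrogram_with_density(density)
        emg = spectrogram_with_density(lambda f: 0.0, fmax=500.0)
        fs = extract_features(eeg, emg)
        np.testing.assert_allclose(fs.theta_delta_ratio, 1.0)

    def test_mismatched_time_bins_rejected(self):
        eeg = spectrogram_with_density(lambda f: 1.0, n_times=4)
        emg = spectrogram_with_density(lambda f: 1.0, n_times=5, fmax=500.0)
        with pytest.raises(ValueError, match="time bins"):
            extract_features(eeg, emg)


class TestComputeThresholds:
    def test_mean_rule(self):
        fs = FeatureSeries(delta=[1, 2, 3], theta=[1, 2, 3], sigma=[1, 2, 3],
                           gamma=[1, 2, 3], emg_power=[1, 2, 3])
        with pytest.warns(UserWarning, match="theta_delta_ratio"):  # ratio is constant here
            thr = compute_thresholds(fs)
        assert thr.delta == pytest.approx(2.0)

    def test_mean_plus_population_sd_rule(self):
        # emg [0,0,0,4]: mean 1, population SD sqrt(3) -> threshold 2.732...
        fs = FeatureSeries(delta=[1, 2, 3, 4], theta=[1, 2, 3, 4], sigma=[1, 2, 3, 4],
                           gamma=[1, 2, 3, 4], emg_power=[0, 0, 0, 4])
        with pytest.warns(UserWarning, match="theta_delta_ratio"):  # ratio is constant here
            thr = compute_thresholds(fs)
        assert thr.emg_power == pytest.approx(1.0 + np.sqrt(3.0))
        assert np.count_nonzero(fs.emg_power > thr.emg_power) == 1

    def test_single_epoch_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            compute_thresholds(features(n=1))

    def test_constant_feature_warns(self):
        fs = FeatureSeries(delta=[2, 2], theta=[1, 3], sigma=[1, 3],
                           gamma=[1, 3], emg_power=[1, 3])
        with pytest.warns(UserWarning, match="constant"):
            compute_thresholds(fs)


class TestClassifyEpochs:
    @pytest.mark.parametrize(
        "kw, expected",
        [
            # δ high, θ/δ low, EMG low -> NREM
            (dict(delta=2.0, theta=0.5, emg=0.5), "N"),
            # θ/δ high, EMG low, δ low -> REM
            (dict(delta=0.5, theta=1.0, emg=0.5), "R"),
            # δ low, EMG low, σ high -> NREM (σ variant)
            (dict(delta=0.5, theta=0.1, sigma=2.0, emg=0.5), "N"),
            # δ low, EMG high -> Wake
            (dict(delta=0.5, theta=0.1, emg=2.0), "W"),
            # γ high alone -> Wake
            (dict(delta=0.5, theta=0.1, gamma=2.0, emg=0.5), "W"),
            # γ high but REM rule also satisfied -> REM takes precedence
            (dict(delta=0.5, theta=1.0, gamma=2.0, emg=0.5), "R"),
        ],
    )
    def test_rules(self, kw, expected):
        hyp = classify_epochs(features(**kw), UNIT_THRESHOLDS)
        assert hyp.states[0] == expected

    def test_undefined_carries_previous_state(self):
        fs = FeatureSeries(
            delta=[2.0, 0.5], theta=[0.5, 0.5], sigma=[0.5, 0.5],
            gamma=[0.5, 0.5], emg_power=[0.5, 0.5],
        )  # epoch 2: everything low, no rule fires
        hyp = classify_epochs(fs, UNIT_THRESHOLDS)
        assert list(hyp.states) == ["N", "N"]

    def test_leading_undefined_becomes_wake(self):
        hyp = classify_epochs(features(delta=0.5, theta=0.1, emg=0.5), UNIT_THRESHOLDS)
        assert hyp.states[0] == "W"

    def test_ties_are_low(self):
        # every feature exactly at threshold: nothing is "high" -> undefined -> W
        hyp = classify_epochs(features(delta=1, theta=1, sigma=1, gamma=1, emg=1),
                              UNIT_THRESHOLDS)
        assert hyp.states[0] == "W"


def brute_force_classifier(fs: FeatureSeries, thr: ThresholdSet):
    """Independent per-epoch rule evaluator (plain conditionals + carry)."""
    out = []
    prev = "W"
    for i in range(len(fs)):
        d = fs.delta[i] > thr.delta
        s = fs.sigma[i] > thr.sigma
        g = fs.gamma[i] > thr.gamma
        e = fs.emg_power[i] > thr.emg_power
        r = fs.theta_delta_ratio[i] > thr.theta_delta_ratio
        if r and not e and not d:
            state = "R"
        elif d and not r and not e:
            state = "N"
        elif not e and not d and s:
            state = "N"
        elif not d and e:
            state = "W"
        elif g:
            state = "W"
        else:
            state = prev
        out.append(state)
        prev = state
    return out


class TestClassifierProperties:
    def test_matches_brute_force_on_random_features(self, rng):
        n = 2000
        fs = FeatureSeries(
            delta=rng.uniform(0, 2, n), theta=rng.uniform(0, 2, n),
            sigma=rng.uniform(0, 2, n), gamma=rng.uniform(0, 2, n),
            emg_power=rng.uniform(0, 2, n),
        )
        thr = compute_thresholds(fs)
        hyp = classify_epochs(fs, thr)
        assert list(hyp.states) == brute_force_classifier(fs, thr)

    def test_output_length_and_no_undefined(self, rng):
        n = 500
        fs = FeatureSeries(
            delta=rng.uniform(0, 2, n), theta=rng.uniform(0, 2, n),
            sigma=rng.uniform(0, 2, n), gamma=rng.uniform(0, 2, n),
            emg_power=rng.uniform(0, 2, n),
        )
        hyp = classify_epochs(fs, compute_thresholds(fs))
        assert len(hyp) == n
        assert "U" not in hyp.states
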