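"""Threshold-based Wake/NREM/REM staging on 2.5 s epochs.

Each epoch is described by EEG band powers (δ 0.5–4, θ 5–12, σ 12–20,
γ 100–150 Hz), the θ/δ ratio and EMG power (50–500 Hz). Every feature is
split into a "low" and "high" part at its temporal mean — except EMG
power and θ/δ, which use mean + 1 SD. The rules, applied in precedence
order:

1. REM:  θ/δ high, EMG low, δ low;
2. NREM: δ high, θ/δ low, EMG low;
3. NREM (σ variant): EMG low, δ low, σ high;
4. Wake: δ low, EMG high;
5. Wake: γ high (unless already REM by rule 1);
6. otherwise undefined; undefined epochs inherit the previous resolved
   state (leading undefined epochs become Wake).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .core import EPOCH_S, Hypnogram
from .spectral import BandScheme, Spectrogram, band_power


@dataclass
class FeatureSeries:
    """Per-epoch staging features (µV²; ratio dimensionless)."""

    delta: np.ndarray
    theta: np.ndarray
    sigma: np.ndarray
    gamma: np.ndarray
    emg_power: np.ndarray
    theta_delta_ratio: np.ndarray = None
    epoch_s: float = EPOCH_S

    def __post_init__(self) -> None:
        arrays = [self.delta, self.theta, self.sigma, self.gamma, self.emg_power]
        arrays = [np.asarray(a, dtype=float) for a in arrays]
        self.delta, self.theta, self.sigma, self.gamma, self.emg_power = arrays
        n = self.delta.size
        if any(a.size != n for a in arrays):
            raise ValueError("all feature series must have equal length")
        if any(np.any(a < 0) for a in arrays):
            raise ValueError("band powers must be non-negative")
        if self.theta_delta_ratio is None:
            # zero-δ epochs get ratio 0 so they can never score as "high θ/δ"
            with np.errstate(divide="ignore", invalid="ignore"):
                ratio = np.where(self.delta > 0, self.theta / self.delta, 0.0)
            self.theta_delta_ratio = ratio
        else:
            self.theta_delta_ratio = np.asarray(self.theta_delta_ratio, dtype=float)
            if self.theta_delta_ratio.size != n:
                raise ValueError("theta_delta_ratio length mismatch")

    def __len__(self) -> int:
        return int(self.delta.size)


#: Threshold rule per feature: the temporal mean, or mean plus one SD.
THRESHOLD_RULES = {
    "delta": "mean",
    "theta": "mean",
    "sigma": "mean",
    "gamma": "mean",
    "emg_power": "mean_plus_sd",
    "theta_delta_ratio": "mean_plus_sd",
}


@dataclass(frozen=True)
class ThresholdSet:
    """One scalar threshold per staging feature ("high" = strictly above)."""

    delta: float
    theta: float
    sigma: float
    gamma: float
    emg_power: float
    theta_delta_ratio: float


def extract_features(
    eeg_spectrogram: Spectrogram,
    emg_spectrogram: Spectrogram,
    bands: BandScheme | None = None,
) -> FeatureSeries:
    """Band powers + θ/δ ratio + EMG power from matched spectrograms."""
    bands = bands or BandScheme()
    if eeg_spectrogram.times.size != emg_spectrogram.times.size or not np.allclose(
        eeg_spectrogram.times, emg_spectrogram.times
    ):
        raise ValueError("EEG and EMG spectrograms must share time bins")
    return FeatureSeries(
        delta=band_power(eeg_spectrogram, bands.delta),
        theta=band_power(eeg_spectrogram, bands.theta),
        sigma=band_power(eeg_spectrogram, bands.sigma_stage),
        gamma=band_power(eeg_spectrogram, bands.gamma),
        emg_power=band_power(emg_spectrogram, bands.emg),
    )


def compute_thresholds(features: FeatureSeries) -> ThresholdSet:
    """Per-feature thresholds: temporal mean, or mean + 1 population SD.

    The SD is the population (divide-by-n) standard deviation of the
    observed series — the threshold describes this recording, not an
    estimate of a parent distribution.
    """
    if len(features) < 2:
        raise ValueError("need at least 2 epochs to compute thresholds")
    values = {}
    for name, rule in THRESHOLD_RULES.items():
        series = getattr(features, name)
        thr = float(series.mean())
        if rule == "mean_plus_sd":
            thr += float(series.std())  # ddof=0
        if np.ptp(series) == 0:
            warnings.warn(
                f"feature {name!r} is constant; nothing exceeds its threshold "
                "under the strict 'high' rule",
                stacklevel=2,
            )
        values[name] = thr
    return ThresholdSet(**values)


def classify_epochs(features: FeatureSeries, thresholds: ThresholdSet) -> Hypnogram:
    """Apply the staging rules per epoch; deterministic.

    "High" means strictly greater than the threshold, ties are "low".
    Rules fire in precedence order REM → NREM → NREM(σ) → Wake(EMG) →
    Wake(γ); epochs no rule covers carry the previous resolved state
    forward (leading undefined → Wake).
    """
    d_hi = features.delta > thresholds.delta
    s_hi = features.sigma > thresholds.sigma
    g_hi = features.gamma > thresholds.gamma
    e_hi = features.emg_power > thresholds.emg_power
    r_hi = features.theta_delta_ratio > thresholds.theta_delta_ratio

    states = np.select(
        [
            r_hi & ~e_hi & ~d_hi,          # REM
            d_hi & ~r_hi & ~e_hi,          # NREM
            ~e_hi & ~d_hi & s_hi,          # NREM, σ variant
            ~d_hi & e_hi,                  # Wake by EMG
            g_hi,                          # Wake by γ (REM took precedence)
        ],
        ["R", "N", "N", "W", "W"],
        default="U",
    )
    resolved = states.copy()
    prev = "W"  # leading undefined epochs default to Wake
    for i, s in enumerate(resolved):
        if s == "U":
            resolved[i] = prev
        else:
            prev = resolved[i]
    return Hypnogram(states=resolved)


def stage_recording(recording, bands: BandScheme | None = None) -> Hypnogram:
    """Convenience: spectrograms → features → thresholds → hypnogram."""
    from .spectral import compute_spectrogram

    eeg_spec = compute_spectrogram(recording.eeg, recording.fs)
    emg_spec = compute_spectrogram(recording.emg, recording.fs)
    features = extract_features(eeg_spec, emg_spec, bands)
    return classify_epochs(features, compute_thresholds(features))
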