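"""Epoch-resolution spectrograms and band powers.

The scoring spectrogram follows the sliding-window Welch scheme used for
rodent polysomnography: one power spectral density per half-overlapping
5 s window (2.5 s step, matching the scoring epoch), where each window's
PSD is Welch's average of Hanning-tapered, half-overlapping 2 s
periodograms (0.5 Hz frequency resolution). Powers are densities in
µV²/Hz; band powers integrate the density over a closed frequency
interval.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .core import EPOCH_S


@dataclass
class Spectrogram:
    """Time-frequency power density.

    ``times`` mark window starts (step = one scoring epoch for the staging
    spectrogram); ``power`` has shape (n_times, n_freqs) in µV²/Hz (or
    dimensionless after :func:`normalize_spectrogram`).
    """

    times: np.ndarray
    freqs: np.ndarray
    power: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.power = np.asarray(self.power, dtype=float)
        if self.power.shape != (self.times.size, self.freqs.size):
            raise ValueError(
                f"power shape {self.power.shape} does not match "
                f"(n_times={self.times.size}, n_freqs={self.freqs.size})"
            )
        if np.any(self.power < 0):
            raise ValueError("spectrogram power must be non-negative")
        if self.times.size > 1 and np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.freqs.size > 1 and np.any(np.diff(self.freqs) <= 0):
            raise ValueError("freqs must be strictly increasing")

    @property
    def df(self) -> float:
        """Frequency bin width (uniform grid)."""
        return float(self.freqs[1] - self.freqs[0]) if self.freqs.size > 1 else 1.0


@dataclass(frozen=True)
class BandScheme:
    """Frequency bands (Hz) used across the pipeline.

    ``sigma_stage`` feeds the staging classifier, ``sigma_infraslow`` the
    infraslow σ-rhythm analysis and ``sigma_spindle`` the spindle detector;
    the three σ definitions are deliberately kept separate.
    """

    delta: tuple = (0.5, 4.0)
    theta: tuple = (5.0, 12.0)
    sigma_stage: tuple = (12.0, 20.0)
    gamma: tuple = (100.0, 150.0)
    emg: tuple = (50.0, 500.0)
    sigma_infraslow: tuple = (10.5, 16.0)
    sigma_spindle: tuple = (10.0, 16.67)

    def __post_init__(self):
        for name in ("delta", "theta", "sigma_stage", "gamma", "emg",
                     "sigma_infraslow", "sigma_spindle"):
            lo, hi = getattr(self, name)
            if not lo < hi:
                raise ValueError(f"band {name} must satisfy low < high (got {lo}, {hi})")


def compute_spectrogram(
    x: np.ndarray,
    fs: float,
    window_s: float = 5.0,
    overlap: float = 0.5,
    subwindow_s: float = 2.0,
    subwindow_overlap: float = 0.5,
    chunk: int = 2048,
) -> Spectrogram:
    """Sliding-window Welch spectrogram.

    One PSD column per window of ``window_s`` seconds advanced by
    ``window_s * (1 - overlap)``; within each window the PSD is Welch's
    mean of Hanning-tapered subwindow periodograms (mean removed per
    subwindow). Defaults give the 5 s / 2.5 s-step scoring spectrogram
    with 0.5 Hz resolution.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValueError("signal must be 1-D")
    nan_idx = np.flatnonzero(np.isnan(x))
    if nan_idx.size:
        raise ValueError(f"signal contains NaN (first at sample {nan_idx[0]})")
    nwin = int(round(window_s * fs))
    step = int(round(window_s * (1.0 - overlap) * fs))
    nsub = int(round(subwindow_s * fs))
    sub_overlap = int(round(nsub * subwindow_overlap))
    if step <= 0 or nwin <= 0:
        raise ValueError("window and step must be positive")
    if x.size < nwin:
        raise ValueError(
            f"signal of {x.size / fs:g} s is shorter than one {window_s:g} s window"
        )
    n_times = (x.size - nwin) // step + 1
    starts = step * np.arange(n_times)
    times = starts / fs

    windows = np.lib.stride_tricks.sliding_window_view(x, nwin)[::step]
    psd_chunks = []
    freqs = None
    for i in range(0, n_times, chunk):  # bound the welch work-array size
        freqs, psd = signal.welch(
            windows[i : i + chunk],
            fs=fs,
            window="hann",
            nperseg=nsub,
            noverlap=sub_overlap,
            detrend="constant",
            scaling="density",
            axis=-1,
        )
        psd_chunks.append(psd)
    power = np.concatenate(psd_chunks, axis=0)
    return Spectrogram(times=times, freqs=freqs, power=power)


def band_power(spectrogram: Spectrogram, band) -> np.ndarray:
    """Integrate the power density over a closed frequency band.

    Per time bin: sum of density over bins with ``lo <= f <= hi``
    (both edge bins included) times the bin width. Returns µV² per epoch.
    """
    lo, hi = band
    if lo < spectrogram.freqs[0] - 1e-9 or hi > spectrogram.freqs[-1] + 1e-9:
        raise ValueError(
            f"band [{lo}, {hi}] Hz is outside the spectrogram grid "
            f"[{spectrogram.freqs[0]}, {spectrogram.freqs[-1]}] Hz"
        )
    mask = (spectrogram.freqs >= lo - 1e-9) & (spectrogram.freqs <= hi + 1e-9)
    if not mask.any():
        raise ValueError(f"no frequency bins inside band [{lo}, {hi}] Hz")
    return spectrogram.power[:, mask].sum(axis=1) * spectrogram.df


def normalize_spectrogram(spectrogram: Spectrogram) -> Spectrogram:
    """Divide each frequency row by its own temporal mean.

    Every row of the result has temporal mean 1; downstream σ-rhythm
    analysis averages these dimensionless densities across the σ band.
    """
    means = spectrogram.power.mean(axis=0)
    bad = np.flatnonzero(means <= 0)
    if bad.size:
        raise ValueError(
            f"frequency row at {spectrogram.freqs[bad[0]]:g} Hz has non-positive "
            "temporal mean; cannot normalize"
        )
    return Spectrogram(
        times=spectrogram.times,
        freqs=spectrogram.freqs,
        power=spectrogram.power / means,
    )
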