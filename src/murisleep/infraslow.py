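"""Infraslow σ-rhythm quantification.

During consolidated NREM sleep, EEG power in the spindle (σ) band waxes
and wanes on a ~1-minute timescale (~0.02 Hz). The analysis: normalize
the scoring spectrogram per frequency, average the normalized density
over the σ band (10.5–16 Hz) to get a dimensionless σ time course at
2.5 s resolution, compute a Hanning-tapered PSD of that series per
consolidated NREM bout (>= 120 s), average PSDs across bouts, and
summarize with

* strength = area under the PSD over 0.01–0.04 Hz minus area over
  0.08–0.12 Hz (positive when the rhythm concentrates in the infraslow
  range), and
* peak frequency = argmax of the averaged PSD in a search range.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import signal

from .architecture import ConsolidatedBout
from .spectral import Spectrogram

logger = logging.getLogger(__name__)

SIGMA_BAND_INFRASLOW = (10.5, 16.0)
STRENGTH_BAND_LOW = (0.01, 0.04)
STRENGTH_BAND_HIGH = (0.08, 0.12)


@dataclass
class SigmaTimecourse:
    """Normalized σ power per 2.5 s epoch (dimensionless, ~1 on average)."""

    times: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.size != self.values.size:
            raise ValueError("times and values must have equal length")
        if np.any(self.values < 0):
            raise ValueError("normalized σ power must be non-negative")

    @property
    def fs(self) -> float:
        """Sampling rate of the σ series (Hz), 0.4 for the 2.5 s grid."""
        return 1.0 / float(self.times[1] - self.times[0])


@dataclass
class InfraslowPSD:
    """Bout-averaged PSD of the σ time course with summary metrics."""

    freqs: np.ndarray
    density: np.ndarray
    n_bouts: int
    strength: float
    peak_freq_hz: float


def sigma_timecourse(
    normalized_spectrogram: Spectrogram,
    band: tuple[float, float] = SIGMA_BAND_INFRASLOW,
    tol: float = 1e-6,
) -> SigmaTimecourse:
    """Mean normalized density over the σ band, per time bin.

    The input must already be normalized (per-frequency temporal mean 1);
    band rows deviating from mean 1 beyond ``tol`` raise ``ValueError``.
    """
    lo, hi = band
    mask = (normalized_spectrogram.freqs >= lo - 1e-9) & (
        normalized_spectrogram.freqs <= hi + 1e-9
    )
    if not mask.any():
        raise ValueError(f"no frequency bins inside σ band [{lo}, {hi}] Hz")
    row_means = normalized_spectrogram.power[:, mask].mean(axis=0)
    if np.any(np.abs(row_means - 1.0) > tol):
        raise ValueError(
            "spectrogram does not look normalized (per-frequency temporal "
            "means deviate from 1); call normalize_spectrogram first"
        )
    return SigmaTimecourse(
        times=normalized_spectrogram.times,
        values=normalized_spectrogram.power[:, mask].mean(axis=1),
    )


def infraslow_psd(
    timecourse: SigmaTimecourse, bouts: list[ConsolidatedBout]
) -> InfraslowPSD:
    """PSD of the σ series per consolidated bout, averaged across bouts.

    Each bout's PSD is a single mean-removed, Hanning-tapered periodogram
    of the whole bout (no Welch segmentation: bouts barely exceed the
    ~100 s needed to resolve 0.01 Hz, so splitting would destroy the
    frequency resolution). Bout PSDs are linearly interpolated onto the
    grid of the longest bout before averaging.
    """
    if not bouts:
        raise ValueError("no consolidated NREM bouts to analyze")
    fs = timecourse.fs
    per_bout = []
    for b in bouts:
        sel = (timecourse.times >= b.start_s) & (timecourse.times < b.end_s)
        x = timecourse.values[sel]
        if x.size < 2:
            raise ValueError(f"bout at {b.start_s:g} s has too few σ samples")
        f, p = signal.periodogram(x, fs=fs, window="hann", detrend="constant")
        per_bout.append((f, p))
    # common grid: the longest bout resolves frequency finest
    freqs = max(per_bout, key=lambda fp: fp[0].size)[0]
    density = np.mean([np.interp(freqs, f, p) for f, p in per_bout], axis=0)
    strength = infraslow_strength((freqs, density))
    peak = infraslow_peak_frequency((freqs, density))
    return InfraslowPSD(
        freqs=freqs,
        density=density,
        n_bouts=len(per_bout),
        strength=strength,
        peak_freq_hz=peak,
    )


def _freqs_density(psd) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(psd, InfraslowPSD):
        return psd.freqs, psd.density
    f, d = psd
    return np.asarray(f, dtype=float), np.asarray(d, dtype=float)


def _band_area(freqs: np.ndarray, density: np.ndarray, lo: float, hi: float) -> float:
    """Trapezoidal area of the density over [lo, hi], with the endpoints
    interpolated onto the grid (linear in the density)."""
    if lo < freqs[0] or hi > freqs[-1]:
        raise ValueError(
            f"PSD grid [{freqs[0]:g}, {freqs[-1]:g}] Hz does not cover [{lo}, {hi}] Hz"
        )
    inner = freqs[(freqs > lo) & (freqs < hi)]
    grid = np.concatenate([[lo], inner, [hi]])
    vals = np.interp(grid, freqs, density)
    return float(np.trapezoid(vals, grid))


def infraslow_strength(psd) -> float:
    """Area under the PSD over 0.01–0.04 Hz minus area over 0.08–0.12 Hz.

    Accepts an :class:`InfraslowPSD` or a ``(freqs, density)`` pair.
    Linear in the density.
    """
    freqs, density = _freqs_density(psd)
    return _band_area(freqs, density, *STRENGTH_BAND_LOW) - _band_area(
        freqs, density, *STRENGTH_BAND_HIGH
    )


def infraslow_peak_frequency(psd, search: tuple[float, float] = (0.005, 0.12)) -> float:
    """Frequency of the maximum density within the search range.

    Ties resolve to the lowest frequency (logged).
    """
    freqs, density = _freqs_density(psd)
    lo, hi = search
    mask = (freqs >= lo) & (freqs <= hi)
    if not mask.any():
        raise ValueError(f"search range [{lo}, {hi}] Hz contains no PSD bins")
    d = density[mask]
    f = freqs[mask]
    imax = int(np.argmax(d))  # first occurrence = lowest frequency on ties
    if np.count_nonzero(d == d[imax]) > 1:
        logger.info("infraslow peak tie; reporting the lowest tied frequency")
    return float(f[imax])
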