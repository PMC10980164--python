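"""Sleep-spindle detection from the frontal EEG.

Bin-wise two-criterion detector: a high-resolution spectrogram (600 ms
windows, 100 ms step) is scanned per bin for the maximum σ-band
(10–16.67 Hz) spectral peak. A bin is a spindle candidate iff

1. its σ-peak height exceeds the 96th percentile of all bins' σ-peak
   heights, and
2. its σ-peak height exceeds half the spectral peak in 0–10 Hz.

Adjacent candidate bins form events, events separated by gaps < 300 ms
are fused, events of duration <= 200 ms are discarded, and surviving
events must have the per-bin σ peak frequency inside 10–16.7 Hz in at
least half of their bins.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .core import Hypnogram
from .spectral import Spectrogram


@dataclass(frozen=True)
class SpindleParams:
    """Detector tunables (defaults are the optimized published values)."""

    win_ms: float = 600.0
    step_ms: float = 100.0
    sigma_band: tuple = (10.0, 16.67)
    low_band: tuple = (0.0, 10.0)
    sigma_percentile: float = 96.0
    peak_ratio: float = 0.5
    fuse_gap_ms: float = 300.0  # fuse gaps strictly below this
    min_dur_ms: float = 200.0   # discard events with duration <= this
    freq_fraction: float = 0.5  # fraction of bins that must peak in-band

    def __post_init__(self):
        if not 0 < self.sigma_percentile < 100:
            raise ValueError("sigma_percentile must be in (0, 100)")
        if not 0 < self.peak_ratio <= 1 or not 0 < self.freq_fraction <= 1:
            raise ValueError("ratios must be in (0, 1]")
        if min(self.win_ms, self.step_ms, self.fuse_gap_ms, self.min_dur_ms) <= 0:
            raise ValueError("durations must be positive")


@dataclass(frozen=True)
class SpindleEvent:
    """A detected spindle; duration counts bins (fused gaps included)."""

    start_s: float
    end_s: float
    n_bins: int
    bin_freqs: tuple  # σ-peak frequency (Hz) of every bin in the span
    in_band_fraction: float

    @property
    def duration_ms(self) -> float:
        return (self.end_s - self.start_s) * 1000.0


@dataclass
class CandidateBins:
    """Per-bin σ-peak measurements and the candidate mask."""

    times: np.ndarray        # bin (window) start times, 100 ms step
    is_candidate: np.ndarray
    peak_height: np.ndarray  # σ-band maximum density per bin
    peak_freq: np.ndarray    # frequency of that maximum (Hz)
    threshold: float         # the percentile threshold actually used


def spindle_spectrogram(eeg: np.ndarray, fs: float, params: SpindleParams | None = None) -> Spectrogram:
    """Per-bin spectrum: 600 ms Hanning-tapered windows every 100 ms.

    One column per 100 ms step; frequency resolution 1/0.6 s ≈ 1.67 Hz.
    """
    params = params or SpindleParams()
    x = np.asarray(eeg, dtype=float)
    nwin = int(round(params.win_ms / 1000.0 * fs))
    step = int(round(params.step_ms / 1000.0 * fs))
    if x.size < nwin:
        raise ValueError(
            f"signal of {x.size / fs * 1000:g} ms is shorter than one "
            f"{params.win_ms:g} ms window"
        )
    windows = np.lib.stride_tricks.sliding_window_view(x, nwin)[::step]
    freqs, power = signal.periodogram(
        windows, fs=fs, window="hann", detrend="constant", axis=-1
    )
    times = step * np.arange(windows.shape[0]) / fs
    return Spectrogram(times=times, freqs=freqs, power=power)


def detect_candidate_bins(
    spectrogram: Spectrogram,
    params: SpindleParams | None = None,
    hypnogram: Hypnogram | None = None,
) -> CandidateBins:
    """Flag bins passing the percentile and σ/low-peak-ratio criteria.

    With a hypnogram, detection (and the percentile threshold) is
    restricted to bins whose window start lies in a NREM epoch.
    """
    params = params or SpindleParams()
    lo, hi = params.sigma_band
    sigma_mask = (spectrogram.freqs >= lo - 1e-9) & (spectrogram.freqs <= hi + 1e-9)
    low_mask = (spectrogram.freqs >= params.low_band[0] - 1e-9) & (
        spectrogram.freqs <= params.low_band[1] + 1e-9
    )
    if not sigma_mask.any() or not low_mask.any():
        raise ValueError("spectrogram grid does not cover the detector bands")

    sigma_power = spectrogram.power[:, sigma_mask]
    peak_idx = np.argmax(sigma_power, axis=1)
    peak_height = sigma_power[np.arange(sigma_power.shape[0]), peak_idx]
    peak_freq = spectrogram.freqs[sigma_mask][peak_idx]
    low_peak = spectrogram.power[:, low_mask].max(axis=1)

    if hypnogram is not None:
        epoch_idx = np.clip(
            np.floor(spectrogram.times / hypnogram.epoch_s).astype(int),
            0,
            len(hypnogram) - 1,
        )
        in_scope = hypnogram.states[epoch_idx] == "N"
    else:
        in_scope = np.ones(spectrogram.times.size, dtype=bool)

    if in_scope.any():
        threshold = float(np.percentile(peak_height[in_scope], params.sigma_percentile))
    else:
        threshold = np.inf
    is_candidate = (
        in_scope & (peak_height > threshold) & (peak_height > params.peak_ratio * low_peak)
    )
    return CandidateBins(
        times=spectrogram.times,
        is_candidate=is_candidate,
        peak_height=peak_height,
        peak_freq=peak_freq,
        threshold=threshold,
    )


def assemble_spindles(
    candidates: CandidateBins, params: SpindleParams | None = None
) -> list[SpindleEvent]:
    """Merge candidate bins into spindle events.

    Adjacent candidate bins are one event; events separated by gaps
    strictly shorter than ``fuse_gap_ms`` are fused (the gap bins count
    toward the duration); events with duration <= ``min_dur_ms`` are
    discarded; surviving events need >= ``freq_fraction`` of their bins'
    σ-peak frequencies inside the σ band.
    """
    params = params or SpindleParams()
    step_s = params.step_ms / 1000.0
    idx = np.flatnonzero(candidates.is_candidate)
    if idx.size == 0:
        return []
    # runs of adjacent bins
    breaks = np.flatnonzero(np.diff(idx) > 1)
    runs = [(int(g[0]), int(g[-1])) for g in np.split(idx, breaks + 1)]
    # fuse runs separated by gaps < fuse_gap_ms
    fused = [list(runs[0])]
    for a, b in runs[1:]:
        gap_bins = a - fused[-1][1] - 1
        if gap_bins * params.step_ms < params.fuse_gap_ms:
            fused[-1][1] = b
        else:
            fused.append([a, b])

    lo, hi = params.sigma_band
    events = []
    for a, b in fused:
        n_bins = b - a + 1
        if n_bins * params.step_ms <= params.min_dur_ms:
            continue
        freqs = candidates.peak_freq[a : b + 1]
        frac = float(np.mean((freqs >= lo - 1e-9) & (freqs <= hi + 1e-9)))
        if frac < params.freq_fraction:
            continue
        start = float(candidates.times[a])
        events.append(
            SpindleEvent(
                start_s=start,
                end_s=start + n_bins * step_s,
                n_bins=n_bins,
                bin_freqs=tuple(float(f) for f in freqs),
                in_band_fraction=frac,
            )
        )
    return events


def detect_spindles(
    eeg: np.ndarray,
    fs: float,
    params: SpindleParams | None = None,
    hypnogram: Hypnogram | None = None,
) -> list[SpindleEvent]:
    """Full detector: spectrogram → candidate bins → assembled events."""
    params = params or SpindleParams()
    spec = spindle_spectrogram(eeg, fs, params)
    cands = detect_candidate_bins(spec, params, hypnogram)
    return assemble_spindles(cands, params)


def grid_search_params(
    eeg: np.ndarray,
    fs: float,
    true_events,
    hypnogram: Hypnogram | None = None,
    percentiles=(90.0, 93.0, 96.0, 98.0),
    peak_ratios=(0.3, 0.5, 0.7),
    fuse_gaps_ms=(200.0, 300.0, 400.0),
    match_tol_s: float = 0.3,
) -> tuple[SpindleParams, float]:
    """Grid-search detector parameters against known ground-truth events.

    Scores each parameter set by F1 (events matched within ``match_tol_s``)
    and returns the best set with its F1. Stands in for calibration
    against manual annotations when ground truth is synthetic.
    """
    best, best_f1 = SpindleParams(), -1.0
    for pc in percentiles:
        for pr in peak_ratios:
            for fg in fuse_gaps_ms:
                params = SpindleParams(sigma_percentile=pc, peak_ratio=pr, fuse_gap_ms=fg)
                det = detect_spindles(eeg, fs, params, hypnogram)
                tp, _, _ = match_events(det, true_events, match_tol_s)
                prec = tp / len(det) if det else 0.0
                rec = tp / len(true_events) if len(true_events) else 0.0
                f1 = 2 * prec * rec / (prec + rec) if prec + rec else 0.0
                if f1 > best_f1:
                    best, best_f1 = params, f1
    return best, best_f1


def match_events(detected, truth, tol_s: float = 0.3) -> tuple[int, float, float]:
    """Greedy one-to-one interval matching with ``tol_s`` padding.

    A detected event matches a true event when their intervals overlap
    after expanding the true interval by ``tol_s`` on each side. Returns
    (n_matched, precision, recall); truth items may be (start_s,
    duration_s) pairs or objects with those attributes.
    """

    def _interval(ev):
        if hasattr(ev, "start_s"):
            end = getattr(ev, "end_s", None)
            if end is None:
                end = ev.start_s + getattr(ev, "duration_s", 0.0)
            return float(ev.start_s), float(end)
        s, d = ev
        return float(s), float(s) + float(d)

    truth_iv = [_interval(t) for t in truth]
    used = [False] * len(truth_iv)
    matched = 0
    for ev in detected:
        a, b = _interval(ev)
        for k, (s, e) in enumerate(truth_iv):
            if not used[k] and a <= e + tol_s and b >= s - tol_s:
                used[k] = True
                matched += 1
                break
    precision = matched / len(detected) if detected else 0.0
    recall = matched / len(truth_iv) if truth_iv else 0.0
    return matched, precision, recall
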