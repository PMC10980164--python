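"""Fiber-photometry ΔF/F and infraslow-timescale calcium transients.

ΔF/F uses the isosbestic correction: both the calcium-dependent 465 nm
signal and the calcium-independent 405 nm reference are low-pass
filtered at 2 Hz (4th-order Butterworth, zero-phase), the 405 nm trace
is fitted to the 465 nm trace by least squares (slope + intercept), and
ΔF/F = (F465 − fit) / fit. The fit absorbs photobleaching and motion
artifacts shared by the two excitation wavelengths.

Transients on the infraslow timescale are local maxima of the ΔF/F
signal low-passed at 1/15 Hz (zero-phase Butterworth), with topographic
prominence of at least 0.05 × (99th − 1st percentile) of the filtered
signal — a threshold invariant under affine rescaling of ΔF/F.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import signal

from .core import Hypnogram
from .architecture import detect_microarousals

logger = logging.getLogger(__name__)

#: Photometry is decimated to this rate before filtering; the 1/15 Hz
#: filter is numerically ill-conditioned at acquisition rates ~1.5 kHz.
TARGET_FS = 100.0


@dataclass
class PhotometryTrace:
    """Dual-wavelength photometry channels (arbitrary fluorescence units)."""

    sig465: np.ndarray
    sig405: np.ndarray
    fs: float
    dff: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.sig465 = np.asarray(self.sig465, dtype=float)
        self.sig405 = np.asarray(self.sig405, dtype=float)
        if self.sig465.size != self.sig405.size:
            raise ValueError("465 and 405 nm channels must have equal length")
        if not self.fs > 0:
            raise ValueError("sampling rate must be positive")

    @property
    def duration_s(self) -> float:
        return self.sig465.size / self.fs


@dataclass(frozen=True)
class TransientEvent:
    """A detected calcium transient (peak time and prominence)."""

    time_s: float
    prominence: float


def _zero_phase_lowpass(x: np.ndarray, fs: float, cutoff_hz: float, order: int = 4) -> np.ndarray:
    sos = signal.butter(order, cutoff_hz, btype="low", fs=fs, output="sos")
    return signal.sosfiltfilt(sos, x)


def compute_dff(trace: PhotometryTrace, lowpass_hz: float = 2.0) -> PhotometryTrace:
    """Isosbestic-corrected ΔF/F.

    Returns a new trace (decimated to ~100 Hz if acquired faster) with
    ``dff`` set. Raises if the 405 nm channel is constant (the fit is
    degenerate) or if the fitted baseline is not strictly positive.
    """
    fs = trace.fs
    s465, s405 = trace.sig465, trace.sig405
    if fs > TARGET_FS:
        q = int(round(fs / TARGET_FS))
        logger.info("decimating photometry by %d: %g -> %g Hz", q, fs, fs / q)
        s465 = signal.resample_poly(s465, 1, q)
        s405 = signal.resample_poly(s405, 1, q)
        fs = fs / q
    s465 = _zero_phase_lowpass(s465, fs, lowpass_hz)
    s405 = _zero_phase_lowpass(s405, fs, lowpass_hz)
    if np.ptp(s405) == 0:
        raise ValueError("405 nm reference channel is constant; cannot fit baseline")
    slope, intercept = np.polyfit(s405, s465, deg=1)
    fit = slope * s405 + intercept
    if np.any(fit <= 0):
        raise ValueError("fitted 405->465 baseline is not strictly positive; ΔF/F undefined")
    return PhotometryTrace(sig465=s465, sig405=s405, fs=fs, dff=(s465 - fit) / fit)


def detect_transients(
    dff: np.ndarray,
    fs: float,
    cutoff_hz: float = 1.0 / 15.0,
    prominence_scale: float = 0.05,
    hypnogram: Hypnogram | None = None,
    ma_max_s: float = 20.0,
) -> list[TransientEvent]:
    """Prominence-thresholded peaks of the slow-filtered ΔF/F signal.

    The prominence threshold is ``prominence_scale`` × (p99 − p1) of the
    *filtered* signal, so the detector is invariant under positive affine
    rescaling of ΔF/F. With a hypnogram, only peaks occurring during NREM
    or inside microarousals are kept, matching the convention of counting
    transients during NREM sleep.
    """
    dff = np.asarray(dff, dtype=float)
    if dff.size <= 15 * fs:
        raise ValueError("ΔF/F shorter than one 15 s filter period")
    x = _zero_phase_lowpass(dff, fs, cutoff_hz)
    p1, p99 = np.percentile(x, [1, 99])
    prominence = prominence_scale * (p99 - p1)
    peaks, props = signal.find_peaks(x, prominence=max(prominence, 0.0) or None)
    times = peaks / fs
    proms = props.get("prominences", np.zeros(peaks.size))

    if hypnogram is not None:
        keep = _nrem_or_ma_mask(times, hypnogram, ma_max_s)
        times, proms = times[keep], proms[keep]
    return [TransientEvent(time_s=float(t), prominence=float(p)) for t, p in zip(times, proms)]


def _nrem_or_ma_mask(times: np.ndarray, hypnogram: Hypnogram, ma_max_s: float) -> np.ndarray:
    epoch_idx = np.floor(times / hypnogram.epoch_s).astype(int)
    inside = (epoch_idx >= 0) & (epoch_idx < len(hypnogram))
    keep = np.zeros(times.size, dtype=bool)
    keep[inside] = hypnogram.states[epoch_idx[inside]] == "N"
    for ma in detect_microarousals(hypnogram, ma_max_s):
        keep |= (times >= ma.start_s) & (times < ma.end_s)
    return keep


def state_activity(dff: np.ndarray, fs: float, hypnogram: Hypnogram) -> dict[str, float]:
    """Mean z-scored ΔF/F per sleep state.

    ΔF/F is z-scored over the whole recording, then averaged over the
    samples falling in each state's epochs. Absent states yield NaN.
    """
    dff = np.asarray(dff, dtype=float)
    sd = dff.std()
    z = (dff - dff.mean()) / sd if sd > 0 else np.zeros_like(dff)
    t = np.arange(dff.size) / fs
    epoch_idx = np.floor(t / hypnogram.epoch_s).astype(int)
    valid = epoch_idx < len(hypnogram)
    out = {}
    for state in ("W", "N", "R"):
        mask = valid & (hypnogram.states[np.clip(epoch_idx, 0, len(hypnogram) - 1)] == state)
        if mask.any():
            out[state] = float(z[mask].mean())
        else:
            logger.info("state %s absent from hypnogram; activity is NaN", state)
            out[state] = math.nan
    return out


@dataclass(frozen=True)
class OverlapResult:
    """Transient–microarousal coincidence summary."""

    proportion: float
    n_coincident: int
    n_transients: int


def transient_event_overlap(
    transients: list[TransientEvent], ma_events, window_s: float = 10.0
) -> OverlapResult:
    """Fraction of transients whose peak falls within a window around an MA.

    A transient coincides with an MA when its peak lies inside
    ``[MA.start − window_s, MA.start + MA.duration + window_s]``. The
    default ±10 s window reflects the infraslow (~15 s) timescale of the
    transients; it is configurable and reported alongside results.
    """
    if not transients:
        return OverlapResult(proportion=0.0, n_coincident=0, n_transients=0)
    n_hit = 0
    for tr in transients:
        for ma in ma_events:
            if ma.start_s - window_s <= tr.time_s <= ma.start_s + ma.duration_s + window_s:
                n_hit += 1
                break
    return OverlapResult(
        proportion=n_hit / len(transients), n_coincident=n_hit, n_transients=len(transients)
    )
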