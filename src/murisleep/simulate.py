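"""Ground-truth-labelled synthetic recordings.

The generator emulates the statistical structure the analysis stages
assume, so the whole pipeline is testable without animal data:

* a semi-Markov hypnogram (Wake → NREM → {REM | Wake}, REM entered only
  from NREM) with exponential dwell times, plus microarousals (wake
  interruptions <= 20 s) injected into NREM runs at a configurable rate;
* EEG built from band-limited noise whose amplitudes switch by state
  (δ-dominant NREM, θ-dominant REM, broadband + γ wake), a σ component
  amplitude-modulated at the infraslow frequency during NREM, and
  injected spindle bursts; EMG with state-dependent tone (W ≫ N >= R);
* dual-wavelength photometry with shared bleaching/motion, state-
  dependent ΔF/F offsets (W > N > R) and calcium transients coupled to
  microarousal onsets;
* randomized tone schedules, optionally with wake probability coupled
  to the instantaneous phase of the infraslow σ modulation.

Every generator is deterministic under a fixed seed and returns the
ground truth alongside the signals.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal

from .core import EPOCH_S, Hypnogram, Recording, make_event_table
from .photometry import PhotometryTrace


def _default_band_amps() -> dict:
    # per-state RMS amplitude (µV) of each EEG noise component
    return {
        "W": {"delta": 15.0, "theta": 20.0, "sigma": 5.0, "gamma": 10.0, "broadband": 30.0},
        "N": {"delta": 60.0, "theta": 20.0, "sigma": 12.0, "gamma": 2.0, "broadband": 10.0},
        "R": {"delta": 10.0, "theta": 50.0, "sigma": 5.0, "gamma": 3.0, "broadband": 10.0},
    }


@dataclass
class SimConfig:
    """Study conditions for the synthetic generators.

    Defaults emulate a mouse polysomnography session: 1 kHz EEG/EMG,
    exponential dwells (W 120 s, N 300 s, R 60 s), one microarousal per
    NREM minute, a 0.02 Hz infraslow σ modulation, ~12 Hz spindles, and
    LC-like calcium transients coupled to microarousals.
    """

    duration_s: float = 3600.0
    fs_eeg: float = 1000.0
    fs_photo: float = 100.0
    seed: int = 0

    # hypnogram
    dwell_mean_s: dict = field(default_factory=lambda: {"W": 120.0, "N": 300.0, "R": 60.0})
    p_nrem_to_rem: float = 0.25
    min_wake_bout_s: float = 25.0  # spontaneous wake bouts exceed the MA bound
    ma_rate_per_min_nrem: float = 1.0
    ma_dur_range_s: tuple = (2.5, 20.0)

    # EEG / EMG
    band_amps: dict = field(default_factory=_default_band_amps)
    emg_rms: dict = field(default_factory=lambda: {"W": 40.0, "N": 8.0, "R": 5.0})
    infraslow_freq_hz: float = 0.02
    infraslow_depth: float = 0.4
    infraslow_phase: float = 0.0
    spindle_rate_per_min: float = 3.0
    spindle_dur_ms: tuple = (500.0, 800.0)
    spindle_freq_hz: float = 12.0
    spindle_amp_uv: float = 90.0

    # photometry
    transient_rate_per_min_nrem: float = 0.3
    p_transient_given_ma: float = 0.5
    transient_amp: float = 0.1
    transient_width_s: float = 6.0   # Gaussian sigma; bump width ~ the 15 s detection timescale
    transient_min_gap_s: float = 20.0
    bleach_tau_s: float = 7200.0
    photo_baseline: float = 1.0
    photo_noise: float = 0.01
    motion_amp: float = 0.002  # sleeping animal: shared motion artifacts are small
    state_dff_offsets: dict = field(default_factory=lambda: {"W": 0.15, "N": 0.05, "R": 0.0})
    offset_smooth_s: float = 5.0  # indicator kinetics: state offsets ramp, not step

    def __post_init__(self):
        if any(v < 0 for v in (self.ma_rate_per_min_nrem, self.spindle_rate_per_min,
                               self.transient_rate_per_min_nrem)):
            raise ValueError("rates must be non-negative")
        if not 0 <= self.infraslow_depth <= 1:
            raise ValueError("infraslow_depth must be in [0, 1]")
        if not 0 <= self.p_transient_given_ma <= 1:
            raise ValueError("p_transient_given_ma must be in [0, 1]")
        lo, hi = self.ma_dur_range_s
        if not (0 < lo <= hi <= 20.0):
            raise ValueError("ma_dur_range_s must lie within (0, 20]")


def _rng(rng, config: SimConfig | None = None) -> np.random.Generator:
    if rng is None:
        return np.random.default_rng(config.seed if config is not None else 0)
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)


# ---------------------------------------------------------------------------
# hypnogram
# ---------------------------------------------------------------------------

def simulate_hypnogram(config: SimConfig, rng=None) -> tuple[Hypnogram, pd.DataFrame]:
    """Semi-Markov hypnogram plus the ground-truth microarousal table.

    Spontaneous wake dwells are floored at ``min_wake_bout_s`` (> 20 s),
    so every wake run at or below the MA bound flanked by NREM is an
    injected, recorded microarousal.
    """
    rng = _rng(rng, config)
    n_epochs = int(math.floor(config.duration_s / EPOCH_S))
    if n_epochs < 1:
        raise ValueError(
            f"duration {config.duration_s:g} s is too short for one {EPOCH_S:g} s epoch"
        )
    states: list[str] = []
    state = "W"
    while len(states) < n_epochs:
        dwell = rng.exponential(config.dwell_mean_s[state])
        if state == "W":
            dwell = max(dwell, config.min_wake_bout_s)
        n_run = min(max(1, int(math.ceil(dwell / EPOCH_S))), n_epochs - len(states))
        states.extend([state] * n_run)
        if state == "W":
            state = "N"
        elif state == "N":
            state = "R" if rng.random() < config.p_nrem_to_rem else "W"
        else:
            state = "W"
    arr = np.array(states[:n_epochs])
    ma_rows = _insert_microarousals(arr, config, rng)
    mas = make_event_table(
        {"time_s": [r[0] for r in ma_rows],
         "kind": ["MA"] * len(ma_rows),
         "duration_s": [r[1] for r in ma_rows]}
    )
    return Hypnogram(states=arr), mas


def _insert_microarousals(states: np.ndarray, config: SimConfig, rng) -> list:
    """Replace interior NREM epochs with wake runs <= 20 s, in place."""
    if config.ma_rate_per_min_nrem == 0:
        return []
    lo_ep = max(1, int(math.ceil(config.ma_dur_range_s[0] / EPOCH_S)))
    hi_ep = max(lo_ep, int(math.floor(config.ma_dur_range_s[1] / EPOCH_S)))
    rows = []
    boundaries = np.flatnonzero(states[1:] != states[:-1]) + 1
    starts = np.concatenate([[0], boundaries])
    ends = np.concatenate([boundaries, [states.size]])
    for s, e in zip(starts, ends):
        if states[s] != "N":
            continue
        run_min = (e - s) * EPOCH_S / 60.0
        n_ma = rng.poisson(config.ma_rate_per_min_nrem * run_min)
        occupied: list[tuple[int, int]] = []
        for _ in range(n_ma):
            dur_ep = int(rng.integers(lo_ep, hi_ep + 1))
            # interior placement: >= 1 NREM epoch on each side and between MAs
            lo_start, hi_start = s + 1, e - 1 - dur_ep
            if hi_start < lo_start:
                continue
            for _attempt in range(50):
                a = int(rng.integers(lo_start, hi_start + 1))
                b = a + dur_ep
                if all(b + 1 <= oa or a >= ob + 1 for oa, ob in occupied):
                    occupied.append((a, b))
                    states[a:b] = "W"
                    rows.append((a * EPOCH_S, dur_ep * EPOCH_S))
                    break
    rows.sort()
    return rows


# ---------------------------------------------------------------------------
# EEG / EMG
# ---------------------------------------------------------------------------

_COMPONENT_BANDS = {
    "delta": (0.5, 4.0),
    "theta": (5.0, 12.0),
    "sigma": (10.5, 16.0),
    "gamma": (100.0, 150.0),
}


def _band_noise(n: int, fs: float, band, rng) -> np.ndarray:
    """Unit-RMS band-limited Gaussian noise."""
    white = rng.standard_normal(n)
    sos = signal.butter(4, band, btype="bandpass", fs=fs, output="sos")
    x = signal.sosfilt(sos, white)
    return x / x.std()


def synthesize_signals(
    hypnogram: Hypnogram, config: SimConfig, rng=None
) -> tuple[Recording, pd.DataFrame]:
    """EEG/EMG from the hypnogram plus the ground-truth spindle table."""
    rng = _rng(rng, config)
    fs = config.fs_eeg
    epoch_len = int(round(hypnogram.epoch_s * fs))
    n = len(hypnogram) * epoch_len
    t = np.arange(n) / fs
    is_nrem = np.repeat(hypnogram.states == "N", epoch_len)

    eeg = np.zeros(n)
    for name, band in _COMPONENT_BANDS.items():
        amp = np.repeat(
            np.array([config.band_amps[s][name] for s in hypnogram.states]), epoch_len
        )
        if name == "sigma" and config.infraslow_depth > 0:
            mod = 1.0 + config.infraslow_depth * np.sin(
                2 * np.pi * config.infraslow_freq_hz * t + config.infraslow_phase
            )
            amp = np.where(is_nrem, amp * mod, amp)
        eeg += amp * _band_noise(n, fs, band, rng)
    bb_amp = np.repeat(
        np.array([config.band_amps[s]["broadband"] for s in hypnogram.states]), epoch_len
    )
    eeg += bb_amp * rng.standard_normal(n)

    spindle_rows = _inject_spindles(eeg, hypnogram, config, rng)
    spindles = make_event_table(
        {"time_s": [r[0] for r in spindle_rows],
         "kind": ["spindle"] * len(spindle_rows),
         "duration_s": [r[1] for r in spindle_rows]}
    )

    emg_white = rng.standard_normal(n)
    sos = signal.butter(4, 50.0, btype="highpass", fs=fs, output="sos")
    emg = signal.sosfilt(sos, emg_white)
    emg /= emg.std()
    emg *= np.repeat(np.array([config.emg_rms[s] for s in hypnogram.states]), epoch_len)

    return Recording(eeg=eeg, emg=emg, fs=fs), spindles


def _inject_spindles(eeg: np.ndarray, hypnogram: Hypnogram, config: SimConfig, rng) -> list:
    """Add Hann-windowed σ-frequency bursts during NREM, in place."""
    if config.spindle_rate_per_min == 0:
        return []
    fs = config.fs_eeg
    rows = []
    states = hypnogram.states
    boundaries = np.flatnonzero(states[1:] != states[:-1]) + 1
    starts = np.concatenate([[0], boundaries])
    ends = np.concatenate([boundaries, [states.size]])
    for s, e in zip(starts, ends):
        if states[s] != "N":
            continue
        run_start_s, run_end_s = s * EPOCH_S, e * EPOCH_S
        n_sp = rng.poisson(config.spindle_rate_per_min * (run_end_s - run_start_s) / 60.0)
        placed: list[tuple[float, float]] = []
        for _ in range(n_sp):
            dur = rng.uniform(*config.spindle_dur_ms) / 1000.0
            if run_end_s - run_start_s <= dur:
                continue
            for _attempt in range(50):
                t0 = rng.uniform(run_start_s, run_end_s - dur)
                if all(t0 + dur + 0.3 <= a or t0 >= a + d + 0.3 for a, d in placed):
                    placed.append((t0, dur))
                    break
            else:
                continue
            i0 = int(round(t0 * fs))
            m = int(round(dur * fs))
            tt = np.arange(m) / fs
            burst = (
                config.spindle_amp_uv
                * np.hanning(m)
                * np.sin(2 * np.pi * config.spindle_freq_hz * tt + rng.uniform(0, 2 * np.pi))
            )
            eeg[i0 : i0 + m] += burst
            rows.append((t0, dur))
    rows.sort()
    return rows


def pink_noise(n: int, rng) -> np.ndarray:
    """Unit-RMS 1/f-amplitude noise (spectral shaping of white noise)."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n)
    f[0] = f[1]  # keep DC finite
    spec /= np.sqrt(f)
    x = np.fft.irfft(spec, n)
    return x / x.std()


def synthesize_spindle_benchmark(
    duration_s: float,
    fs: float = 1000.0,
    rate_per_min: float = 5.0,
    amp_factor: float = 3.0,
    dur_range_ms: tuple = (500.0, 800.0),
    freq_hz: float = 12.0,
    background_rms_uv: float = 30.0,
    rng=None,
) -> tuple[np.ndarray, pd.DataFrame]:
    """EEG benchmark for the spindle detector: pink-noise background plus
    injected σ-frequency bursts at known times.

    Burst σ-band RMS is ``amp_factor`` × the background's σ-band RMS.
    The default burst rate keeps burst bins above the ~4 % bin occupancy
    the 96th-percentile criterion presumes of the scanned signal.
    Returns the signal (µV) and the ground-truth event table.
    """
    rng = _rng(rng)
    n = int(round(duration_s * fs))
    eeg = background_rms_uv * pink_noise(n, rng)
    sos = signal.butter(4, (10.0, 16.67), btype="bandpass", fs=fs, output="sos")
    sigma_rms = signal.sosfilt(sos, eeg).std()
    # Hann-windowed sinusoid: RMS over the burst = amp * sqrt(0.375 / 2)
    amp = amp_factor * sigma_rms / math.sqrt(0.375 / 2.0)
    n_bursts = rng.poisson(rate_per_min * duration_s / 60.0)
    placed: list[tuple[float, float]] = []
    for _ in range(n_bursts):
        dur = rng.uniform(*dur_range_ms) / 1000.0
        for _attempt in range(100):
            t0 = rng.uniform(0, duration_s - dur)
            if all(t0 + dur + 1.0 <= a or t0 >= a + d + 1.0 for a, d in placed):
                placed.append((t0, dur))
                break
        else:
            continue
        i0 = int(round(t0 * fs))
        m = int(round(dur * fs))
        tt = np.arange(m) / fs
        eeg[i0 : i0 + m] += amp * np.hanning(m) * np.sin(
            2 * np.pi * freq_hz * tt + rng.uniform(0, 2 * np.pi)
        )
    placed.sort()
    truth = make_event_table(
        {"time_s": [a for a, _ in placed],
         "kind": ["spindle"] * len(placed),
         "duration_s": [d for _, d in placed]}
    )
    return eeg, truth


# ---------------------------------------------------------------------------
# photometry
# ---------------------------------------------------------------------------

def synthesize_photometry(
    hypnogram: Hypnogram, ma_events, config: SimConfig, rng=None
) -> tuple[PhotometryTrace, pd.DataFrame]:
    """Dual-wavelength photometry plus ground-truth transient peak times.

    465 nm carries bleaching × (1 + state offset + transient kernels +
    motion) + noise; 405 nm shares the bleaching and motion but no
    calcium activity. Transients sit at microarousal onsets with
    probability ``p_transient_given_ma``, plus independent NREM
    transients at ``transient_rate_per_min_nrem``; peaks closer than
    ``transient_min_gap_s`` to an accepted one are dropped (and so never
    enter the ground truth).
    """
    rng = _rng(rng, config)
    fs = config.fs_photo
    epoch_len = int(round(hypnogram.epoch_s * fs))
    n = len(hypnogram) * epoch_len
    t = np.arange(n) / fs

    candidates = []
    ma_starts = _ma_start_times(ma_events)
    for start in ma_starts:
        if rng.random() < config.p_transient_given_ma:
            candidates.append(float(start))
    if config.transient_rate_per_min_nrem > 0:
        for i, s in enumerate(hypnogram.states):
            if s != "N":
                continue
            lam = config.transient_rate_per_min_nrem * hypnogram.epoch_s / 60.0
            for _ in range(rng.poisson(lam)):
                candidates.append(float(i * hypnogram.epoch_s + rng.uniform(0, hypnogram.epoch_s)))
    candidates.sort()
    peaks: list[float] = []
    for c in candidates:
        if not peaks or c - peaks[-1] >= config.transient_min_gap_s:
            peaks.append(c)

    # State-dependent ΔF/F offset. Microarousal epochs keep the NREM
    # offset: the calcium surge at an MA is modelled by the coupled
    # transient kernel, not by the wake offset (otherwise every MA would
    # carry an unrecorded second bump).
    from .architecture import detect_microarousals

    offset_states = hypnogram.states.copy()
    for ma in detect_microarousals(hypnogram):
        a = int(round(ma.start_s / hypnogram.epoch_s))
        b = a + int(round(ma.duration_s / hypnogram.epoch_s))
        offset_states[a:b] = "N"
    activity = np.repeat(
        np.array([config.state_dff_offsets[s] for s in offset_states]), epoch_len
    ).astype(float)
    if config.offset_smooth_s > 0:
        # Gaussian smoothing of the offset trace emulates indicator
        # kinetics; instantaneous steps would ring through the 1/15 Hz
        # transient-detection filter.
        ksig = config.offset_smooth_s * fs
        kt = np.arange(-int(4 * ksig), int(4 * ksig) + 1)
        kernel = np.exp(-0.5 * (kt / ksig) ** 2)
        kernel /= kernel.sum()
        activity = np.convolve(activity, kernel, mode="same")
    sig = config.transient_width_s
    half = int(round(5 * sig * fs))
    for t0 in peaks:
        i0 = int(round(t0 * fs))
        lo, hi = max(0, i0 - half), min(n, i0 + half + 1)
        tt = t[lo:hi] - t0
        activity[lo:hi] += config.transient_amp * np.exp(-0.5 * (tt / sig) ** 2)

    bleach = np.exp(-t / config.bleach_tau_s) if np.isfinite(config.bleach_tau_s) else np.ones(n)
    if config.motion_amp > 0:
        sos = signal.butter(2, 0.1, btype="low", fs=fs, output="sos")
        motion = signal.sosfilt(sos, rng.standard_normal(n))
        motion *= config.motion_amp / motion.std()
    else:
        motion = np.zeros(n)

    s465 = config.photo_baseline * bleach * (1.0 + activity + motion)
    s405 = 0.7 * config.photo_baseline * bleach * (1.0 + motion)
    if config.photo_noise > 0:
        s465 = s465 + config.photo_noise * rng.standard_normal(n)
        s405 = s405 + config.photo_noise * rng.standard_normal(n)

    transients = make_event_table(
        {"time_s": peaks, "kind": ["transient"] * len(peaks), "duration_s": [0.0] * len(peaks)}
    )
    return PhotometryTrace(sig465=s465, sig405=s405, fs=fs), transients


def _ma_start_times(ma_events) -> np.ndarray:
    if isinstance(ma_events, pd.DataFrame):
        return ma_events["time_s"].to_numpy(dtype=float)
    return np.array([getattr(m, "start_s") for m in ma_events], dtype=float)


# ---------------------------------------------------------------------------
# tones
# ---------------------------------------------------------------------------

def schedule_tones(
    duration_s: float,
    min_gap_s: float = 240.0,
    max_gap_s: float = 1200.0,
    rng=None,
) -> np.ndarray:
    """Tone onsets with i.i.d. uniform gaps in [min_gap_s, max_gap_s].

    The first onset falls one gap after t=0; recordings shorter than one
    gap yield an empty schedule.
    """
    rng = _rng(rng)
    onsets = []
    t = 0.0
    while True:
        t += rng.uniform(min_gap_s, max_gap_s)
        if t >= duration_s:
            break
        onsets.append(t)
    return np.array(onsets)


def apply_sound_evoked_arousals(
    hypnogram: Hypnogram,
    tone_onsets,
    config: SimConfig,
    rng=None,
    phase_coupled: bool = True,
    p_descending: float = 0.9,
    p_ascending: float = 0.1,
    p_flat: float = 0.5,
    wake_delay_s: float = 5.0,
    wake_dur_range_s: tuple = (25.0, 40.0),
) -> tuple[Hypnogram, np.ndarray]:
    """Insert tone-triggered awakenings into a hypnogram.

    For each tone falling in NREM the animal wakes with a probability
    that, when ``phase_coupled``, depends on the sign of the derivative
    of the infraslow σ modulation at onset (descending phase → high wake
    probability — the phase-tuning signature); otherwise the probability
    is ``p_flat``. Awakenings start ``wake_delay_s`` after onset (inside
    the 20 s tone) and last > 20 s so they score as genuine wake bouts,
    not microarousals. Returns the modified hypnogram and the onsets
    that produced an awakening.
    """
    rng = _rng(rng, config)
    states = hypnogram.states.copy()
    woke = []
    for onset in np.asarray(tone_onsets, dtype=float):
        try:
            k = hypnogram.epoch_of(onset)
        except IndexError:
            continue
        if states[k] != "N":
            continue
        if phase_coupled:
            deriv = np.cos(2 * np.pi * config.infraslow_freq_hz * onset + config.infraslow_phase)
            p = p_descending if deriv < 0 else p_ascending
        else:
            p = p_flat
        if rng.random() < p:
            first = hypnogram.epoch_of(min(onset + wake_delay_s, hypnogram.duration_s - EPOCH_S))
            dur_ep = int(math.ceil(rng.uniform(*wake_dur_range_s) / EPOCH_S))
            states[first : first + dur_ep] = "W"
            woke.append(onset)
    return Hypnogram(states=states), np.array(woke)


# ---------------------------------------------------------------------------
# full study
# ---------------------------------------------------------------------------

@dataclass
class SimStudy:
    """Bundle of one synthetic session with all ground truth."""

    config: SimConfig
    hypnogram: Hypnogram
    ma_events: pd.DataFrame
    recording: Recording
    spindle_events: pd.DataFrame
    photometry: PhotometryTrace
    transient_events: pd.DataFrame


def simulate_study(config: SimConfig, rng=None) -> SimStudy:
    """Generate hypnogram, EEG/EMG and photometry with one seed."""
    root = _rng(rng, config)
    r_hyp, r_sig, r_photo = [np.random.default_rng(s) for s in root.spawn(3)]
    hyp, mas = simulate_hypnogram(config, r_hyp)
    rec, spindles = synthesize_signals(hyp, config, r_sig)
    photo, transients = synthesize_photometry(hyp, mas, config, r_photo)
    return SimStudy(
        config=config,
        hypnogram=hyp,
        ma_events=mas,
        recording=rec,
        spindle_events=spindles,
        photometry=photo,
        transient_events=transients,
    )
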