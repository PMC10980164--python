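"""Sound-evoked arousal trials.

Tones (20 s) are presented during sleep; a trial is *eligible* when the
animal is in NREM at tone onset and the MA-bridged NREM span preceding
the onset exceeds 120 s. Eligible trials split into *arousal* (any wake
epoch within the tone window) versus *sleep-through*. The σ-power time
course before tone onset carries the infraslow-phase signature: σ power
falls before arousals and rises before sleep-throughs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .architecture import consolidate_nrem
from .core import Hypnogram
from .infraslow import SigmaTimecourse


@dataclass
class ToneTrial:
    """One sound presentation and its outcome."""

    onset_s: float
    eligible: bool
    outcome: str  # "arousal" | "sleep_through" | "ineligible"
    reason: str | None = None


def classify_tone_trials(
    hypnogram: Hypnogram,
    tone_onsets,
    tone_dur_s: float = 20.0,
    min_nrem_s: float = 120.0,
    eligibility: str = "pre_onset",
    ma_max_s: float = 20.0,
) -> list[ToneTrial]:
    """Classify tone presentations into arousal vs sleep-through.

    Eligibility requires NREM at onset and an MA-bridged NREM span
    exceeding ``min_nrem_s``; ``eligibility`` selects whether the
    pre-onset portion of the span ("pre_onset", default — the quantity
    causally available at stimulus time) or the whole span ("episode")
    must exceed the bound. Outcome is "arousal" iff any wake epoch
    overlaps ``[onset, onset + tone_dur_s)``.
    """
    if eligibility not in ("pre_onset", "episode"):
        raise ValueError("eligibility must be 'pre_onset' or 'episode'")
    spans = consolidate_nrem(hypnogram, min_span_s=0.0, ma_max_s=ma_max_s)
    trials = []
    for onset in np.asarray(tone_onsets, dtype=float):
        if not 0 <= onset < hypnogram.duration_s:
            trials.append(ToneTrial(onset, False, "ineligible", reason="onset beyond hypnogram"))
            continue
        if hypnogram.state_at(onset) != "N":
            trials.append(ToneTrial(onset, False, "ineligible", reason="not NREM at onset"))
            continue
        span = next((s for s in spans if s.start_s <= onset < s.end_s), None)
        if span is None:  # unreachable: NREM at onset implies a containing span
            trials.append(ToneTrial(onset, False, "ineligible", reason="no NREM span"))
            continue
        measured = onset - span.start_s if eligibility == "pre_onset" else span.span_s
        if not measured > min_nrem_s:
            trials.append(
                ToneTrial(onset, False, "ineligible", reason=f"NREM span {measured:g} s <= {min_nrem_s:g} s")
            )
            continue
        first = hypnogram.epoch_of(onset)
        last = min(
            int(np.ceil((onset + tone_dur_s) / hypnogram.epoch_s)) - 1, len(hypnogram) - 1
        )
        woke = np.any(hypnogram.states[first : last + 1] == "W")
        trials.append(ToneTrial(onset, True, "arousal" if woke else "sleep_through"))
    return trials


def arousal_percentage(trials: list[ToneTrial]) -> float:
    """Percentage of eligible trials ending in arousal (NaN if none)."""
    eligible = [t for t in trials if t.eligible]
    if not eligible:
        return float("nan")
    return 100.0 * sum(t.outcome == "arousal" for t in eligible) / len(eligible)


@dataclass
class PeriToneAverage:
    """Onset-aligned σ-power average for one outcome class."""

    rel_times: np.ndarray  # seconds relative to onset, <= 0
    mean: np.ndarray
    n: np.ndarray          # trials contributing per timepoint
    n_trials: int


def peri_tone_sigma(
    timecourse: SigmaTimecourse,
    trials: list[ToneTrial],
    pre_window_s: float = 60.0,
) -> dict[str, PeriToneAverage]:
    """Mean pre-tone σ trace per outcome class.

    Eligible trials are aligned to tone onset over
    ``[-pre_window_s, 0]`` on the σ series' 2.5 s grid; trials starting
    too close to the recording edge contribute NaN-padded traces, and a
    per-timepoint count is reported. Empty classes are omitted with a
    warning.
    """
    step = timecourse.times[1] - timecourse.times[0]
    n_back = int(round(pre_window_s / step))
    rel_times = step * np.arange(-n_back, 1)
    out: dict[str, PeriToneAverage] = {}
    for klass in ("arousal", "sleep_through"):
        rows = []
        for tr in trials:
            if not tr.eligible or tr.outcome != klass:
                continue
            k = int(np.floor(tr.onset_s / step))
            row = np.full(n_back + 1, np.nan)
            lo = max(0, k - n_back)
            row[n_back - (k - lo):] = timecourse.values[lo : k + 1]
            rows.append(row)
        if not rows:
            warnings.warn(f"no {klass} trials; class omitted", stacklevel=2)
            continue
        stack = np.vstack(rows)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN columns
            mean = np.nanmean(stack, axis=0)
        out[klass] = PeriToneAverage(
            rel_times=rel_times,
            mean=mean,
            n=np.sum(~np.isnan(stack), axis=0),
            n_trials=stack.shape[0],
        )
    return out


def pre_tone_slope(average: PeriToneAverage, fit_window_s: float = 20.0) -> float:
    """Least-squares slope (per second) of the mean σ trace over the last
    ``fit_window_s`` seconds before onset."""
    mask = (average.rel_times >= -fit_window_s) & ~np.isnan(average.mean)
    if mask.sum() < 2:
        return float("nan")
    return float(np.polyfit(average.rel_times[mask], average.mean[mask], 1)[0])
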