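"""Sleep architecture: bouts, microarousals, consolidated NREM, and the
spatial-object-recognition behavioural metrics.

A *bout* is a maximal run of identical states. A *microarousal* (MA) is a
wake run of at most 20 s with NREM immediately on both sides; MAs index
sleep fragmentation. A *consolidated NREM bout* is a NREM span of at
least 120 s that may contain embedded MAs — any REM epoch or wake run
longer than 20 s terminates the span.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .core import EPOCH_S, Hypnogram


@dataclass(frozen=True)
class Bout:
    """Maximal run of one state; epoch indices are inclusive."""

    state: str
    start_epoch: int
    end_epoch: int
    epoch_s: float = EPOCH_S

    @property
    def n_epochs(self) -> int:
        return self.end_epoch - self.start_epoch + 1

    @property
    def duration_s(self) -> float:
        return self.n_epochs * self.epoch_s

    @property
    def start_s(self) -> float:
        return self.start_epoch * self.epoch_s

    @property
    def end_s(self) -> float:
        """End of the last epoch (half-open)."""
        return (self.end_epoch + 1) * self.epoch_s


@dataclass(frozen=True)
class MAEvent:
    """Microarousal: wake run <= 20 s flanked by NREM on both sides."""

    start_s: float
    duration_s: float

    @property
    def end_s(self) -> float:
        return self.start_s + self.duration_s


@dataclass(frozen=True)
class ConsolidatedBout:
    """NREM span >= min duration, possibly interrupted by MAs.

    The span (end_s - start_s) includes embedded MA time.
    """

    start_s: float
    end_s: float
    ma_events: tuple = ()

    @property
    def span_s(self) -> float:
        return self.end_s - self.start_s


def detect_bouts(hypnogram: Hypnogram) -> list[Bout]:
    """Run-length partition of the hypnogram; concatenation reconstructs it."""
    states = hypnogram.states
    boundaries = np.flatnonzero(states[1:] != states[:-1]) + 1
    starts = np.concatenate([[0], boundaries])
    ends = np.concatenate([boundaries - 1, [states.size - 1]])
    return [
        Bout(state=str(states[s]), start_epoch=int(s), end_epoch=int(e),
             epoch_s=hypnogram.epoch_s)
        for s, e in zip(starts, ends)
    ]


def detect_microarousals(
    hypnogram: Hypnogram, max_dur_s: float = 20.0
) -> list[MAEvent]:
    """Wake runs of duration <= ``max_dur_s`` with NREM immediately on
    both sides. Edge- or REM-flanked wake runs are not MAs."""
    bouts = detect_bouts(hypnogram)
    events = []
    for i, b in enumerate(bouts):
        if b.state != "W" or b.duration_s > max_dur_s:
            continue
        if i == 0 or i == len(bouts) - 1:
            continue
        if bouts[i - 1].state == "N" and bouts[i + 1].state == "N":
            events.append(MAEvent(start_s=b.start_s, duration_s=b.duration_s))
    return events


def microarousal_rate_per_h(hypnogram: Hypnogram, ma_events: list[MAEvent]) -> float:
    """MA count per hour of NREM time (NaN if there is no NREM)."""
    nrem_h = np.count_nonzero(hypnogram.states == "N") * hypnogram.epoch_s / 3600.0
    return len(ma_events) / nrem_h if nrem_h > 0 else math.nan


def consolidate_nrem(
    hypnogram: Hypnogram, min_span_s: float = 120.0, ma_max_s: float = 20.0
) -> list[ConsolidatedBout]:
    """NREM runs bridged across qualifying MAs; keep spans >= ``min_span_s``.

    Any REM epoch or wake run longer than ``ma_max_s`` terminates a span.
    Returned spans are disjoint and time-ordered.
    """
    bouts = detect_bouts(hypnogram)
    out: list[ConsolidatedBout] = []
    i = 0
    while i < len(bouts):
        if bouts[i].state != "N":
            i += 1
            continue
        start = bouts[i]
        end = bouts[i]
        mas: list[MAEvent] = []
        j = i + 1
        while (
            j + 1 < len(bouts)
            and bouts[j].state == "W"
            and bouts[j].duration_s <= ma_max_s
            and bouts[j + 1].state == "N"
        ):
            mas.append(MAEvent(start_s=bouts[j].start_s, duration_s=bouts[j].duration_s))
            end = bouts[j + 1]
            j += 2
        span = ConsolidatedBout(start_s=start.start_s, end_s=end.end_s, ma_events=tuple(mas))
        if span.span_s >= min_span_s:
            out.append(span)
        i = j
    return out


def state_percentages(
    hypnogram: Hypnogram, interval: tuple[float, float] | None = None
) -> dict[str, float]:
    """Percentage of epochs per state within ``interval`` (whole recording
    by default). Epoch membership is by epoch start time."""
    starts = hypnogram.epoch_starts_s
    if interval is None:
        mask = np.ones(len(hypnogram), dtype=bool)
    else:
        lo, hi = interval
        mask = (starts >= lo) & (starts < hi)
    n = int(mask.sum())
    if n == 0:
        raise ValueError("interval contains no epochs")
    states = hypnogram.states[mask]
    return {s: 100.0 * np.count_nonzero(states == s) / n for s in ("W", "N", "R")}


def episode_stats(bouts: list[Bout], state: str, total_hours: float) -> dict[str, float]:
    """Mean bout duration (s) and bout frequency (per hour of recording)."""
    if not total_hours > 0:
        raise ValueError("total_hours must be positive")
    durations = [b.duration_s for b in bouts if b.state == state]
    return {
        "mean_duration_s": float(np.mean(durations)) if durations else math.nan,
        "frequency_per_h": len(durations) / total_hours,
    }


def bout_duration_distribution(
    bouts: list[Bout], state: str, bin_edges_s
) -> np.ndarray:
    """Fraction of the state's bouts per duration bin (half-open bins,
    ``np.inf`` allowed as last edge). All-zero vector if no bouts."""
    edges = np.asarray(bin_edges_s, dtype=float)
    if np.any(np.diff(edges) <= 0):
        raise ValueError("bin edges must be strictly increasing")
    durations = np.array([b.duration_s for b in bouts if b.state == state])
    counts = np.histogram(durations, bins=edges)[0].astype(float) if durations.size else np.zeros(edges.size - 1)
    total = durations.size
    return counts / total if total else counts


@dataclass(frozen=True)
class SORResult:
    """Spatial-object-recognition metrics for one session."""

    preference_pct: float
    discrimination_ratio: float
    excluded: bool


def sor_metrics(
    t_novel_s: float, t_familiar_s: float, min_exploration_s: float = 2.0
) -> SORResult:
    """Novel-location preference and discrimination ratio.

    preference % = T_novel / (T_familiar + T_novel) × 100;
    discrimination = (T_novel − T_familiar) / (T_familiar + T_novel).
    Sessions with total exploration below ``min_exploration_s`` are
    flagged excluded; zero total exploration leaves both metrics NaN.
    """
    if t_novel_s < 0 or t_familiar_s < 0:
        raise ValueError("exploration times must be non-negative")
    total = t_novel_s + t_familiar_s
    excluded = total < min_exploration_s
    if total == 0:
        return SORResult(math.nan, math.nan, True)
    return SORResult(
        preference_pct=100.0 * t_novel_s / total,
        discrimination_ratio=(t_novel_s - t_familiar_s) / total,
        excluded=excluded,
    )
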