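"""Core containers shared across the pipeline.

Conventions used throughout the package:

* all timestamps are seconds from recording start, 0-based;
* the hypnogram epoch length is 2.5 s and epoch *i* is the half-open
  interval ``[2.5 i, 2.5 (i + 1))``;
* EEG/EMG signals are in microvolts (µV).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Epoch length of the sleep scoring grid (seconds).
EPOCH_S = 2.5

#: Valid sleep-state tokens: Wake, NREM, REM, Undefined.
STATES = ("W", "N", "R", "U")

#: Event kinds an :class:`EventTable` may hold.
EVENT_KINDS = ("tone", "laser", "MA", "transient", "spindle_start", "spindle_end", "spindle")

#: Minimum recording length accepted by the pipeline: one staging window.
MIN_RECORDING_S = 5.0


@dataclass
class Recording:
    """A dual-channel EEG/EMG recording.

    Parameters
    ----------
    eeg, emg
        Signals in µV, equal length.
    fs
        Sampling rate in Hz.
    start_time
        Offset of the first sample in seconds (shared t=0 across systems
        is the caller's responsibility).
    subject_id
        Opaque identifier carried through to outputs.
    """

    eeg: np.ndarray
    emg: np.ndarray
    fs: float
    start_time: float = 0.0
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.eeg = np.asarray(self.eeg, dtype=float)
        self.emg = np.asarray(self.emg, dtype=float)
        if self.eeg.ndim != 1 or self.emg.ndim != 1:
            raise ValueError("eeg and emg must be 1-D arrays")
        if self.eeg.size != self.emg.size:
            raise ValueError(
                f"eeg and emg must have equal length (got {self.eeg.size} and {self.emg.size})"
            )
        if not self.fs > 0:
            raise ValueError(f"sampling rate must be positive (got {self.fs})")
        if self.duration_s < MIN_RECORDING_S:
            raise ValueError(
                f"recording of {self.duration_s:g} s is shorter than one "
                f"staging window ({MIN_RECORDING_S:g} s)"
            )

    @property
    def duration_s(self) -> float:
        return self.eeg.size / self.fs

    @property
    def n_samples(self) -> int:
        return self.eeg.size


@dataclass
class Hypnogram:
    """Per-epoch sleep-state labels on the 2.5 s scoring grid."""

    states: np.ndarray
    epoch_s: float = EPOCH_S
    start_s: float = 0.0

    def __post_init__(self) -> None:
        self.states = np.asarray(self.states, dtype="<U1")
        if self.states.size == 0:
            raise ValueError("hypnogram must contain at least one epoch")
        bad = set(np.unique(self.states)) - set(STATES)
        if bad:
            raise ValueError(f"unknown state token(s): {sorted(bad)}")

    def __len__(self) -> int:
        return int(self.states.size)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Hypnogram):
            return NotImplemented
        return (
            np.array_equal(self.states, other.states)
            and self.epoch_s == other.epoch_s
            and self.start_s == other.start_s
        )

    @property
    def duration_s(self) -> float:
        return len(self) * self.epoch_s

    @property
    def epoch_starts_s(self) -> np.ndarray:
        return self.start_s + self.epoch_s * np.arange(len(self))

    def epoch_of(self, time_s: float) -> int:
        """Index of the epoch whose half-open interval contains ``time_s``."""
        i = int(np.floor((time_s - self.start_s) / self.epoch_s))
        if not 0 <= i < len(self):
            raise IndexError(f"time {time_s:g} s is outside the hypnogram")
        return i

    def state_at(self, time_s: float) -> str:
        return str(self.states[self.epoch_of(time_s)])


#: Required leading columns of an event table, in stable order.
EVENT_COLUMNS = ["time_s", "kind", "duration_s"]


def make_event_table(rows=None, **columns) -> pd.DataFrame:
    """Build a validated event table.

    An event table is a DataFrame with leading columns ``time_s`` (s,
    non-negative, sorted ascending), ``kind`` and ``duration_s`` (s, >= 0);
    any further columns are free-form attributes.
    """
    if rows is not None:
        df = pd.DataFrame(rows, columns=EVENT_COLUMNS + [c for c in columns])
    else:
        df = pd.DataFrame(columns)
    for col in EVENT_COLUMNS:
        if col not in df.columns:
            if df.empty:
                df[col] = pd.Series(dtype=float if col != "kind" else object)
            else:
                raise ValueError(f"event table is missing required column {col!r}")
    extras = [c for c in df.columns if c not in EVENT_COLUMNS]
    df = df[EVENT_COLUMNS + extras].reset_index(drop=True)
    validate_event_table(df)
    return df


def validate_event_table(df: pd.DataFrame) -> None:
    """Raise ``ValueError`` if ``df`` violates the event-table invariants."""
    for col in EVENT_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"event table is missing required column {col!r}")
    if df.empty:
        return
    t = df["time_s"].to_numpy(dtype=float)
    if np.any(t < 0):
        raise ValueError("event times must be non-negative")
    if np.any(np.diff(t) < 0):
        raise ValueError("event times must be sorted ascending; sort before writing")
    d = df["duration_s"].to_numpy(dtype=float)
    if np.any(d < 0):
        raise ValueError("event durations must be >= 0")
    bad = set(df["kind"].astype(str)) - set(EVENT_KINDS)
    if bad:
        raise ValueError(f"unknown event kind(s): {sorted(bad)}")
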