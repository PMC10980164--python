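"""Readers and writers for the formats the pipeline touches.

Supported inputs:

* EDF recordings (channel selection by label, physical units preserved);
* raw binary signal files with a JSON sidecar declaring
  ``{fs, channels, dtype, units}``;
* hypnogram CSV (2.5 s epochs) and event CSV/JSON, both round-trip safe;
* YAML configuration files with one section per pipeline stage.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .core import EPOCH_S, EVENT_COLUMNS, Hypnogram, Recording, STATES, validate_event_table

logger = logging.getLogger(__name__)


class FormatError(ValueError):
    """File exists but its header/sidecar is not self-consistent."""


class MissingChannelError(ValueError):
    """A requested channel label is absent from the file."""


class HypnogramParseError(ValueError):
    """Hypnogram CSV contains an invalid row; carries the 1-based line number."""

    def __init__(self, message: str, line: int):
        super().__init__(f"{message} (line {line})")
        self.line = line


# ---------------------------------------------------------------------------
# recordings
# ---------------------------------------------------------------------------

def _pick_channel(available: list[str], requested: str | None, prefix: str) -> str:
    if requested is not None:
        if requested not in available:
            raise MissingChannelError(
                f"channel {requested!r} not found; available channels: {available}"
            )
        return requested
    for name in available:
        if name.upper().startswith(prefix):
            return name
    raise MissingChannelError(
        f"no channel labelled with prefix {prefix!r}; available channels: {available}"
    )


def read_recording(
    path: str | Path,
    format: str = "edf",
    eeg_channel: str | None = None,
    emg_channel: str | None = None,
    subject_id: str | None = None,
) -> Recording:
    """Read a dual-channel EEG/EMG recording.

    Parameters
    ----------
    path
        EDF file, or raw binary file with a ``<path>.json`` sidecar when
        ``format="raw"``.
    format
        ``"edf"`` or ``"raw"``.
    eeg_channel, emg_channel
        Channel labels; when omitted the first channel whose label starts
        with ``EEG`` / ``EMG`` (case-insensitive) is used.

    Returns
    -------
    Recording
        Signals in µV, sampling rate from the header.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "edf":
        return _read_edf(path, eeg_channel, emg_channel, subject_id)
    if format == "raw":
        return _read_raw_binary(path, eeg_channel, emg_channel, subject_id)
    raise ValueError(f"unknown format {format!r}; expected 'edf' or 'raw'")


def _read_edf(path, eeg_channel, emg_channel, subject_id) -> Recording:
    import mne

    try:
        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    except Exception as exc:  # unreadable header
        raise FormatError(f"cannot read EDF header of {path}: {exc}") from exc
    names = list(raw.ch_names)
    eeg_name = _pick_channel(names, eeg_channel, "EEG")
    emg_name = _pick_channel(names, emg_channel, "EMG")

    def _uv(name: str) -> np.ndarray:
        picks = [raw.ch_names.index(name)]
        try:
            # channels with a voltage unit come back scaled to µV
            return raw.get_data(picks=picks, units="uV")[0]
        except ValueError:
            # dimensionless/misc channel: take values as stored (assumed µV)
            return raw.get_data(picks=picks)[0]

    logger.info("EDF %s: using EEG=%r EMG=%r fs=%g", path.name, eeg_name, emg_name, raw.info["sfreq"])
    return Recording(
        eeg=_uv(eeg_name),
        emg=_uv(emg_name),
        fs=float(raw.info["sfreq"]),
        subject_id=subject_id or path.stem,
    )


def _read_raw_binary(path, eeg_channel, emg_channel, subject_id) -> Recording:
    sidecar = path.with_suffix(path.suffix + ".json")
    if not sidecar.exists():
        raise FormatError(f"raw binary {path} requires a JSON sidecar at {sidecar}")
    meta = json.loads(sidecar.read_text())
    for key in ("fs", "channels", "dtype", "units"):
        if key not in meta:
            raise FormatError(f"sidecar {sidecar} is missing required key {key!r}")
    channels = list(meta["channels"])
    data = np.fromfile(path, dtype=np.dtype(meta["dtype"]))
    if data.size % len(channels):
        raise FormatError(
            f"{path}: {data.size} samples is not a multiple of {len(channels)} channels"
        )
    data = data.reshape(-1, len(channels)).astype(float)
    if meta["units"] == "uV":
        scale = 1.0
    elif meta["units"] == "V":
        scale = 1e6
    else:
        raise FormatError(f"unsupported units {meta['units']!r}; expected 'uV' or 'V'")
    eeg_name = _pick_channel(channels, eeg_channel, "EEG")
    emg_name = _pick_channel(channels, emg_channel, "EMG")
    return Recording(
        eeg=data[:, channels.index(eeg_name)] * scale,
        emg=data[:, channels.index(emg_name)] * scale,
        fs=float(meta["fs"]),
        subject_id=subject_id or path.stem,
    )


def write_raw_binary(path: str | Path, recording: Recording, dtype: str = "<f4") -> None:
    """Write a Recording as interleaved raw binary plus JSON sidecar."""
    path = Path(path)
    data = np.stack([recording.eeg, recording.emg], axis=1).astype(np.dtype(dtype))
    data.tofile(path)
    sidecar = {
        "fs": recording.fs,
        "channels": ["EEG1", "EMG1"],
        "dtype": dtype,
        "units": "uV",
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=1))


# ---------------------------------------------------------------------------
# hypnograms
# ---------------------------------------------------------------------------

def write_hypnogram(hypnogram: Hypnogram, path: str | Path) -> None:
    """Write a hypnogram as CSV.

    First line declares the epoch grid (``# epoch_s=2.5 start_s=0``),
    followed by a header row and one row per epoch with columns
    ``epoch_index,start_s,state``.
    """
    if len(hypnogram) == 0:  # unreachable through the constructor, kept explicit
        raise ValueError("refusing to write an empty hypnogram")
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# epoch_s={hypnogram.epoch_s:g} start_s={hypnogram.start_s:g}\n")
        fh.write("epoch_index,start_s,state\n")
        for i, (t, s) in enumerate(zip(hypnogram.epoch_starts_s, hypnogram.states)):
            fh.write(f"{i},{t:g},{s}\n")


def read_hypnogram(path: str | Path) -> Hypnogram:
    """Read a hypnogram CSV written by :func:`write_hypnogram`."""
    path = Path(path)
    lines = path.read_text().splitlines()
    if not lines or not lines[0].startswith("#"):
        raise HypnogramParseError("missing '# epoch_s=...' declaration", line=1)
    header = dict(item.split("=", 1) for item in lines[0].lstrip("# ").split())
    epoch_s = float(header.get("epoch_s", EPOCH_S))
    start_s = float(header.get("start_s", 0.0))
    states = []
    for lineno, line in enumerate(lines[2:], start=3):
        if not line.strip():
            continue
        parts = line.split(",")
        if len(parts) != 3:
            raise HypnogramParseError(f"expected 3 columns, got {len(parts)}", line=lineno)
        state = parts[2].strip()
        if state not in STATES:
            raise HypnogramParseError(f"unknown state token {state!r}", line=lineno)
        states.append(state)
    if not states:
        raise HypnogramParseError("hypnogram file contains no epochs", line=len(lines))
    return Hypnogram(states=np.array(states), epoch_s=epoch_s, start_s=start_s)


# ---------------------------------------------------------------------------
# event tables
# ---------------------------------------------------------------------------

def write_events(events: pd.DataFrame, path: str | Path) -> None:
    """Write an event table as CSV (or JSON if the suffix is ``.json``).

    Column order is stable: ``time_s, kind, duration_s`` then the remaining
    attribute columns in their existing order. Unsorted times are refused.
    """
    validate_event_table(events)
    path = Path(path)
    extras = [c for c in events.columns if c not in EVENT_COLUMNS]
    out = events[EVENT_COLUMNS + extras]
    if path.suffix == ".json":
        out.to_json(path, orient="records", indent=1)
    else:
        out.to_csv(path, index=False)


def read_events(path: str | Path) -> pd.DataFrame:
    """Read an event table written by :func:`write_events`."""
    path = Path(path)
    if path.suffix == ".json":
        df = pd.read_json(path, orient="records")
        if df.empty:
            df = pd.DataFrame({c: pd.Series(dtype=float if c != "kind" else object)
                               for c in EVENT_COLUMNS})
    else:
        df = pd.read_csv(path)
    validate_event_table(df)
    return df


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

def load_config(path: str | Path) -> dict:
    """Load a YAML configuration file.

    The file holds one mapping per pipeline stage (``spectral``, ``staging``,
    ``architecture``, ``infraslow``, ``spindles``, ``photometry``,
    ``arousal``, ``simulate``); each stage's keys are passed through as
    keyword arguments to that stage's entry points.
    """
    with Path(path).open() as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise FormatError(f"config {path} must be a mapping of sections")
    return cfg
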