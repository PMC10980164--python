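"""Shared fixtures: a minimal EDF fixture writer and small synthetic studies."""

from __future__ import annotations

import numpy as np
import pytest

from murisleep import SimConfig, simulate_study


def write_minimal_edf(path, channels, fs, data_uv, record_s=1):
    """Write a minimal, valid EDF file for fixtures (16-bit, 1 µV/LSB).

    Synthetic test fixture only — the package itself reads EDF through mne.
    """
    n_ch = len(channels)
    n_rec = data_uv.shape[1] // (fs * record_s)

    def f(s, width):
        return str(s)[:width].ljust(width).encode()

    hdr = b"".join(
        [
            f(0, 8),
            f("X X X X", 80),
            f("Startdate X X X X", 80),
            f("01.01.20", 8),
            f("00.00.00", 8),
            f(256 * (1 + n_ch), 8),
            f("", 44),
            f(n_rec, 8),
            f(record_s, 8),
            f(n_ch, 4),
            b"".join(f(c, 16) for c in channels),
            b"".join(f("", 80) for _ in channels),
            b"".join(f("uV", 8) for _ in channels),
            b"".join(f(-32768.0, 8) for _ in channels),
            b"".join(f(32767.0, 8) for _ in channels),
            b"".join(f(-32768, 8) for _ in channels),
            b"".join(f(32767, 8) for _ in channels),
            b"".join(f("", 80) for _ in channels),
            b"".join(f(fs * record_s, 8) for _ in channels),
            b"".join(f("", 32) for _ in channels),
        ]
    )
    spr = fs * record_s
    with open(path, "wb") as fh:
        fh.write(hdr)
        for r in range(n_rec):
            for c in range(n_ch):
                seg = data_uv[c, r * spr : (r + 1) * spr]
                fh.write(np.round(seg).astype("<i2").tobytes())


@pytest.fixture(scope="session")
def short_study():
    """One 600 s synthetic session with full ground truth (shared, read-only)."""
    return simulate_study(SimConfig(duration_s=600.0, seed=11), rng=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
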