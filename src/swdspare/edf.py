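"""Minimal European Data Format (EDF) writer.

Writes plain continuous EDF: one data record per second, 16-bit samples,
per-channel symmetric physical range. The complementary read path goes
through :func:`mne.io.read_raw_edf` (see :mod:`swdspare.io`); keeping the
writer independent of the reader makes round-trip tests meaningful.
"""

from __future__ import annotations

import math
from pathlib import Path

import numpy as np

_DIG_MIN = -32768
_DIG_MAX = 32767


def _field(value: str, width: int) -> bytes:
    s = str(value)
    if len(s) > width:
        raise ValueError(f"EDF header field too long: {s!r} (> {width})")
    return s.ljust(width).encode("ascii")


def write_edf(
    path: str | Path,
    samples: np.ndarray,
    rate_hz: float,
    channel_names: list[str],
    patient_id: str = "X",
    physical_max: float | None = None,
) -> None:
    """Write ``samples`` (channels x time, µV) to ``path`` as 16-bit EDF.

    The sampling rate must be an integer (one data record per second). A
    trailing partial second is zero-padded. ``physical_max`` fixes a symmetric
    physical range for all channels; by default each channel gets its own
    range snug around its extremes, which minimizes quantization error.
    """
    samples = np.asarray(samples, dtype=float)
    if samples.ndim != 2:
        raise ValueError("samples must be channels x time")
    n_ch, n_samp = samples.shape
    if len(channel_names) != n_ch:
        raise ValueError("channel_names length mismatch")
    if rate_hz <= 0 or abs(rate_hz - round(rate_hz)) > 1e-9:
        raise ValueError("EDF writer requires a positive integer sampling rate")
    rate = int(round(rate_hz))
    n_records = max(1, math.ceil(n_samp / rate))
    padded = np.zeros((n_ch, n_records * rate))
    padded[:, :n_samp] = samples

    phys_max = np.empty(n_ch)
    for i in range(n_ch):
        if physical_max is not None:
            pm = float(physical_max)
        else:
            pm = float(np.max(np.abs(padded[i]))) * (1 + 1e-6)
            if pm == 0:
                pm = 1.0
        # header carries at most 8 ascii chars; scale with the value the
        # reader will parse, not the full-precision float
        phys_max[i] = float(f"{pm:.5g}"[:8])
    digital = np.empty_like(padded, dtype="<i2")
    span = _DIG_MAX - _DIG_MIN
    for i in range(n_ch):
        # exact inverse of the EDF affine map [pmin, pmax] <-> [dmin, dmax]
        scaled = np.round((padded[i] + phys_max[i]) / (2 * phys_max[i]) * span + _DIG_MIN)
        digital[i] = np.clip(scaled, _DIG_MIN, _DIG_MAX).astype("<i2")

    header_bytes = 256 * (1 + n_ch)
    with open(Path(path), "wb") as fh:
        fh.write(_field("0", 8))
        fh.write(_field(patient_id, 80))
        fh.write(_field("Startdate 01-JAN-2001 synthetic", 80))
        fh.write(_field("01.01.01", 8))
        fh.write(_field("00.00.00", 8))
        fh.write(_field(str(header_bytes), 8))
        fh.write(_field("", 44))
        fh.write(_field(str(n_records), 8))
        fh.write(_field("1", 8))
        fh.write(_field(str(n_ch), 4))
        for name in channel_names:
            fh.write(_field(name, 16))
        for _ in range(n_ch):
            fh.write(_field("AgAgCl electrode", 80))
        for _ in range(n_ch):
            fh.write(_field("uV", 8))
        for i in range(n_ch):
            fh.write(_field(f"{-phys_max[i]:.5g}"[:8], 8))
        for i in range(n_ch):
            fh.write(_field(f"{phys_max[i]:.5g}"[:8], 8))
        for _ in range(n_ch):
            fh.write(_field(str(_DIG_MIN), 8))
        for _ in range(n_ch):
            fh.write(_field(str(_DIG_MAX), 8))
        for _ in range(n_ch):
            fh.write(_field("", 80))
        for _ in range(n_ch):
            fh.write(_field(str(rate), 8))
        for _ in range(n_ch):
            fh.write(_field("", 32))
        for rec in range(n_records):
            sl = slice(rec * rate, (rec + 1) * rate)
            fh.write(digital[:, sl].tobytes())


def quantization_step(physical_max: float) -> float:
    """Worst-case amplitude error of the 16-bit encoding for a given range."""
    return 2 * physical_max / (_DIG_MAX - _DIG_MIN)
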