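"""Minimal European Data Format (EDF) reader/writer.

Implements just enough of the EDF standard (fixed-width ASCII header,
16-bit little-endian samples with linear physical/digital scaling) to
round-trip multichannel EEG records; written in-repo because no EDF
library is available in the target environment.  The whole record is
stored as a single data record, so the round-trip is exact up to the
16-bit quantization step.  Seizure annotations are *not* part of plain
EDF; they travel in a TSV sidecar (see :func:`eegsmote.pipeline.read_annotations`).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .preprocessing import EEGRecord

__all__ = ["read_edf", "write_edf"]

_DIG_MIN, _DIG_MAX = -32768, 32767


def _field(value, width: int) -> bytes:
    s = str(value)
    if len(s) > width:
        s = s[:width]
    return s.ljust(width).encode("ascii")


def write_edf(record: EEGRecord, path: str | Path) -> None:
    """Write the record's signals as one EDF data record.

    Per channel, physical min/max are the data extremes, mapped linearly
    onto the 16-bit digital range; quantization error is at most one
    digital step.  Seizure intervals are not stored (use a TSV sidecar).
    """
    ns = record.n_channels
    n = record.n_samples
    header_bytes = 256 + 256 * ns
    phys_min = record.data.min(axis=1)
    phys_max = record.data.max(axis=1)
    # degenerate (constant) channels need a nonzero physical span
    flat = phys_max - phys_min <= 0
    phys_max = np.where(flat, phys_min + 1.0, phys_max)

    with open(path, "wb") as fh:
        fh.write(_field("0", 8))
        fh.write(_field("X", 80))                       # patient id
        fh.write(_field("X", 80))                       # recording id
        fh.write(_field("01.01.00", 8))
        fh.write(_field("00.00.00", 8))
        fh.write(_field(header_bytes, 8))
        fh.write(_field("", 44))
        fh.write(_field(1, 8))                          # one data record
        fh.write(_field(f"{n / record.fs:.6g}", 8))     # its duration (s)
        fh.write(_field(ns, 4))
        for name in record.channel_names:
            fh.write(_field(name, 16))
        for _ in range(ns):
            fh.write(_field("", 80))                    # transducer
        for _ in range(ns):
            fh.write(_field("uV", 8))
        for v in phys_min:
            fh.write(_field(f"{v:.8g}"[:8], 8))
        for v in phys_max:
            fh.write(_field(f"{v:.8g}"[:8], 8))
        for _ in range(ns):
            fh.write(_field(_DIG_MIN, 8))
        for _ in range(ns):
            fh.write(_field(_DIG_MAX, 8))
        for _ in range(ns):
            fh.write(_field("", 80))                    # prefilter
        for _ in range(ns):
            fh.write(_field(n, 8))                      # samples / record
        for _ in range(ns):
            fh.write(_field("", 32))

        # re-read the header's truncated physical extremes so the scaling
        # used for the samples matches what a reader will reconstruct
        pmin = np.array([float(f"{v:.8g}"[:8]) for v in phys_min])
        pmax = np.array([float(f"{v:.8g}"[:8]) for v in phys_max])
        pmax = np.where(pmax - pmin <= 0, pmin + 1.0, pmax)
        gain = (_DIG_MAX - _DIG_MIN) / (pmax - pmin)
        dig = np.rint((record.data - pmin[:, None]) * gain[:, None]
                      + _DIG_MIN)
        dig = np.clip(dig, _DIG_MIN, _DIG_MAX).astype("<i2")
        fh.write(dig.tobytes())        # one record: signals sequentially


def read_edf(path: str | Path,
             seizure_intervals: list[tuple[float, float]] | None = None,
             ) -> EEGRecord:
    """Read an EDF file written with one or more data records."""
    with open(path, "rb") as fh:
        hdr = fh.read(256)
        if len(hdr) < 256:
            raise ValueError("truncated EDF header")
        n_records = int(hdr[236:244].decode("ascii"))
        rec_dur = float(hdr[244:252].decode("ascii"))
        ns = int(hdr[252:256].decode("ascii"))
        sig_hdr = fh.read(256 * ns)

        def fields(offset: int, width: int) -> list[str]:
            start = offset * ns
            return [sig_hdr[start + i * width:start + (i + 1) * width]
                    .decode("ascii").strip() for i in range(ns)]

        labels = fields(0, 16)
        pmin = np.array([float(v) for v in fields(104, 8)])
        pmax = np.array([float(v) for v in fields(112, 8)])
        dmin = np.array([float(v) for v in fields(120, 8)])
        dmax = np.array([float(v) for v in fields(128, 8)])
        spr = [int(v) for v in fields(216, 8)]
        if len(set(spr)) != 1:
            raise ValueError("heterogeneous sampling rates not supported")
        spr = spr[0]
        fs = spr / rec_dur
        raw = np.frombuffer(fh.read(2 * spr * ns * n_records), dtype="<i2")

    data = np.empty((ns, spr * n_records))
    raw = raw.reshape(n_records, ns, spr)
    for c in range(ns):
        gain = (pmax[c] - pmin[c]) / (dmax[c] - dmin[c])
        data[c] = (raw[:, c, :].reshape(-1) - dmin[c]) * gain + pmin[c]
    return EEGRecord(data=data, fs=fs, channel_names=labels,
                     seizure_intervals=seizure_intervals or [])
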