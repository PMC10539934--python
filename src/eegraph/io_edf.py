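"""Minimal EDF (European Data Format) reader/writer.

Supports plain continuous EDF with a fixed sampling rate per signal — enough
to round-trip synthetic cohorts and to ingest standard clinical exports.  No
EDF+ annotations.  Implemented here because no EDF library is available in
the runtime environment.
"""

from __future__ import annotations

import datetime as _dt

import numpy as np

from .montage import CHANNELS
from .preprocess import Recording

__all__ = ["write_edf", "read_edf"]

_DIGITAL_MIN, _DIGITAL_MAX = -32768, 32767


def _field(value: str, width: int) -> bytes:
    s = str(value)[:width]
    return s.ljust(width).encode("ascii")


def write_edf(rec: Recording, path) -> None:
    """Write a recording as 16-bit EDF, one 1-second data record per second.

    The sampling rate must be an integer; the trailing partial second is
    dropped.  Per-channel physical scaling is chosen from the data range, so
    the quantization error is at most ``range / 65535``.
    """
    fs = rec.fs
    if fs != int(fs):
        raise ValueError("EDF writer requires an integer sampling rate")
    fs = int(fs)
    n_records = rec.n_samples // fs
    if n_records < 1:
        raise ValueError("recording shorter than one 1-s data record")
    n_ch = len(rec.channels)
    data = rec.data[:, : n_records * fs]

    phys_min = np.floor(data.min(axis=1))
    phys_max = np.ceil(data.max(axis=1))
    flat = phys_max <= phys_min
    phys_max[flat] = phys_min[flat] + 1.0

    now = _dt.datetime(2000, 1, 1)
    header = b"".join([
        _field("0", 8),
        _field(rec.subject_id or "X", 80),
        _field(f"Startdate 01-JAN-2000 {rec.group or 'X'}", 80),
        _field(now.strftime("%d.%m.%y"), 8),
        _field(now.strftime("%H.%M.%S"), 8),
        _field(str(256 * (1 + n_ch)), 8),
        _field("", 44),
        _field(str(n_records), 8),
        _field("1", 8),
        _field(str(n_ch), 4),
    ])
    header += b"".join(_field(c, 16) for c in rec.channels)
    header += b"".join(_field("", 80) for _ in range(n_ch))
    header += b"".join(_field("uV", 8) for _ in range(n_ch))
    header += b"".join(_field(f"{m:g}", 8) for m in phys_min)
    header += b"".join(_field(f"{m:g}", 8) for m in phys_max)
    header += b"".join(_field(str(_DIGITAL_MIN), 8) for _ in range(n_ch))
    header += b"".join(_field(str(_DIGITAL_MAX), 8) for _ in range(n_ch))
    header += b"".join(_field("", 80) for _ in range(n_ch))
    header += b"".join(_field(str(fs), 8) for _ in range(n_ch))
    header += b"".join(_field("", 32) for _ in range(n_ch))

    scale = (phys_max - phys_min) / (_DIGITAL_MAX - _DIGITAL_MIN)
    digital = np.rint(
        (data - phys_min[:, None]) / scale[:, None] + _DIGITAL_MIN
    ).astype("<i2")

    with open(path, "wb") as fh:
        fh.write(header)
        # records: for each second, all channels sequentially
        chunks = digital.reshape(n_ch, n_records, fs).transpose(1, 0, 2)
        fh.write(np.ascontiguousarray(chunks).tobytes())


def read_edf(path, subject_id: str = "", group: str = "") -> Recording:
    """Read an EDF file into a :class:`Recording`.

    Channel labels are matched to the 19-channel montage case-insensitively;
    signals outside the montage (e.g. ear references A1/A2, annotations) are
    ignored.  All kept signals must share one sampling rate.
    """
    with open(path, "rb") as fh:
        head = fh.read(256)
        n_bytes_header = int(head[184:192])
        n_records = int(head[236:244])
        record_dur = float(head[244:252])
        n_sig = int(head[252:256])
        sig_head = fh.read(n_bytes_header - 256)
        raw = np.frombuffer(fh.read(), dtype="<i2")

    def col(offset: int, width: int) -> list[str]:
        start = offset * n_sig
        return [
            sig_head[start + i * width : start + (i + 1) * width].decode("ascii").strip()
            for i in range(n_sig)
        ]

    labels = col(0, 16)
    # field offsets within the per-signal header block, in bytes per signal
    off = 16 * n_sig
    def fcol(width: int) -> list[str]:
        nonlocal off
        start = off
        off += width * n_sig
        return [
            sig_head[start + i * width : start + (i + 1) * width].decode("ascii").strip()
            for i in range(n_sig)
        ]

    _transducer = fcol(80)
    _dim = fcol(8)
    phys_min = np.array([float(v) for v in fcol(8)])
    phys_max = np.array([float(v) for v in fcol(8)])
    dig_min = np.array([float(v) for v in fcol(8)])
    dig_max = np.array([float(v) for v in fcol(8)])
    _prefilter = fcol(80)
    n_per_rec = np.array([int(v) for v in fcol(8)])

    montage = {c.lower(): c for c in CHANNELS}
    keep = [i for i, lab in enumerate(labels) if lab.lower() in montage]
    if not keep:
        raise ValueError("no montage channels found in EDF file")
    fs_set = {n_per_rec[i] / record_dur for i in keep}
    if len(fs_set) != 1:
        raise ValueError("montage channels have mixed sampling rates")
    fs = fs_set.pop()

    rec_len = int(n_per_rec.sum())
    raw = raw[: n_records * rec_len].reshape(n_records, rec_len)
    starts = np.concatenate([[0], np.cumsum(n_per_rec)])
    data = np.empty((len(keep), int(n_records * n_per_rec[keep[0]])))
    for row, i in enumerate(keep):
        dig = raw[:, starts[i] : starts[i + 1]].ravel().astype(float)
        gain = (phys_max[i] - phys_min[i]) / (dig_max[i] - dig_min[i])
        data[row] = (dig - dig_min[i]) * gain + phys_min[i]
    channels = tuple(montage[labels[i].lower()] for i in keep)
    return Recording(channels, fs, data, subject_id=subject_id, group=group)
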