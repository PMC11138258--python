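"""Minimal reader/writer for 16-bit European Data Format (EDF) recordings.

Only the plain-EDF subset this package produces and consumes is supported:
a uniform sampling rate across all signals, one-second data records, and
microvolt physical units. Subject and session identifiers travel in the
standard patient / recording header fields, and the session timestamp in
the startdate/starttime fields.

The reader refuses files whose signals disagree on sampling rate
(:class:`UnsupportedInputError`) and malformed headers
(:class:`FormatError`). Round-tripping a matrix through
:func:`write_edf` / :func:`read_edf` is exact up to the 16-bit digital
quantisation of the physical range.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from datetime import datetime
from pathlib import Path

import numpy as np

from ._exceptions import FormatError, UnsupportedInputError, ValidationError

__all__ = ["Recording", "read_edf", "write_edf"]

_HDR = 256  # bytes in the fixed part of an EDF header
_DIG_MAX = 32767
_DIG_MIN = -32768


@dataclass
class Recording:
    """One subject-session multichannel EEG time series.

    data is channels x samples in microvolts; fs in Hz.
    """

    data: np.ndarray
    fs: float
    channel_labels: tuple[str, ...]
    subject_id: str = "S"
    session_id: str = "ses"
    session_datetime: datetime = field(default_factory=lambda: datetime(2000, 1, 1))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValidationError("data must be 2-D (channels x samples)")
        if self.fs <= 0:
            raise ValidationError("sampling rate must be positive")
        self.channel_labels = tuple(str(l) for l in self.channel_labels)
        if len(self.channel_labels) != self.data.shape[0]:
            raise ValidationError(
                f"{len(self.channel_labels)} labels for {self.data.shape[0]} channels"
            )

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    def copy_with(self, **kw) -> "Recording":
        if "data" in kw:
            kw["data"] = np.array(kw["data"], dtype=float)
        return replace(self, **kw)


def _ascii(value: str, width: int) -> bytes:
    s = value[:width].ljust(width)
    b = s.encode("ascii", errors="replace")
    return b


def write_edf(rec: Recording, path: str | Path) -> Path:
    """Write a Recording as plain 16-bit EDF with one-second data records.

    The recording must contain a whole number of seconds; the physical
    range per channel is the symmetric range covering the data (minimum
    +/-1 uV so that all-zero channels stay representable).
    """
    if not np.all(np.isfinite(rec.data)):
        raise ValidationError("cannot write non-finite samples to EDF")
    fs = rec.fs
    if abs(fs - round(fs)) > 1e-9:
        raise ValidationError("EDF writer requires an integer sampling rate")
    fs = int(round(fs))
    n_ch, n_samp = rec.data.shape
    if n_samp % fs != 0:
        raise ValidationError(
            "EDF writer requires a whole number of seconds "
            f"({n_samp} samples at {fs} Hz)"
        )
    n_records = n_samp // fs

    # symmetric physical range per channel, padded 1% against rounding
    absmax = np.abs(rec.data).max(axis=1)
    phys = np.maximum(absmax * 1.01, 1.0)
    if np.any(phys > 99_999_999):
        raise ValidationError("physical range does not fit EDF header fields")

    dt = rec.session_datetime
    header = b"".join(
        [
            _ascii("0", 8),
            _ascii(rec.subject_id, 80),
            _ascii(rec.session_id, 80),
            _ascii(dt.strftime("%d.%m.%y"), 8),
            _ascii(dt.strftime("%H.%M.%S"), 8),
            _ascii(str(_HDR * (1 + n_ch)), 8),
            _ascii("", 44),
            _ascii(str(n_records), 8),
            _ascii("1", 8),
            _ascii(str(n_ch), 4),
        ]
    )
    per_signal = [
        b"".join(_ascii(lbl, 16) for lbl in rec.channel_labels),
        b"".join(_ascii("EEG", 80) for _ in range(n_ch)),
        b"".join(_ascii("uV", 8) for _ in range(n_ch)),
        b"".join(_ascii(f"{-p:.8g}"[:8], 8) for p in phys),
        b"".join(_ascii(f"{p:.8g}"[:8], 8) for p in phys),
        b"".join(_ascii(str(_DIG_MIN), 8) for _ in range(n_ch)),
        b"".join(_ascii(str(_DIG_MAX), 8) for _ in range(n_ch)),
        b"".join(_ascii("", 80) for _ in range(n_ch)),
        b"".join(_ascii(str(fs), 8) for _ in range(n_ch)),
        b"".join(_ascii("", 32) for _ in range(n_ch)),
    ]

    # physical -> digital with the same affine map the reader inverts:
    # digital = (phys_value - phys_min)/gain + dig_min
    gain = (phys * 2) / (_DIG_MAX - _DIG_MIN)
    digital = np.rint((rec.data + phys[:, None]) / gain[:, None]) + _DIG_MIN
    digital = np.clip(digital, _DIG_MIN, _DIG_MAX).astype("<i2")

    path = Path(path)
    with open(path, "wb") as fh:
        fh.write(header)
        for blk in per_signal:
            fh.write(blk)
        # record-major interleaving: for each second, all channels in order
        view = digital.reshape(n_ch, n_records, fs)
        for r in range(n_records):
            fh.write(view[:, r, :].tobytes())
    return path


def _parse_field(raw: bytes, name: str, conv=str):
    text = raw.decode("ascii", errors="replace").strip()
    try:
        return conv(text)
    except ValueError as exc:
        raise FormatError(f"malformed EDF header field {name!r}: {text!r}") from exc


def read_edf(path: str | Path) -> Recording:
    """Read a plain EDF file into a Recording (data in microvolts)."""
    path = Path(path)
    with open(path, "rb") as fh:
        fixed = fh.read(_HDR)
        if len(fixed) < _HDR:
            raise FormatError(f"{path}: truncated EDF header")
        subject_id = fixed[8:88].decode("ascii", errors="replace").strip()
        session_id = fixed[88:168].decode("ascii", errors="replace").strip()
        date_s = fixed[168:176].decode("ascii", errors="replace").strip()
        time_s = fixed[176:184].decode("ascii", errors="replace").strip()
        n_records = _parse_field(fixed[236:244], "n_records", int)
        rec_dur = _parse_field(fixed[244:252], "record_duration", float)
        n_ch = _parse_field(fixed[252:256], "n_signals", int)
        if n_ch <= 0 or n_records < 0 or rec_dur <= 0:
            raise FormatError(f"{path}: inconsistent EDF header counts")

        sig_hdr = fh.read(_HDR * n_ch)
        if len(sig_hdr) < _HDR * n_ch:
            raise FormatError(f"{path}: truncated EDF signal headers")

        def col(offset: int, width: int) -> list[bytes]:
            base = offset * n_ch
            return [sig_hdr[base + i * width : base + (i + 1) * width] for i in range(n_ch)]

        labels = [b.decode("ascii", errors="replace").strip() for b in col(0, 16)]
        phys_min = np.array([_parse_field(b, "phys_min", float) for b in col(104, 8)])
        phys_max = np.array([_parse_field(b, "phys_max", float) for b in col(104 + 8, 8)])
        dig_min = np.array([_parse_field(b, "dig_min", float) for b in col(104 + 16, 8)])
        dig_max = np.array([_parse_field(b, "dig_max", float) for b in col(104 + 24, 8)])
        ns = np.array([_parse_field(b, "samples_per_record", int) for b in col(216, 8)])

        if len(set(ns.tolist())) != 1:
            raise UnsupportedInputError(
                f"{path}: signals have mixed sampling rates ({sorted(set(ns.tolist()))})"
            )
        if np.any(dig_max <= dig_min) or np.any(phys_max <= phys_min):
            raise FormatError(f"{path}: degenerate scaling in EDF signal headers")
        spr = int(ns[0])
        fs = spr / rec_dur

        raw = np.frombuffer(fh.read(2 * spr * n_ch * n_records), dtype="<i2")
        if raw.size < spr * n_ch * n_records:
            raise FormatError(f"{path}: data section shorter than header promises")
    digital = raw.reshape(n_records, n_ch, spr).transpose(1, 0, 2).reshape(n_ch, -1)
    gain = (phys_max - phys_min) / (dig_max - dig_min)
    data = (digital - dig_min[:, None]) * gain[:, None] + phys_min[:, None]
    if not np.all(np.isfinite(data)):
        raise FormatError(f"{path}: non-finite samples after scaling")

    try:
        dt = datetime.strptime(date_s + " " + time_s, "%d.%m.%y %H.%M.%S")
    except ValueError:
        dt = datetime(2000, 1, 1)
    return Recording(
        data=data,
        fs=fs,
        channel_labels=tuple(labels),
        subject_id=subject_id,
        session_id=session_id,
        session_datetime=dt,
    )
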