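"""Minimal EDF (European Data Format) reader and writer.

EDF stores a fixed-width ASCII header (256 bytes global + 256 per
signal) followed by data records of little-endian int16 samples that
are affinely mapped between a digital and a physical range.  This
module implements exactly the subset the pipeline needs: uniform
per-signal sampling rates, one-second data records on write, and
microvolt physical units.
"""

from __future__ import annotations

import math
from pathlib import Path

import numpy as np

from .recording import EEGRecording

_DIG_MIN, _DIG_MAX = -32768, 32767


class EDFError(ValueError):
    """Raised for malformed or unsupported EDF content."""


def _field(text: str, width: int) -> bytes:
    raw = text.encode("ascii")
    if len(raw) > width:
        raise EDFError(f"EDF field {text!r} exceeds {width} ascii characters")
    return raw.ljust(width)


def _num(raw: bytes, kind=float):
    text = raw.decode("ascii", errors="replace").strip()
    try:
        return kind(text)
    except ValueError as exc:
        raise EDFError(f"malformed EDF header field {text!r}") from exc


def write_edf(rec: EEGRecording, path: str | Path) -> Path:
    """Write a recording as a standard EDF file.

    Data are split into one-second records, so the total sample count per
    channel must be divisible by the sampling rate.  Each signal gets a
    symmetric physical range just covering its data, which bounds the
    round-trip quantization error at one digital step.
    """
    path = Path(path)
    fs = rec.fs
    if abs(fs - round(fs)) > 1e-9:
        raise EDFError("EDF writer requires an integer sampling rate")
    fs = int(round(fs))
    n_sig = rec.n_channels
    if rec.n_samples % fs:
        raise EDFError("sample count per channel must be a whole number of seconds")
    n_rec = rec.n_samples // fs

    # per-signal symmetric physical range; 8-char header fields
    phys_max = np.maximum(np.ceil(np.abs(rec.samples).max(axis=1)) + 1.0, 1.0)
    header = bytearray()
    header += _field("0", 8)
    header += _field(rec.subject_id[:80], 80)
    header += _field("eegnld fixture", 80)
    header += _field("01.01.01", 8)
    header += _field("00.00.00", 8)
    header += _field(str(256 * (1 + n_sig)), 8)
    header += _field("", 44)
    header += _field(str(n_rec), 8)
    header += _field("1", 8)
    header += _field(str(n_sig), 4)

    def sig_fields(width: int, values) -> bytes:
        return b"".join(_field(str(v), width) for v in values)

    header += sig_fields(16, rec.channel_labels)
    header += sig_fields(80, [""] * n_sig)
    header += sig_fields(8, ["uV"] * n_sig)
    header += sig_fields(8, [f"{-m:g}" for m in phys_max])
    header += sig_fields(8, [f"{m:g}" for m in phys_max])
    header += sig_fields(8, [_DIG_MIN] * n_sig)
    header += sig_fields(8, [_DIG_MAX] * n_sig)
    header += sig_fields(80, [""] * n_sig)
    header += sig_fields(8, [fs] * n_sig)
    header += sig_fields(32, [""] * n_sig)

    scale = (_DIG_MAX - _DIG_MIN) / (2.0 * phys_max)
    digital = np.rint((rec.samples + phys_max[:, None]) * scale[:, None]) + _DIG_MIN
    digital = np.clip(digital, _DIG_MIN, _DIG_MAX).astype("<i2")

    with open(path, "wb") as fh:
        fh.write(bytes(header))
        for r in range(n_rec):
            block = digital[:, r * fs:(r + 1) * fs]
            fh.write(block.tobytes())
    return path


def read_edf(path: str | Path) -> EEGRecording:
    """Read an EDF/EDF+ file into an :class:`EEGRecording` (microvolts).

    All signals must share one sampling rate; annotation-only EDF+
    channels are not supported.  A file shorter than its header promises
    raises :class:`EDFError` naming the first incomplete record.
    """
    path = Path(path)
    data = path.read_bytes()
    if len(data) < 256:
        raise EDFError("file too short to contain an EDF header")
    subject = data[8:88].decode("ascii", errors="replace").strip()
    n_rec = int(_num(data[236:244]))
    rec_dur = _num(data[244:252])
    n_sig = int(_num(data[252:256]))
    if n_sig < 1:
        raise EDFError("EDF header declares no signals")
    hdr_len = 256 * (1 + n_sig)
    if len(data) < hdr_len:
        raise EDFError("truncated EDF signal header")

    # per-signal header block offsets, in bytes past the 256-byte prologue
    pos = 0
    blocks = {}
    for name, width in [("label", 16), ("transducer", 80), ("dim", 8),
                        ("phys_min", 8), ("phys_max", 8), ("dig_min", 8),
                        ("dig_max", 8), ("prefilter", 80), ("spr", 8)]:
        base = 256 + pos
        blocks[name] = [data[base + i * width: base + (i + 1) * width]
                        for i in range(n_sig)]
        pos += width * n_sig

    labels = [b.decode("ascii", errors="replace").strip() for b in blocks["label"]]
    phys_min = np.array([_num(b) for b in blocks["phys_min"]])
    phys_max = np.array([_num(b) for b in blocks["phys_max"]])
    dig_min = np.array([_num(b) for b in blocks["dig_min"]])
    dig_max = np.array([_num(b) for b in blocks["dig_max"]])
    spr = np.array([int(_num(b)) for b in blocks["spr"]])
    if rec_dur <= 0:
        raise EDFError("non-positive record duration")
    rates = spr / rec_dur
    if np.unique(rates).size != 1:
        raise EDFError(f"mixed per-channel sampling rates {sorted(set(rates))} are not supported")
    fs = float(rates[0])

    rec_bytes = int(spr.sum()) * 2
    if n_rec < 0:  # unknown record count: infer from file size
        n_rec = (len(data) - hdr_len) // rec_bytes
    samples = np.empty((n_sig, int(spr[0]) * n_rec), dtype=np.float64)
    offsets = np.concatenate([[0], np.cumsum(spr)]).astype(int)
    for r in range(n_rec):
        start = hdr_len + r * rec_bytes
        chunk = data[start:start + rec_bytes]
        if len(chunk) < rec_bytes:
            raise EDFError(f"truncated EDF file: data record {r} incomplete")
        raw = np.frombuffer(chunk, dtype="<i2")
        for i in range(n_sig):
            samples[i, r * spr[0]:(r + 1) * spr[0]] = raw[offsets[i]:offsets[i + 1]]

    gain = (phys_max - phys_min) / (dig_max - dig_min)
    samples = (samples - dig_min[:, None]) * gain[:, None] + phys_min[:, None]
    return EEGRecording(
        subject_id=subject or path.stem,
        channel_labels=tuple(labels),
        fs=fs,
        samples=samples,
    )
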