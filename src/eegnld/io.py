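"""Ingest operations: montage selection, rate normalization, segment cut.

The working convention downstream is a 19-channel 10-20 montage at
250 Hz; recordings acquired at 500 Hz are anti-alias filtered and
decimated, and the analysis segment is always taken from the start of
the recording (no splicing or manual review).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
from scipy import signal

from .edf import read_edf as _read_edf
from .recording import EEGRecording, MONTAGE_19

SUPPORTED_RATES = (250.0, 500.0)


class MontageError(KeyError):
    """A required montage channel could not be resolved in the recording."""


def read_edf(path: str | Path) -> EEGRecording:
    """Read an EDF file; all channels are returned, selection is separate."""
    return _read_edf(path)


def select_montage(
    rec: EEGRecording,
    montage: tuple[str, ...] = MONTAGE_19,
    aliases: dict[str, str] | None = None,
) -> EEGRecording:
    """Return exactly the montage channels, in canonical order.

    Parameters
    ----------
    rec
        Source recording; may carry extra channels (e.g. a 64/128-channel
        net) as long as every montage label resolves.
    montage
        Ordered target labels; defaults to the 19-channel 10-20 set.
    aliases
        Optional map from montage label to the recording's native label,
        for nets that do not use 10-20 names.  No silent nearest-sensor
        guessing is performed: unresolvable labels raise.
    """
    aliases = aliases or {}
    lookup = {lab: i for i, lab in enumerate(rec.channel_labels)}
    rows, missing = [], []
    for lab in montage:
        src = aliases.get(lab, lab)
        if src in lookup:
            rows.append(lookup[src])
        else:
            missing.append(lab)
    if missing:
        raise MontageError(f"montage channels not found in recording: {missing}")
    return rec.copy_with(
        channel_labels=tuple(montage), samples=rec.samples[rows].copy()
    )


def resample_to_250(rec: EEGRecording) -> EEGRecording:
    """Normalize the sampling rate to 250 Hz.

    250 Hz input is returned unchanged; 500 Hz input is low-pass filtered
    with a zero-phase 8th-order Butterworth at 0.8x the target Nyquist
    (100 Hz) and decimated by two.  Other rates are rejected.
    """
    if abs(rec.fs - 250.0) < 1e-9:
        return rec
    if abs(rec.fs - 500.0) > 1e-9:
        raise ValueError(
            f"unsupported sampling rate {rec.fs} Hz; expected one of {SUPPORTED_RATES}"
        )
    sos = signal.butter(8, 100.0, btype="low", fs=rec.fs, output="sos")
    filtered = signal.sosfiltfilt(sos, rec.samples, axis=1)
    return rec.copy_with(fs=250.0, samples=filtered[:, ::2].copy())


def extract_segment(
    rec: EEGRecording, duration_s: float, start_s: float = 0.0
) -> EEGRecording:
    """Take a continuous ``duration_s`` segment starting at ``start_s``.

    Defaults to the first ``duration_s`` seconds of every channel; the
    optional offset exists for recordings whose opening seconds are
    unusable, but no automatic segment search is ever performed.
    """
    n = int(round(duration_s * rec.fs))
    i0 = int(round(start_s * rec.fs))
    if n <= 0:
        raise ValueError("segment duration must be positive")
    if i0 + n > rec.n_samples:
        raise ValueError(
            f"recording has {rec.duration_s:.3f} s, cannot extract "
            f"{duration_s} s starting at {start_s} s"
        )
    if i0 == 0 and n == rec.n_samples:
        return rec
    return rec.copy_with(samples=rec.samples[:, i0:i0 + n].copy())


def preprocess(
    rec: EEGRecording,
    duration_s: float = 30.0,
    montage: tuple[str, ...] = MONTAGE_19,
    aliases: dict[str, str] | None = None,
) -> EEGRecording:
    """Montage-select, resample to 250 Hz, and cut the analysis segment."""
    out = select_montage(rec, montage, aliases)
    out = resample_to_250(out)
    return extract_segment(out, duration_s)
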