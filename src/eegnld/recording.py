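"""Core recording container and the 19-channel 10-20 montage.

All downstream feature indexing is keyed to the fixed channel order in
:data:`MONTAGE_19`; changing that order would silently permute every
feature vector, so it is defined once here and treated as immutable.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

#: Canonical 10-20 scalp positions, in the fixed order that defines
#: sensor-major feature indexing everywhere downstream.
MONTAGE_19: tuple[str, ...] = (
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8", "T7", "C3", "Cz",
    "C4", "T8", "P7", "P3", "Pz", "P4", "P8", "O1", "O2",
)


@dataclass
class EEGRecording:
    """One subject-visit's multichannel EEG segment.

    Parameters
    ----------
    subject_id
        Opaque identifier for the subject.
    channel_labels
        Ordered montage names, one per row of ``samples``.
    fs
        Sampling rate in Hz.
    samples
        ``(n_channels, n_samples)`` array in microvolts.
    age_months
        Visit age in months, if known.
    """

    subject_id: str
    channel_labels: tuple[str, ...]
    fs: float
    samples: np.ndarray
    age_months: float | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        self.channel_labels = tuple(str(c) for c in self.channel_labels)
        if self.samples.ndim != 2:
            raise ValueError("samples must be a 2-D (channels x time) array")
        if self.samples.shape[0] != len(self.channel_labels):
            raise ValueError(
                f"{len(self.channel_labels)} labels for "
                f"{self.samples.shape[0]} sample rows"
            )
        if len(set(self.channel_labels)) != len(self.channel_labels):
            raise ValueError("channel labels must be unique")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def copy_with(self, **changes) -> "EEGRecording":
        return replace(self, **changes)
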