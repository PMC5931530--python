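"""Synthetic infant-EEG cohorts with group- and severity-linked dynamics.

The real study data this pipeline is designed for cannot be shared, so
every downstream stage is exercised on synthetic recordings instead.
Each channel is a severity-weighted mixture of

* fractional Gaussian noise (exact circulant-embedding generator) whose
  Hurst parameter rises with the outcome group, and
* deterministic fixed-frequency tones with slow random phase drift,
  placed in designated sensor/band cells (temporal/parietal beta+gamma,
  occipital delta), whose mixing weight grows with the severity score.

More tone means a more regular signal: determinism (DET) rises and
sample entropy falls in the designated cells as severity grows, which
is the group contrast the analysis stages are built to detect.  All
group and severity dependence is multiplied by ``effect_size``, so at
``effect_size=0`` the three groups are statistically exchangeable — the
null case for calibration tests.

This generator makes no attempt at biophysical realism (no forward
model, no blink/muscle artifacts, no 1/f spectral shaping beyond fGn);
it reproduces only the statistical structure the analysis assumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .edf import write_edf
from .recording import EEGRecording, MONTAGE_19

GROUPS: tuple[str, ...] = ("LRC-", "HRA-", "ASD")

#: Sensor/band cells that carry the group effect by default:
#: temporal/parietal beta+gamma and occipital delta.
DEFAULT_TARGET_CELLS: dict[str, tuple[str, ...]] = {
    "T7": ("beta", "gamma"),
    "T8": ("beta", "gamma"),
    "P4": ("beta", "gamma"),
    "P8": ("beta", "gamma"),
    "O1": ("delta",),
    "O2": ("delta",),
}

#: Tone periods in samples for the deterministic component per band.
#: Periods share a small common multiple with the 2**6 dyadic grid
#: (LCM 192), so the wavelet detail of each tone is itself strictly
#: periodic — an incommensurate tone's detail is quasi-periodic and
#: *more* complex, which would invert the intended severity effect.
#: At 250 Hz these are 20.8 Hz (beta), 41.7 Hz (gamma), 2.6 Hz (delta).
_BAND_TONE_PERIODS: dict[str, int] = {"beta": 12, "gamma": 6, "delta": 96}

#: CSS sampling ranges per outcome group; the high-risk-no-ASD group is
#: intermediate and overlaps both endpoints.
_CSS_RANGES: dict[str, tuple[float, float]] = {
    "LRC-": (1.0, 2.5),
    "HRA-": (1.0, 5.0),
    "ASD": (4.0, 10.0),
}

_GROUP_CODE: dict[str, float] = {"LRC-": 0.0, "HRA-": 0.5, "ASD": 1.0}


def fractional_gaussian_noise(
    n: int, hurst: float, rng: np.random.Generator
) -> np.ndarray:
    """Exact stationary fGn sample of length ``n`` via circulant embedding.

    The target autocovariance gamma(k) = ((k+1)^2H - 2k^2H + |k-1|^2H)/2
    is embedded in a circulant of size 2n whose eigenvalues are
    non-negative for fGn; white noise filtered by the eigenvalue square
    root in the Fourier domain then has exactly that covariance.
    """
    if not 0 < hurst < 1:
        raise ValueError("Hurst parameter must be in (0, 1)")
    if n < 1:
        raise ValueError("need n >= 1")
    if abs(hurst - 0.5) < 1e-12:
        return rng.standard_normal(n)
    k = np.arange(n + 1, dtype=np.float64)
    g = 0.5 * ((k + 1) ** (2 * hurst) - 2 * k ** (2 * hurst)
               + np.abs(k - 1) ** (2 * hurst))
    c = np.concatenate([g, g[-2:0:-1]])          # length 2n, circularly even
    eig = np.fft.rfft(c).real
    eig = np.clip(eig, 0.0, None)                # guard tiny negative rounding
    w = rng.standard_normal(2 * n)
    y = np.fft.irfft(np.fft.rfft(w) * np.sqrt(eig), n=2 * n)
    return y[:n]


@dataclass
class CohortSpec:
    """Design of a synthetic cohort.

    ``effect_size`` scales every group/severity dependence (0 = null
    cohort, 1 = default contrast); all other parameters are the study's
    recording conventions (19 channels, 250 Hz, 30 s).
    """

    n_per_group: int = 10
    groups: tuple[str, ...] = GROUPS
    ages_months: tuple[float, ...] = (6.0,)
    n_channels: int = 19
    fs: float = 250.0
    duration_s: float = 30.0
    effect_size: float = 1.0
    seed: int = 0
    age_shift: bool = False          # flip the group contrast after 12 months
    target_cells: dict[str, tuple[str, ...]] = field(
        default_factory=lambda: dict(DEFAULT_TARGET_CELLS)
    )

    def __post_init__(self) -> None:
        if self.n_per_group < 1:
            raise ValueError("n_per_group must be >= 1")
        if not self.groups:
            raise ValueError("groups must be non-empty")
        unknown = set(self.groups) - set(GROUPS)
        if unknown:
            raise ValueError(f"unknown group names {sorted(unknown)}")
        if self.fs <= 0 or self.duration_s <= 0:
            raise ValueError("fs and duration_s must be positive")
        if self.n_channels < 1:
            raise ValueError("n_channels must be >= 1")

    @property
    def n_samples(self) -> int:
        return int(round(self.fs * self.duration_s))


@dataclass
class SubjectOutcome:
    """Outcome-table row for one subject-visit."""

    subject_id: str
    group: str
    css: float
    age_months: float

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"unknown group {self.group!r}")
        if not 1.0 <= self.css <= 10.0:
            raise ValueError("css must lie in [1, 10]")


def montage_labels(n_channels: int) -> tuple[str, ...]:
    """Channel labels for a synthetic net of ``n_channels`` sensors.

    19 gives the canonical 10-20 montage.  Larger nets embed the 19
    montage labels at spread positions among generic ``E##`` electrode
    names, emulating a high-density net whose 10-20 subset must be
    selected out; smaller counts truncate the montage (for edge-case
    tests only).
    """
    if n_channels == len(MONTAGE_19):
        return MONTAGE_19
    if n_channels < len(MONTAGE_19):
        return MONTAGE_19[:n_channels]
    labels = [f"E{i + 1}" for i in range(n_channels)]
    slots = np.linspace(0, n_channels - 1, len(MONTAGE_19)).astype(int)
    for slot, name in zip(slots, MONTAGE_19):
        labels[slot] = name
    return tuple(labels)


def _tone_amplitude(css: float, effect_size: float) -> float:
    """Designated-cell tone amplitude (units of the noise SD).

    Already dominant in its band at the lowest severity and growing
    with it, so the band content moves monotonically from "mostly
    periodic" to "almost purely periodic" — a weak-tone mixture regime
    would be *less* regular than noise alone and break monotonicity.
    Scaled by ``effect_size`` so the null cohort has no tone at all.
    """
    s = (css - 1.0) / 9.0
    return effect_size * (1.2 + 2.8 * s)


def generate_recording(
    group: str,
    css: float,
    spec: CohortSpec,
    channel_seed: int,
    subject_id: str = "synthetic",
    age_months: float | None = None,
) -> EEGRecording:
    """One synthetic multichannel recording for a subject-visit.

    Reproducible bit-for-bit from ``(spec, channel_seed)``.  Higher
    ``css`` raises the deterministic-tone weight in the designated
    sensor/band cells (lower sample entropy, higher determinism there);
    the fGn Hurst parameter rises with the group code.  With
    ``spec.age_shift`` the severity mapping is inverted at and after 12
    months, moving the group contrast to the opposite sign.
    """
    if group not in GROUPS:
        raise ValueError(f"unknown group {group!r}; expected one of {GROUPS}")
    if not 1.0 <= css <= 10.0:
        raise ValueError("css must lie in [1, 10]")
    n = spec.n_samples
    if n < 2:
        raise ValueError("duration too short")
    rng = np.random.default_rng(channel_seed)
    labels = montage_labels(spec.n_channels)
    t = np.arange(n) / spec.fs

    css_eff = css
    if spec.age_shift and age_months is not None and age_months >= 12.0:
        css_eff = 11.0 - css  # invert the severity mapping past 12 months
    amp = _tone_amplitude(css_eff, spec.effect_size)
    hurst = float(np.clip(0.55 + 0.12 * spec.effect_size * _GROUP_CODE[group],
                          0.05, 0.95))
    sigma = 20.0  # microvolt scale of the stochastic component
    samp_idx = np.arange(n, dtype=np.float64)

    samples = np.empty((spec.n_channels, n))
    for ci, lab in enumerate(labels):
        noise = fractional_gaussian_noise(n, hurst, rng)
        # ubiquitous alpha-range background rhythm with slow phase drift
        drift = np.cumsum(rng.standard_normal(n)) * 0.01
        x = noise + 0.35 * np.sin(2 * np.pi * 10.0 * t + drift)
        for band in spec.target_cells.get(lab, ()):
            period = _BAND_TONE_PERIODS[band]
            drift_b = np.cumsum(rng.standard_normal(n)) * 0.002
            x = x + amp * np.sin(2 * np.pi * samp_idx / period + drift_b)
        samples[ci] = sigma * x
    return EEGRecording(
        subject_id=subject_id,
        channel_labels=labels,
        fs=spec.fs,
        samples=samples,
        age_months=age_months,
        meta={"group": group, "css": float(css)},
    )


def generate_cohort(
    spec: CohortSpec,
) -> tuple[list[EEGRecording], list[SubjectOutcome]]:
    """Generate one recording per subject per visit age, plus outcomes.

    Severity scores are drawn per subject (constant across visits) from
    group-specific uniform ranges that overlap the way real outcome
    groups do: controls 1-2.5, high-risk-no-ASD 1-5 (intermediate), ASD
    4-10 (diagnosis requires a score of 4 or higher).
    """
    rng = np.random.default_rng(spec.seed)
    recordings: list[EEGRecording] = []
    outcomes: list[SubjectOutcome] = []
    sid = 0
    for group in spec.groups:
        lo, hi = _CSS_RANGES[group]
        for _ in range(spec.n_per_group):
            sid += 1
            subject_id = f"S{sid:04d}"
            css = float(rng.uniform(lo, hi))
            for age in spec.ages_months:
                child_seed = int(rng.integers(0, 2 ** 31))
                recordings.append(
                    generate_recording(
                        group, css, spec, child_seed,
                        subject_id=subject_id, age_months=age,
                    )
                )
                outcomes.append(
                    SubjectOutcome(
                        subject_id=subject_id, group=group,
                        css=css, age_months=age,
                    )
                )
    return recordings, outcomes


def write_fixture_edf(rec: EEGRecording, path: str | Path) -> Path:
    """Serialize a synthetic recording as a standard EDF fixture file."""
    return write_edf(rec, path)


def outcomes_to_frame(outcomes: list[SubjectOutcome]):
    """Outcome table as a DataFrame (subject_id, group, css, age_months)."""
    import pandas as pd

    return pd.DataFrame(
        [
            {"subject_id": o.subject_id, "group": o.group,
             "css": o.css, "age_months": o.age_months}
            for o in outcomes
        ]
    )
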