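"""Per-session feature vectors: 19 sensors x 6 bands x 9 measures = 1026.

Naming is stable and parseable: ``<sensor>.<band>.<measure>`` with
sensor-major ordering (10-20 montage order), then band (level 1 "high
gamma" down to level 6 "delta"), then the canonical nine measures.
Degenerate cells (e.g. a constant channel) are NaN with the sentinel
mask set; imputation is deferred to model-fitting time so it can be
done with training-fold statistics only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .decomposition import BAND_NAMES, wavelet_bands
from .nld import MEASURE_NAMES, NLDSettings, channel_band_measures
from .recording import EEGRecording, MONTAGE_19

N_FEATURES = len(MONTAGE_19) * len(BAND_NAMES) * len(MEASURE_NAMES)


def feature_names(montage: tuple[str, ...] = MONTAGE_19) -> list[str]:
    """The canonical ordered feature-name list (1026 for the full montage)."""
    return [
        f"{ch}.{band}.{meas}"
        for ch in montage
        for band in BAND_NAMES
        for meas in MEASURE_NAMES
    ]


def parse_feature_name(name: str) -> tuple[str, str, str]:
    """Split ``sensor.band.measure`` (age-prefixed names keep the prefix on the sensor)."""
    parts = name.split(".")
    if len(parts) == 4:  # ageX.sensor.band.measure
        return parts[1], parts[2], parts[3]
    if len(parts) != 3:
        raise ValueError(f"not a feature name: {name!r}")
    return parts[0], parts[1], parts[2]


@dataclass
class FeatureVector:
    """Named nonlinear feature set for one session."""

    subject_id: str
    age_months: float | None
    values: np.ndarray
    names: list[str]
    sentinel_mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if len(self.names) != self.values.size:
            raise ValueError("names and values disagree in length")
        if len(set(self.names)) != len(self.names):
            raise ValueError("feature names must be unique")
        if self.sentinel_mask is None:
            self.sentinel_mask = np.isnan(self.values)

    def __len__(self) -> int:
        return self.values.size

    def to_series(self) -> pd.Series:
        return pd.Series(self.values, index=self.names, name=self.subject_id)


def extract_features(
    rec: EEGRecording, settings: NLDSettings | None = None,
    expected_duration_s: float | None = 30.0,
) -> FeatureVector:
    """All 1026 nonlinear features for one montage-selected recording.

    The recording must carry exactly the 19-channel montage in canonical
    order at 250 Hz; ``expected_duration_s`` guards against accidentally
    featurizing an uncut recording (pass None to disable the check).
    """
    if rec.channel_labels != MONTAGE_19:
        raise ValueError(
            "recording must be montage-selected to the canonical 19 channels "
            "(use eegnld.io.select_montage first)"
        )
    if expected_duration_s is not None and abs(
        rec.duration_s - expected_duration_s
    ) > 1.0 / rec.fs:
        raise ValueError(
            f"expected a {expected_duration_s} s segment, got {rec.duration_s:.3f} s"
        )
    settings = settings or NLDSettings()
    values = np.empty(len(rec.channel_labels) * len(BAND_NAMES) * len(MEASURE_NAMES))
    pos = 0
    for ch in range(rec.n_channels):
        bands = wavelet_bands(rec.samples[ch], rec.fs)
        for b in range(len(BAND_NAMES)):
            ms = channel_band_measures(bands.bands[b], settings)
            values[pos:pos + len(MEASURE_NAMES)] = ms.values
            pos += len(MEASURE_NAMES)
    return FeatureVector(
        subject_id=rec.subject_id,
        age_months=rec.age_months,
        values=values,
        names=feature_names(rec.channel_labels),
    )


def combine_ages(v1: FeatureVector, v2: FeatureVector) -> FeatureVector:
    """Concatenate two visits of one subject into a single 2052-feature vector."""
    if v1.subject_id != v2.subject_id:
        raise ValueError(
            f"cannot combine different subjects {v1.subject_id!r} and {v2.subject_id!r}"
        )
    if v1.age_months == v2.age_months:
        raise ValueError("combine_ages needs two distinct visit ages")
    first, second = sorted([v1, v2], key=lambda v: v.age_months)

    def prefixed(v: FeatureVector) -> list[str]:
        tag = f"age{v.age_months:g}"
        return [f"{tag}.{n}" for n in v.names]

    return FeatureVector(
        subject_id=v1.subject_id,
        age_months=None,
        values=np.concatenate([first.values, second.values]),
        names=prefixed(first) + prefixed(second),
        sentinel_mask=np.concatenate([first.sentinel_mask, second.sentinel_mask]),
    )


def feature_table(
    recordings, outcomes, settings: NLDSettings | None = None,
    expected_duration_s: float | None = 30.0,
) -> pd.DataFrame:
    """Featurize a cohort into one DataFrame.

    Rows are sessions; columns are ``subject_id, group, css, age_months``
    followed by the 1026 named features.  ``recordings`` and ``outcomes``
    must be parallel lists as produced by ``synthetic.generate_cohort``.
    """
    if len(recordings) != len(outcomes):
        raise ValueError("recordings and outcomes must be parallel lists")
    rows = []
    for rec, out in zip(recordings, outcomes):
        fv = extract_features(rec, settings, expected_duration_s)
        row = {"subject_id": out.subject_id, "group": out.group,
               "css": out.css, "age_months": out.age_months}
        row.update(zip(fv.names, fv.values))
        rows.append(row)
    return pd.DataFrame(rows)


def combine_age_table(table: pd.DataFrame, age_a: float, age_b: float) -> pd.DataFrame:
    """Join two visit ages into one row per subject with both visits.

    Subjects lacking either visit are dropped, mirroring a combined
    6+9-month analysis restricted to subjects seen at both ages.
    """
    meta = ["subject_id", "group", "css", "age_months"]
    feats = [c for c in table.columns if c not in meta]
    a = table[table["age_months"] == age_a]
    b = table[table["age_months"] == age_b]
    common = sorted(set(a["subject_id"]) & set(b["subject_id"]))
    rows = []
    for sid in common:
        ra = a[a["subject_id"] == sid].iloc[0]
        rb = b[b["subject_id"] == sid].iloc[0]
        row = {"subject_id": sid, "group": ra["group"], "css": ra["css"],
               "age_months": np.nan}
        row.update({f"age{age_a:g}.{c}": ra[c] for c in feats})
        row.update({f"age{age_b:g}.{c}": rb[c] for c in feats})
        rows.append(row)
    return pd.DataFrame(rows)
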