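"""Descriptive group analyses: difference maps and regional trajectories.

A difference map tests one nonlinear measure in every sensor/band cell
between two outcome groups (Welch's two-sample t by default) and flags
cells at the strict Bonferroni threshold p < 5e-5 (0.05 over 1026
features treated as independent — stored as the literal constant the
analysis uses, not recomputed).  A trajectory averages a measure over a
sensor region and band subset within subject, then across subjects per
visit age, with bootstrap percentile confidence bands.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .decomposition import BAND_NAMES
from .nld import MEASURE_NAMES
from .recording import MONTAGE_19

#: Strict Bonferroni gate for 1026 simultaneous tests, as used in maps.
BONFERRONI_ALPHA = 5e-5

#: Sensor-region presets used in the trajectory analyses.  Two frontal
#: sets ship because the source analyses print both a five- and a
#: six-sensor frontal list.
REGIONS: dict[str, tuple[str, ...]] = {
    "left_temporal": ("T7",),
    "right_temporal_parietal": ("T8", "P4", "P8"),
    "left_lateral_frontal": ("F7",),
    "frontal_5": ("Fp1", "F7", "Fz", "F8", "Fp2"),
    "frontal_6": ("F7", "F3", "Fp1", "Fp2", "F4", "F8"),
    "posterior": ("O1", "O2"),
}

#: Band-subset presets matching the trajectory figures' frequency labels.
BAND_PRESETS: dict[str, tuple[str, ...]] = {
    "beta_gamma": ("gamma", "beta"),
    "theta_through_gamma": ("gamma", "beta", "alpha", "theta"),
    "delta": ("delta",),
}


@dataclass
class DifferenceMap:
    """Per-cell group contrast for one measure at one age.

    ``direction[b, s]`` is +1 where the first (ASD) group mean exceeds
    the comparison mean, -1 where lower, 0 for ties/degenerate cells;
    ``p_values`` is the matching 6-bands x 19-sensors grid.
    """

    measure: str
    bands: tuple[str, ...]
    sensors: tuple[str, ...]
    direction: np.ndarray      # (6, 19) int
    p_values: np.ndarray       # (6, 19) float
    age_months: float | None
    threshold: float = BONFERRONI_ALPHA

    @property
    def significant(self) -> np.ndarray:
        return self.p_values < self.threshold

    def flagged_cells(self) -> list[tuple[str, str]]:
        """(sensor, band) pairs passing the Bonferroni gate."""
        rows, cols = np.nonzero(self.significant)
        return [(self.sensors[c], self.bands[r]) for r, c in zip(rows, cols)]


@dataclass
class TrajectoryCurve:
    """Region/band-averaged developmental trajectory for one group."""

    group: str
    region_sensors: tuple[str, ...]
    bands: tuple[str, ...]
    measure: str
    ages: np.ndarray
    means: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    n_subjects: np.ndarray


def _measure_columns(measure: str) -> list[str]:
    if measure not in MEASURE_NAMES:
        raise ValueError(f"unknown measure {measure!r}")
    return [f"{ch}.{band}.{measure}" for ch in MONTAGE_19 for band in BAND_NAMES]


def difference_map(
    features_a: pd.DataFrame,
    features_b: pd.DataFrame,
    measure: str,
    age_months: float | None = None,
    threshold: float = BONFERRONI_ALPHA,
    test: str = "welch",
) -> DifferenceMap:
    """Cell-wise two-group contrast of one measure.

    ``features_a`` holds the ASD-group rows and ``features_b`` the
    comparison rows (columns as produced by ``features.feature_table``).
    ``test`` is ``"welch"`` (unequal-variance t) or ``"mannwhitney"``.
    Cells where both groups are constant get p = 1 and direction 0.
    """
    if len(features_a) < 3 or len(features_b) < 3:
        raise ValueError("need at least 3 subjects per group")
    if test not in ("welch", "mannwhitney"):
        raise ValueError(f"unknown test {test!r}")
    n_b, n_s = len(BAND_NAMES), len(MONTAGE_19)
    cols = [f"{ch}.{band}.{measure}" for ch in MONTAGE_19 for band in BAND_NAMES]
    A = features_a[cols].to_numpy(dtype=float)
    B = features_b[cols].to_numpy(dtype=float)
    with np.errstate(invalid="ignore"):
        if test == "welch":
            res = stats.ttest_ind(A, B, axis=0, equal_var=False,
                                  nan_policy="omit")
        else:
            res = stats.mannwhitneyu(A, B, axis=0, alternative="two-sided",
                                     nan_policy="omit")
        pvals = np.asarray(res.pvalue, dtype=float)
        diff = np.nanmean(A, axis=0) - np.nanmean(B, axis=0)
    pvals = np.where(np.isfinite(pvals), pvals, 1.0)  # degenerate cells
    signs = np.where(pvals == 1.0, 0, np.sign(diff)).astype(int)
    # columns are sensor-major; the grid is bands x sensors
    p = pvals.reshape(n_s, n_b).T
    direction = signs.reshape(n_s, n_b).T
    return DifferenceMap(
        measure=measure, bands=BAND_NAMES, sensors=MONTAGE_19,
        direction=direction, p_values=p, age_months=age_months,
        threshold=threshold,
    )


def regional_trajectory(
    table: pd.DataFrame,
    group: str,
    region_sensors: tuple[str, ...],
    bands: tuple[str, ...],
    measure: str,
    n_boot: int = 2000,
    ci: float = 0.95,
    seed: int = 0,
) -> TrajectoryCurve:
    """Developmental trajectory of a region/band-averaged measure.

    Per age: average the measure over the listed sensors and bands
    within each subject, then across subjects; confidence bands are
    bootstrap percentiles over subjects (``n_boot`` resamples).
    """
    if not region_sensors or not bands:
        raise ValueError("region_sensors and bands must be non-empty")
    cols = [f"{ch}.{band}.{measure}" for ch in region_sensors for band in bands]
    missing = [c for c in cols if c not in table.columns]
    if missing:
        raise ValueError(f"feature columns missing from table: {missing[:3]}...")
    sub = table[table["group"] == group]
    ages = np.array(sorted(sub["age_months"].unique()))
    if ages.size < 1:
        raise ValueError(f"no rows for group {group!r}")
    rng = np.random.default_rng(seed)
    alpha = (1.0 - ci) / 2.0
    means = np.empty(ages.size)
    lo = np.empty(ages.size)
    hi = np.empty(ages.size)
    n_subj = np.empty(ages.size, dtype=int)
    for ai, age in enumerate(ages):
        per_subject = sub[sub["age_months"] == age][cols].mean(axis=1).to_numpy()
        per_subject = per_subject[~np.isnan(per_subject)]
        n = per_subject.size
        n_subj[ai] = n
        means[ai] = per_subject.mean()
        if n == 1:
            lo[ai] = hi[ai] = means[ai]
            continue
        idx = rng.integers(0, n, size=(n_boot, n))
        boot = per_subject[idx].mean(axis=1)
        lo[ai] = np.quantile(boot, alpha)
        hi[ai] = np.quantile(boot, 1.0 - alpha)
    return TrajectoryCurve(
        group=group, region_sensors=tuple(region_sensors), bands=tuple(bands),
        measure=measure, ages=ages, means=means, ci_low=lo, ci_high=hi,
        n_subjects=n_subj,
    )
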