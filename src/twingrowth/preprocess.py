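"""qPCR T/S-ratio preprocessing: plate batch adjustment, outlier exclusion, CV.

Batch adjustment regresses the raw T/S-ratio on plate-indicator fixed effects
and re-scales the residuals back to the T/S scale by adding the grand mean, so
every plate's post-adjustment mean equals the grand mean exactly.  Outlier
exclusion removes samples beyond k SDs of the mean, computed either on the
full set (cross-sectional use) or within decade age bands (longitudinal use),
in a single pass with mean/SD taken from the pre-exclusion data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import satsa

logger = logging.getLogger(__name__)


@dataclass
class AgeBandRule:
    """Non-overlapping age bands (closed-open; upper None = open) and SD cut."""

    bands: tuple = satsa.AGE_BANDS
    k_sd: float = satsa.OUTLIER_K_SD

    def __post_init__(self) -> None:
        if self.k_sd <= 0:
            raise ValueError("k_sd must be positive")
        lo = None
        for lower, upper in self.bands:
            if upper is not None and upper <= lower:
                raise ValueError(f"band ({lower}, {upper}) is empty")
            if lo is not None and lower != lo:
                raise ValueError("bands must be contiguous and non-overlapping")
            lo = upper
        if lo is not None:
            raise ValueError("last band must be open-ended (upper = None)")

    def band_index(self, ages: np.ndarray) -> np.ndarray:
        """Index of the band containing each age; -1 below the first band."""
        ages = np.asarray(ages, dtype=float)
        out = np.full(ages.shape, -1, dtype=int)
        for i, (lower, upper) in enumerate(self.bands):
            in_band = ages >= lower
            if upper is not None:
                in_band &= ages < upper
            out[in_band] = i
        return out


def adjust_batch(measurements: pd.DataFrame) -> pd.DataFrame:
    """Fill ts_adjusted with plate-adjusted, re-scaled T/S-ratios.

    ts_adjusted = residual from regressing ts_raw on plate indicators, plus
    the grand mean of ts_raw.  With an intercept-plus-plate-dummies design the
    residual is simply ts_raw minus its plate mean, so after adjustment every
    plate's mean equals the grand mean exactly and the overall mean is
    preserved.  Records with missing ts_raw are left unadjusted (warned).
    """
    if measurements.empty:
        out = measurements.copy()
        out["ts_adjusted"] = pd.Series(dtype=float)
        return out
    if measurements["plate_id"].isna().any():
        raise ValueError("every measurement needs a plate_id")
    out = measurements.copy()
    ts = out["ts_raw"]
    missing = ts.isna()
    if missing.any():
        logger.warning("adjust_batch: %d records missing ts_raw skipped", missing.sum())
    grand_mean = ts.mean()
    plate_means = ts.groupby(out["plate_id"]).transform("mean")
    out["ts_adjusted"] = ts - plate_means + grand_mean
    return out


def exclude_outliers(
    measurements: pd.DataFrame,
    mode: str = "overall",
    k_sd: float = satsa.OUTLIER_K_SD,
    bands: AgeBandRule | None = None,
    value_col: str = "ts_adjusted",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Single-pass k-SD exclusion, overall or within age bands.

    Mean and SD come from the pre-exclusion data (no iteration).  Returns
    (kept, excluded); excluded rows gain an ``exclusion_reason`` column.
    Bands with fewer than two records yield no exclusions (SD undefined).
    """
    if mode not in ("overall", "by_age_band"):
        raise ValueError(f"mode must be 'overall' or 'by_age_band', got {mode!r}")
    if measurements.empty:
        return measurements.copy(), measurements.copy()
    x = measurements[value_col].to_numpy(dtype=float)
    if np.isnan(x).any():
        raise ValueError(f"{value_col} must be filled before outlier exclusion")

    drop = np.zeros(len(measurements), dtype=bool)
    reason = np.full(len(measurements), "", dtype=object)

    def flag(idx: np.ndarray, label: str) -> None:
        sub = x[idx]
        if sub.size < 2:
            logger.info("exclude_outliers: %s has <2 records, skipped", label)
            return
        m, s = sub.mean(), sub.std(ddof=1)
        if s == 0:
            return
        bad = np.abs(sub - m) > k_sd * s
        drop[idx[bad]] = True
        reason[idx[bad]] = f"|{value_col} - mean| > {k_sd} SD ({label})"

    if mode == "overall":
        flag(np.arange(len(measurements)), "overall")
    else:
        rule = bands or AgeBandRule(k_sd=k_sd)
        band_idx = rule.band_index(measurements["age_at_draw"].to_numpy())
        for i, band in enumerate(rule.bands):
            flag(np.flatnonzero(band_idx == i), f"age band {band}")

    kept = measurements.loc[~drop].copy()
    excluded = measurements.loc[drop].copy()
    excluded["exclusion_reason"] = reason[drop]
    return kept, excluded


def compute_cv(measurements: pd.DataFrame) -> float:
    """Mean duplicate-pair coefficient of variation, in percent.

    For each sample with both replicates present, CV = SD of the pair divided
    by the pair mean; the returned value is 100 times the average across
    samples.
    """
    d1 = measurements["duplicate_1"].to_numpy(dtype=float)
    d2 = measurements["duplicate_2"].to_numpy(dtype=float)
    ok = ~(np.isnan(d1) | np.isnan(d2))
    if not ok.any():
        raise ValueError("no records with both duplicate values present")
    pairs = np.column_stack([d1[ok], d2[ok]])
    sds = pairs.std(axis=1, ddof=1)
    means = pairs.mean(axis=1)
    return float(100.0 * np.mean(sds / means))


def first_measurements(measurements: pd.DataFrame) -> pd.DataFrame:
    """First available measurement per individual (cross-sectional dataset)."""
    return (
        measurements.sort_values(["individual_id", "occasion"], kind="mergesort")
        .groupby("individual_id", as_index=False)
        .first()
    )
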