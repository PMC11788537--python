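"""Snowmelt timing and duration from daily snow-cover-fraction series.

Melt timing is the first day after the seasonal maximum on which the
absolute snow-cover fraction is at or below 50%.  Melt duration is the
number of days between the cover first falling below 95% and below 5% of
the seasonal maximum — relative thresholds, because full cover is not
reached in every region and year.  "After snowmelt started" is
operationalized as "after the day of seasonal maximum cover", the unique
unambiguous anchor in a daily series.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger("snowphen")


@dataclass
class SnowmeltMetrics:
    """Per year x region snowmelt statistics (NaN where undefined)."""

    year: int
    region: str
    melt_timing_day: float      # day of year of 50% absolute cover
    melt_duration_days: float   # days between 95% and 5% of max cover
    max_cover: float
    duration_censored: bool = False


def _after_max(doy: np.ndarray, cover: np.ndarray):
    """Series strictly after the day of seasonal maximum cover."""
    peak = int(np.argmax(cover))
    return doy[peak:], cover[peak:]


def snowmelt_timing(doy: np.ndarray, cover: np.ndarray,
                    threshold: float = 0.5, strict: bool = False) -> float:
    """First day after peak cover at or below the absolute 50% threshold.

    Undefined (NaN) when the seasonal maximum never exceeds the threshold.
    ``strict=True`` switches the comparison from <= to <.
    """
    doy = np.asarray(doy, dtype=float)
    cover = np.asarray(cover, dtype=float)
    if cover.max() <= threshold:
        return np.nan
    d_after, c_after = _after_max(doy, cover)
    hit = c_after < threshold if strict else c_after <= threshold
    if not hit.any():
        return np.nan
    return float(d_after[np.argmax(hit)])


def snowmelt_duration(doy: np.ndarray, cover: np.ndarray,
                      hi: float = 0.95, lo: float = 0.05) -> tuple[float, bool]:
    """Days between cover dropping below ``hi`` and ``lo`` times the maximum.

    Returns (duration, censored); censored=True when cover never falls below
    lo*max before the series end (duration then runs to the last day).
    """
    doy = np.asarray(doy, dtype=float)
    cover = np.asarray(cover, dtype=float)
    cmax = cover.max()
    if cmax <= 0:
        return np.nan, False
    d_after, c_after = _after_max(doy, cover)
    below_hi = c_after < hi * cmax
    if not below_hi.any():
        return np.nan, True
    d95 = d_after[np.argmax(below_hi)]
    below_lo = c_after < lo * cmax
    if not below_lo.any():
        return float(d_after[-1] - d95), True
    d05 = d_after[np.argmax(below_lo)]
    return float(d05 - d95), False


def snowmelt_table(climate: pd.DataFrame) -> pd.DataFrame:
    """Snowmelt metrics per year x region from a daily climate table."""
    rows = []
    for (year, region), grp in climate.groupby(["year", "region"], sort=True):
        grp = grp.sort_values("day_of_year")
        doy = grp["day_of_year"].to_numpy(dtype=float)
        cov = grp["snow_cover_fraction"].to_numpy(dtype=float)
        timing = snowmelt_timing(doy, cov)
        duration, censored = snowmelt_duration(doy, cov)
        if not np.isfinite(timing):
            logger.warning("snowmelt timing undefined for %s %d (max cover %.2f)",
                           region, year, cov.max())
        rows.append({
            "year": int(year), "region": region,
            "melt_timing": timing, "melt_duration": duration,
            "max_cover": float(cov.max()), "duration_censored": censored,
        })
    return pd.DataFrame(rows)
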