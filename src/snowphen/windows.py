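"""Sliding-window climate sensitivity scan.

Candidate windows of at least 7 days are slid in 2-day steps (both
endpoints on the step grid) across a search range, each summarized per
year x region as the mean temperature or the number of precipitation days
(days with >= 1 mm).  Every window's summary is correlated (Pearson) with a
phenology metric over the pooled year x region points.  Because many
correlations are computed, a certainty filter keeps only coefficients whose
95% interval (r +/- 1.96 * SE, SE = sqrt((1-r^2)/(n-2))) excludes zero; the
best window is the certain window with the largest |r|.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger("snowphen")

MIN_WINDOW_LENGTH = 7
WINDOW_STEP = 2
PRECIP_DAY_MM = 1.0
#: Search ranges (day-of-year) per response: Apr 1 - Jun 30 for the start,
#: Apr 15 - Aug 15 for the end.
DEFAULT_SEARCH_RANGES = {"start": (91, 181), "end": (105, 227)}

VARIABLES = ("mean_temperature", "precipitation_days")


@dataclass(frozen=True)
class WindowSpec:
    """A candidate climate window [open_day, close_day], inclusive."""

    open_day: int
    close_day: int

    @property
    def length(self) -> int:
        return self.close_day - self.open_day + 1

    def overlap_days(self, other: "WindowSpec") -> int:
        return max(0, min(self.close_day, other.close_day)
                   - max(self.open_day, other.open_day) + 1)


def enumerate_windows(day_range: tuple[int, int],
                      min_len: int = MIN_WINDOW_LENGTH,
                      step: int = WINDOW_STEP) -> list[WindowSpec]:
    """All windows with both endpoints on the step grid anchored at the
    range start, of at least ``min_len`` days, fully inside the range."""
    lo, hi = int(day_range[0]), int(day_range[1])
    grid = np.arange(lo, hi + 1, step)
    out = []
    for o in grid:
        for c in grid:
            if c - o + 1 >= min_len:
                out.append(WindowSpec(int(o), int(c)))
    return out


def window_summary(climate: pd.DataFrame, window: WindowSpec,
                   variable: str, precip_mm: float = PRECIP_DAY_MM) -> pd.DataFrame:
    """Summarize one window per year x region.

    mean_temperature: mean of temp_mean over the window days;
    precipitation_days: count of days with precip_sum >= ``precip_mm``.
    Year x region groups missing any window day are dropped with a warning.
    """
    if variable not in VARIABLES:
        raise ValueError(f"unknown window variable {variable!r}")
    sel = climate[(climate["day_of_year"] >= window.open_day)
                  & (climate["day_of_year"] <= window.close_day)]
    rows = []
    for (year, region), grp in sel.groupby(["year", "region"], sort=True):
        if grp["day_of_year"].nunique() < window.length:
            logger.warning("window %s-%s: missing days for %s %d; dropped",
                           window.open_day, window.close_day, region, year)
            continue
        if variable == "mean_temperature":
            value = float(grp["temp_mean"].mean())
        else:
            value = float((grp["precip_sum"] >= precip_mm).sum())
        rows.append({"year": int(year), "region": region, "value": value})
    return pd.DataFrame(rows)


def _daily_matrix(climate: pd.DataFrame, doy_lo: int, doy_hi: int,
                  variable: str, precip_mm: float):
    """Pivot the climate table to a (year x region) by day matrix."""
    col = "temp_mean" if variable == "mean_temperature" else "precip_sum"
    sel = climate[(climate["day_of_year"] >= doy_lo) & (climate["day_of_year"] <= doy_hi)]
    wide = sel.pivot_table(index=["year", "region"], columns="day_of_year",
                           values=col, aggfunc="first")
    wide = wide.reindex(columns=np.arange(doy_lo, doy_hi + 1))
    vals = wide.to_numpy(dtype=float)
    if variable == "precipitation_days":
        vals = (vals >= precip_mm).astype(float)
    return wide.index.to_frame(index=False), vals


def pearson_with_se(x: np.ndarray, y: np.ndarray) -> tuple[float, float, int]:
    """Pearson r, its large-sample SE sqrt((1-r^2)/(n-2)), and n."""
    ok = np.isfinite(x) & np.isfinite(y)
    n = int(ok.sum())
    if n < 3:
        return np.nan, np.nan, n
    with np.errstate(invalid="ignore", divide="ignore"):
        r = float(np.corrcoef(x[ok], y[ok])[0, 1])
    if not np.isfinite(r):
        return np.nan, np.nan, n
    se = float(np.sqrt((1.0 - min(r * r, 1.0)) / (n - 2)))
    return r, se, n


def correlation_scan(metrics: pd.DataFrame, climate: pd.DataFrame,
                     windows: list[WindowSpec], variable: str, response: str,
                     precip_mm: float = PRECIP_DAY_MM,
                     z: float = 1.96) -> pd.DataFrame:
    """Pearson correlation of every window summary with a phenology metric.

    ``metrics`` needs columns year, region and the response column (start /
    end / duration); correlations pool year x region points.  Entries with
    n < 3 or zero summary variance are omitted with a warning.
    """
    if variable not in VARIABLES:
        raise ValueError(f"unknown window variable {variable!r}")
    if response not in metrics.columns:
        raise ValueError(f"response column {response!r} missing from metrics")
    doy_lo = min(w.open_day for w in windows)
    doy_hi = max(w.close_day for w in windows)
    pairs, daymat = _daily_matrix(climate, doy_lo, doy_hi, variable, precip_mm)
    resp = pairs.merge(metrics[["year", "region", response]], on=["year", "region"],
                       how="left")[response].to_numpy(dtype=float)
    # prefix sums over days for O(1) window sums; NaN-gaps propagate
    cs = np.concatenate([np.zeros((daymat.shape[0], 1)), np.cumsum(daymat, axis=1)], axis=1)
    rows = []
    for w in windows:
        i0, i1 = w.open_day - doy_lo, w.close_day - doy_lo + 1
        total = cs[:, i1] - cs[:, i0]
        summary = total / w.length if variable == "mean_temperature" else total
        r, se, n = pearson_with_se(summary, resp)
        if n < 3:
            continue
        if not np.isfinite(r):
            logger.warning("window %d-%d: zero-variance summary; omitted",
                           w.open_day, w.close_day)
            continue
        rows.append({
            "open": w.open_day, "close": w.close_day, "length": w.length,
            "variable": variable, "response": response,
            "r": r, "se_r": se, "n": n,
            "certain": bool(abs(r) > z * se),
        })
    return pd.DataFrame(rows)


def select_best_window(scan: pd.DataFrame):
    """The certain entry with the largest |r|.

    Ties break toward the shorter window, then the earlier open day.
    Returns (WindowSpec, row) or (None, None) when no entry is certain.
    """
    if scan.empty:
        return None, None
    certain = scan[scan["certain"]]
    if certain.empty:
        logger.warning("no window passes the certainty filter; none selected")
        return None, None
    order = certain.assign(neg_abs_r=lambda d: -d["r"].abs()).sort_values(
        ["neg_abs_r", "length", "open"], kind="stable")
    row = order.iloc[0]
    return WindowSpec(int(row["open"]), int(row["close"])), row


def scan_heatmap_table(scan: pd.DataFrame) -> pd.DataFrame:
    """Long-format (open, close, r, certain) grid for heatmap rendering;
    uncertain cells carry certain=False (to be gray-shaded)."""
    return scan[["open", "close", "r", "certain"]].reset_index(drop=True)
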