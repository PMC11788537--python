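"""Domain types, CSV readers/writers, and the breeding-code -> state classifier.

A citizen-science record carries an ordinal breeding-evidence code (atlas
code).  Records are collapsed to a binary state: ``likely_breeding`` if the
code indicates courtship behaviour or stronger evidence AND the date falls
inside the breeding season window (May 1 - Aug 31 by default); everything
else, including records with no code at all, is ``nonbreeding``.

Climate arrives as one row per region and day: mean temperature (degC),
precipitation sum (mm) and snow-cover fraction (0-1).  The reader enforces a
gapless daily series per region/year over the analysis range.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from datetime import date as _date

import numpy as np
import pandas as pd

logger = logging.getLogger("snowphen")

LIKELY_BREEDING = "likely_breeding"
NONBREEDING = "nonbreeding"

#: Default biogeographic regions (Swiss Alpine sub-regions).
DEFAULT_REGIONS = ("northern", "eastern", "southern", "western")

#: Breeding season window as (month, day) bounds, inclusive.
DEFAULT_SEASON = ((5, 1), (8, 31))

#: Atlas-style ordered evidence ladder (weakest -> strongest).  The national
#: code schemes differ; any ordered list with a cut point can be configured.
DEFAULT_CODE_LADDER = (
    "species_observed",
    "singing_male",
    "pair_in_habitat",
    "courtship_display",
    "territory_behavior",
    "nest_building",
    "distraction_display",
    "carrying_food",
    "feeding_nestlings",
    "fledged_young",
)
DEFAULT_CUT = "courtship_display"


class SnowphenError(ValueError):
    """Base error for malformed inputs."""


@dataclass(frozen=True)
class CodeMap:
    """Ordered breeding-code labels with a courtship-or-higher cut point.

    Codes at or above ``cut`` (in ladder order) count as breeding evidence;
    codes below, or an absent code, do not.
    """

    ladder: tuple[str, ...] = DEFAULT_CODE_LADDER
    cut: str = DEFAULT_CUT

    def __post_init__(self):
        if self.cut not in self.ladder:
            raise SnowphenError(f"cut point {self.cut!r} not in code ladder")
        if len(set(self.ladder)) != len(self.ladder):
            raise SnowphenError("code ladder contains duplicate labels")

    @property
    def cut_rank(self) -> int:
        return self.ladder.index(self.cut)

    def rank(self, code: str) -> int:
        try:
            return self.ladder.index(code)
        except ValueError:
            raise SnowphenError(f"unknown breeding code label: {code!r}") from None

    def is_breeding_evidence(self, code: str | None) -> bool:
        if code is None:
            return False
        return self.rank(code) >= self.cut_rank


@dataclass(frozen=True)
class SeasonWindow:
    """Inclusive month/day window inside which breeding evidence counts."""

    start: tuple[int, int] = DEFAULT_SEASON[0]
    end: tuple[int, int] = DEFAULT_SEASON[1]

    def contains(self, d: _date) -> bool:
        return self.start <= (d.month, d.day) <= self.end


def classify_state(
    code: str | None,
    date: _date,
    code_map: CodeMap | None = None,
    season: SeasonWindow | None = None,
) -> str:
    """Collapse a breeding code + date to the binary breeding state.

    ``likely_breeding`` iff the code is at or above the map's cut point and
    the date falls inside the season window; otherwise ``nonbreeding``.
    Unknown code labels raise :class:`SnowphenError`.
    """
    code_map = code_map or CodeMap()
    season = season or SeasonWindow()
    if code is not None:
        code_map.rank(code)  # validate even out of season
    if code_map.is_breeding_evidence(code) and season.contains(date):
        return LIKELY_BREEDING
    return NONBREEDING


# ---------------------------------------------------------------------------
# Observations


def _parse_dates(raw: pd.Series, what: str) -> pd.Series:
    parsed = pd.to_datetime(raw, format="%Y-%m-%d", errors="coerce")
    bad = parsed.isna() & raw.notna()
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise SnowphenError(f"{what}: malformed date {raw.iloc[row]!r} at data row {row + 1}")
    if parsed.isna().any():
        row = int(np.flatnonzero(parsed.isna().to_numpy())[0])
        raise SnowphenError(f"{what}: missing date at data row {row + 1}")
    return parsed


def read_observations(
    path,
    code_map: CodeMap | None = None,
    season: SeasonWindow | None = None,
    regions: tuple[str, ...] = DEFAULT_REGIONS,
) -> pd.DataFrame:
    """Read an observation CSV (columns date, region, breeding_code).

    Returns a DataFrame with columns date, year, day_of_year, region,
    breeding_code (nullable) and the derived binary state.  Summary counts
    are logged.
    """
    code_map = code_map or CodeMap()
    season = season or SeasonWindow()
    df = pd.read_csv(path, dtype={"region": str, "breeding_code": str})
    required = {"date", "region", "breeding_code"}
    if missing := required - set(df.columns):
        raise SnowphenError(f"observation file missing columns: {sorted(missing)}")
    if df.empty:
        logger.info("observations: 0 rows (0 likely_breeding, 0 nonbreeding)")
        return pd.DataFrame(
            columns=["date", "year", "day_of_year", "region", "breeding_code", "state"]
        )
    dates = _parse_dates(df["date"], "observations")
    unknown = ~df["region"].isin(regions)
    if unknown.any():
        row = int(np.flatnonzero(unknown.to_numpy())[0])
        raise SnowphenError(
            f"observations: unknown region {df['region'].iloc[row]!r} at data row {row + 1}"
        )
    codes = df["breeding_code"].where(df["breeding_code"].notna(), None)
    out = pd.DataFrame(
        {
            "date": dates.dt.date,
            "year": dates.dt.year.astype(int),
            "day_of_year": dates.dt.dayofyear.astype(int),
            "region": df["region"],
            "breeding_code": codes,
        }
    )
    out["state"] = [
        classify_state(c, d, code_map, season) for c, d in zip(out["breeding_code"], out["date"])
    ]
    n_lb = int((out["state"] == LIKELY_BREEDING).sum())
    logger.info(
        "observations: %d rows (%d likely_breeding, %d nonbreeding)",
        len(out), n_lb, len(out) - n_lb,
    )
    return out


def write_observations(df: pd.DataFrame, path) -> None:
    """Write observations back to CSV (date, region, breeding_code)."""
    cols = df[["date", "region", "breeding_code"]].copy()
    cols["date"] = pd.to_datetime(cols["date"]).dt.strftime("%Y-%m-%d")
    cols["breeding_code"] = cols["breeding_code"].fillna("")
    cols.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Climate


def read_climate(
    path,
    regions: tuple[str, ...] = DEFAULT_REGIONS,
    check_gapless: bool = True,
) -> pd.DataFrame:
    """Read a daily climate CSV (region, date, temp_mean, precip_sum,
    snow_cover_fraction), validating bounds and the gapless-series invariant
    per region and year."""
    df = pd.read_csv(path, dtype={"region": str})
    required = {"region", "date", "temp_mean", "precip_sum", "snow_cover_fraction"}
    if missing := required - set(df.columns):
        raise SnowphenError(f"climate file missing columns: {sorted(missing)}")
    dates = _parse_dates(df["date"], "climate")
    unknown = ~df["region"].isin(regions)
    if unknown.any():
        row = int(np.flatnonzero(unknown.to_numpy())[0])
        raise SnowphenError(
            f"climate: unknown region {df['region'].iloc[row]!r} at data row {row + 1}"
        )
    out = pd.DataFrame(
        {
            "region": df["region"],
            "date": dates,
            "year": dates.dt.year.astype(int),
            "day_of_year": dates.dt.dayofyear.astype(int),
            "temp_mean": df["temp_mean"].astype(float),
            "precip_sum": df["precip_sum"].astype(float),
            "snow_cover_fraction": df["snow_cover_fraction"].astype(float),
        }
    )
    validate_climate(out, check_gapless=check_gapless)
    out["date"] = out["date"].dt.date
    return out


def validate_climate(df: pd.DataFrame, check_gapless: bool = True) -> None:
    """Check bounds and (optionally) the per-region/year gapless invariant."""
    if (df["precip_sum"] < 0).any():
        raise SnowphenError("climate: negative precip_sum")
    snow = df["snow_cover_fraction"]
    if ((snow < 0) | (snow > 1)).any():
        bad = df.loc[(snow < 0) | (snow > 1)].iloc[0]
        raise SnowphenError(
            f"climate: snow_cover_fraction {bad['snow_cover_fraction']} out of [0,1] "
            f"({bad['region']}, {bad['date']})"
        )
    if not check_gapless:
        return
    dd = pd.to_datetime(df["date"])
    for (region, year), grp in df.assign(_d=dd).groupby(["region", "year"], sort=False):
        days = grp["_d"].sort_values()
        full = pd.date_range(days.iloc[0], days.iloc[-1], freq="D")
        missing = full.difference(pd.DatetimeIndex(days))
        if len(missing):
            raise SnowphenError(
                f"climate: gap in daily series for region {region!r}, "
                f"missing {missing[0].date()}"
            )
        if len(days) != len(set(days)):
            raise SnowphenError(f"climate: duplicate dates for region {region!r} year {year}")


def write_climate(df: pd.DataFrame, path) -> None:
    """Write climate to CSV with stable float formatting (reproducible bytes)."""
    cols = df[["region", "date", "temp_mean", "precip_sum", "snow_cover_fraction"]].copy()
    cols["date"] = pd.to_datetime(cols["date"]).dt.strftime("%Y-%m-%d")
    cols.to_csv(path, index=False, float_format="%.6f")


def season_state_counts(df: pd.DataFrame) -> tuple[int, int, int]:
    """(total, likely_breeding, nonbreeding) partition of an observation table."""
    n = len(df)
    n_lb = int((df["state"] == LIKELY_BREEDING).sum()) if n else 0
    return n, n_lb, n - n_lb
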