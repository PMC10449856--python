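"""Reading, writing and quality-filtering daily flux tables.

The on-disk format is the FLUXNET FULLSET daily CSV dialect: a comma-separated
table with a header row, a ``TIMESTAMP`` column in ``YYYYMMDD`` form, daily GPP
from the night-time partitioning (``GPP_NT_VUT_REF``, gC m-2 d-1) and the
fraction of good-quality NEE half-hours for the day (``NEE_VUT_REF_QC`` in
[0, 1]).  Missing values use the ``-9999`` sentinel.

Quality filtering follows the convention used for long-term trend studies of
eddy-covariance phenology: a day is "good" when its NEE quality fraction
reaches a per-day cutoff (default 0.8, configurable — the FULLSET QC column is
a fraction, not a flag), a year is usable when strictly more than 70% of its
days are good, and a site enters trend analysis when it has strictly more than
10 usable years.
"""

from __future__ import annotations

import calendar
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MISSING_SENTINEL",
    "TIMESTAMP_COL",
    "GPP_COL",
    "QC_COL",
    "SchemaError",
    "DailyFluxSeries",
    "YearQuality",
    "read_daily_flux",
    "write_daily_flux",
    "assess_years",
    "select_trend_sites",
    "days_in_year",
]

MISSING_SENTINEL = -9999.0
TIMESTAMP_COL = "TIMESTAMP"
GPP_COL = "GPP_NT_VUT_REF"
QC_COL = "NEE_VUT_REF_QC"

_SITE_FROM_NAME = re.compile(r"^(?:FLX|AMF|ICOS)_([A-Za-z]{2}-[A-Za-z0-9]{3})_")


class SchemaError(ValueError):
    """A required column is missing or malformed in a flux table."""


def days_in_year(year: int) -> int:
    return 366 if calendar.isleap(year) else 365


@dataclass
class DailyFluxSeries:
    """Daily GPP record for one eddy-covariance site.

    ``frame`` has columns ``date`` (datetime64), ``gpp`` (gC m-2 d-1, NaN for
    missing) and ``nee_qc`` (fraction of good-quality NEE half-hours in [0, 1],
    NaN for missing).  Dates are strictly increasing; days may be absent.
    """

    site_id: str
    frame: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        required = {"date", "gpp", "nee_qc"}
        missing = required - set(self.frame.columns)
        if missing:
            raise SchemaError(f"frame missing columns: {sorted(missing)}")
        self.frame = self.frame.sort_values("date").reset_index(drop=True)
        dates = self.frame["date"]
        if dates.duplicated().any():
            raise ValueError("duplicate dates in daily series")
        qc = self.frame["nee_qc"]
        bad_qc = qc.notna() & ((qc < 0) | (qc > 1))
        if bad_qc.any():
            raise ValueError("nee_qc values outside [0, 1]")

    def years(self) -> list[int]:
        """Calendar years touched by the record, ascending."""
        return sorted(self.frame["date"].dt.year.unique().tolist())

    def full_years(self) -> list[int]:
        """Years for which every calendar day has a row (values may be NaN)."""
        counts = self.frame.groupby(self.frame["date"].dt.year).size()
        return [int(y) for y, n in counts.items() if n == days_in_year(int(y))]

    def year_frame(self, year: int) -> pd.DataFrame:
        """The focal year reindexed onto its complete daily calendar.

        Absent days appear with NaN gpp/nee_qc; a ``doy`` column is attached.
        """
        idx = pd.date_range(f"{year}-01-01", f"{year}-12-31", freq="D")
        sub = self.frame[self.frame["date"].dt.year == year].set_index("date")
        out = sub.reindex(idx)
        out.index.name = "date"
        out = out.reset_index()
        out["doy"] = out["date"].dt.dayofyear
        return out


def _site_from_path(path: Path) -> str:
    m = _SITE_FROM_NAME.match(path.stem)
    return m.group(1) if m else path.stem


def read_daily_flux(
    path: str | Path,
    dialect: str = "fluxnet-fullset",
    site_id: str | None = None,
) -> DailyFluxSeries:
    """Read a daily flux CSV in the FLUXNET FULLSET dialect.

    -9999 sentinels are mapped to missing, dates parsed from YYYYMMDD, and the
    result is sorted by date regardless of row order on disk.
    """
    if dialect != "fluxnet-fullset":
        raise ValueError(f"unknown dialect: {dialect!r}")
    path = Path(path)
    raw = pd.read_csv(path)
    for col in (TIMESTAMP_COL, GPP_COL, QC_COL):
        if col not in raw.columns:
            raise SchemaError(f"{path.name}: required column {col!r} not found")
    dates = pd.to_datetime(raw[TIMESTAMP_COL].astype(str), format="%Y%m%d", errors="coerce")
    if dates.isna().any():
        row = int(np.flatnonzero(dates.isna().to_numpy())[0])
        # +2: one for the header line, one for 1-based line numbering
        raise ValueError(
            f"{path.name}: unparseable TIMESTAMP {raw[TIMESTAMP_COL].iloc[row]!r} "
            f"on line {row + 2}"
        )
    frame = pd.DataFrame(
        {
            "date": dates,
            "gpp": pd.to_numeric(raw[GPP_COL], errors="coerce"),
            "nee_qc": pd.to_numeric(raw[QC_COL], errors="coerce"),
        }
    )
    frame.loc[frame["gpp"] <= MISSING_SENTINEL, "gpp"] = np.nan
    frame.loc[frame["nee_qc"] <= MISSING_SENTINEL, "nee_qc"] = np.nan
    return DailyFluxSeries(site_id or _site_from_path(path), frame)


def write_daily_flux(series: DailyFluxSeries, path: str | Path) -> Path:
    """Write a series back to the FULLSET CSV dialect (-9999 for missing)."""
    path = Path(path)
    out = pd.DataFrame(
        {
            TIMESTAMP_COL: series.frame["date"].dt.strftime("%Y%m%d"),
            GPP_COL: series.frame["gpp"].round(6).fillna(MISSING_SENTINEL),
            QC_COL: series.frame["nee_qc"].round(6).fillna(MISSING_SENTINEL),
        }
    )
    out.to_csv(path, index=False, float_format="%.6f")
    return path


@dataclass(frozen=True)
class YearQuality:
    """Good-day accounting for one calendar year of one site."""

    year: int
    frac_good_days: float
    usable: bool
    n_good: int = 0
    n_days: int = 0


def assess_years(
    series: DailyFluxSeries,
    good_day_rule: float = 0.8,
    qc_year_threshold: float = 0.7,
) -> list[YearQuality]:
    """Classify each calendar year as usable or not.

    A day is good when ``nee_qc >= good_day_rule``; a year is usable when
    good days / days-in-year is strictly greater than ``qc_year_threshold``
    (the "more than 70% of days" rule).  Days missing from the record, or with
    missing nee_qc, count as not good.  Leap years use 366 as denominator.
    """
    out: list[YearQuality] = []
    years = series.frame["date"].dt.year
    good = series.frame["nee_qc"] >= good_day_rule
    for year in series.years():
        n_days = days_in_year(year)
        n_good = int(good[years == year].sum())
        frac = n_good / n_days
        out.append(
            YearQuality(
                year=year,
                frac_good_days=frac,
                usable=frac > qc_year_threshold,
                n_good=n_good,
                n_days=n_days,
            )
        )
    return out


def select_trend_sites(
    quality: Mapping[str, Sequence[YearQuality]],
    min_years: int = 10,
) -> list[str]:
    """Sites with strictly more than ``min_years`` usable years, sorted.

    Mirrors the "more than 10 years of quality data" site-selection rule, so a
    site with exactly ``min_years`` usable years is excluded.
    """
    keep = [
        site
        for site, yqs in quality.items()
        if sum(1 for q in yqs if q.usable) > min_years
    ]
    return sorted(keep)


def usable_years(
    series: DailyFluxSeries,
    good_day_rule: float = 0.8,
    qc_year_threshold: float = 0.7,
) -> list[int]:
    """Convenience: the usable calendar years of a series."""
    return [q.year for q in assess_years(series, good_day_rule, qc_year_threshold) if q.usable]
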