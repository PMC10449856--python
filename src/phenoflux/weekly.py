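"""Weekly GPP trends and their coupling to phenological shifts.

Weeks are redefined from the first day of the year — week w covers DOY
7(w-1)+1 .. 7w — so the same days of year are pooled in every year and
calendar weekday drift cannot misalign the regression.  DOY 365 and the leap
day are excluded (weeks 1..52 of exactly 7 days each).  For each week all
(year, daily GPP) observations of its member days are pooled — about 7x the
number of years — and GPP is regressed on year by ordinary least squares; a
trend is significant at p < 0.05 (two-sided t-test).

Coupling analyses relate, across sites, the trend in a phenological date to
the local GPP trend: for SOS/EOS the mean weekly GPP slope within +-2 weeks
of the site's mean transition date, regressed on the PTD trend per threshold
(and for the derivative method); for GSL the *sum* of weekly GPP slopes over
the weeks between mean SOS and mean EOS, regressed on the GSL trend.  The
regression slope is the sensitivity of GPP trends to PTD trends and R² its
strength.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "week_of_doy",
    "weekly_trends",
    "mean_ptds",
    "ptd_gpp_coupling",
    "gsl_seasonal_coupling",
]

N_WEEKS = 52


def week_of_doy(doy: int) -> int | None:
    """Week index (1..52) of a day of year; None for DOY > 364."""
    if 1 <= doy <= 7 * N_WEEKS:
        return (doy - 1) // 7 + 1
    return None


def weekly_trends(series, alpha: float = 0.05, min_years: int = 3) -> pd.DataFrame:
    """Across-year OLS trend of daily GPP for each of the 52 calendar weeks.

    Columns: site, week, slope (gC m-2 d-1 yr-1), p_value, n_points, n_years,
    significant, issues.  Weeks observed in fewer than ``min_years`` years get
    NaN slopes with a reason.
    """
    frame = series.frame.copy()
    frame["year"] = frame["date"].dt.year
    frame["doy"] = frame["date"].dt.dayofyear
    frame = frame[frame["doy"] <= 7 * N_WEEKS].dropna(subset=["gpp"])
    frame["week"] = ((frame["doy"] - 1) // 7 + 1).astype(int)
    rows = []
    for week in range(1, N_WEEKS + 1):
        sub = frame[frame["week"] == week]
        n_years = sub["year"].nunique()
        row = {
            "site": series.site_id,
            "week": week,
            "slope": np.nan,
            "p_value": np.nan,
            "n_points": len(sub),
            "n_years": n_years,
            "significant": False,
            "issues": "",
        }
        if n_years < min_years:
            row["issues"] = f"only {n_years} years with data (need {min_years})"
        else:
            fit = stats.linregress(sub["year"].to_numpy(float), sub["gpp"].to_numpy(float))
            row.update(
                slope=float(fit.slope),
                p_value=float(fit.pvalue),
                significant=bool(fit.pvalue < alpha),
            )
        rows.append(row)
    return pd.DataFrame(rows)


def mean_ptds(ptd_table: pd.DataFrame) -> pd.DataFrame:
    """Across-year mean SOS/EOS per site x method x threshold."""
    tab = ptd_table.dropna(subset=["sos", "eos"]).copy()
    grouped = (
        tab.groupby(["site", "method", "threshold"], dropna=False)[["sos", "eos"]]
        .mean()
        .reset_index()
        .rename(columns={"sos": "mean_sos", "eos": "mean_eos"})
    )
    return grouped


def _weeks_in_window(lo_day: float, hi_day: float) -> list[int]:
    """Weeks whose 7-day span intersects [lo_day, hi_day] (clipped to 1..52)."""
    weeks = []
    for w in range(1, N_WEEKS + 1):
        start, stop = 7 * (w - 1) + 1, 7 * w
        if stop >= lo_day and start <= hi_day:
            weeks.append(w)
    return weeks


def _site_week_slopes(weekly: pd.DataFrame, weeks: list[int]) -> np.ndarray:
    sub = weekly[weekly["week"].isin(weeks)]
    return sub["slope"].dropna().to_numpy(dtype=float)


def _fit_across_sites(points: list[tuple[float, float]]) -> dict:
    xs = np.array([p[0] for p in points], dtype=float)
    ys = np.array([p[1] for p in points], dtype=float)
    out = {"slope": np.nan, "r_squared": np.nan, "intercept": np.nan, "n_sites": len(points), "issues": ""}
    if len(points) < 3:
        out["issues"] = f"only {len(points)} sites with both quantities (need 3)"
        return out
    if np.ptp(xs) == 0:
        out["issues"] = "degenerate: no variance in PTD trends across sites"
        return out
    fit = stats.linregress(xs, ys)
    out.update(slope=float(fit.slope), intercept=float(fit.intercept), r_squared=float(fit.rvalue**2))
    return out


def ptd_gpp_coupling(
    trend_table: pd.DataFrame,
    weekly_tables: Mapping[str, pd.DataFrame],
    mean_ptd_table: pd.DataFrame,
    window_weeks: int = 2,
    agg: str = "mean",
) -> pd.DataFrame:
    """Sensitivity of GPP trends around PTDs to the PTD trends, across sites.

    For each metric (SOS, EOS) and each threshold (plus the derivative
    method): x = the site's PTD trend in days/decade, y = the mean (or sum,
    via ``agg``) of its weekly GPP slopes for weeks intersecting
    [mean PTD - 7*window_weeks, mean PTD + 7*window_weeks].  OLS of y on x
    across sites gives the coupling slope and R².
    """
    if agg not in ("mean", "sum"):
        raise ValueError("agg must be 'mean' or 'sum'")
    rows = []
    cells = (
        trend_table[["method", "threshold"]]
        .drop_duplicates()
        .itertuples(index=False)
    )
    for method, threshold in cells:
        for metric, col in (("SOS", "mean_sos"), ("EOS", "mean_eos")):
            points = []
            for site, weekly in weekly_tables.items():
                tsel = trend_table[
                    (trend_table["site"] == site)
                    & (trend_table["metric"] == metric)
                    & (trend_table["method"] == method)
                ]
                msel = mean_ptd_table[
                    (mean_ptd_table["site"] == site) & (mean_ptd_table["method"] == method)
                ]
                if threshold is not None and not (isinstance(threshold, float) and np.isnan(threshold)):
                    tsel = tsel[np.isclose(tsel["threshold"].astype(float), float(threshold))]
                    msel = msel[np.isclose(msel["threshold"].astype(float), float(threshold))]
                if tsel.empty or msel.empty or not np.isfinite(tsel["slope_per_decade"].iloc[0]):
                    continue
                centre = float(msel[col].iloc[0])
                slopes = _site_week_slopes(
                    weekly, _weeks_in_window(centre - 7 * window_weeks, centre + 7 * window_weeks)
                )
                if len(slopes) == 0:
                    continue
                y = float(np.mean(slopes) if agg == "mean" else np.sum(slopes))
                points.append((float(tsel["slope_per_decade"].iloc[0]), y))
            fit = _fit_across_sites(points)
            rows.append({"metric": metric, "method": method, "threshold": threshold, **fit})
    return pd.DataFrame(rows)


def gsl_seasonal_coupling(
    trend_table: pd.DataFrame,
    weekly_tables: Mapping[str, pd.DataFrame],
    mean_ptd_table: pd.DataFrame,
) -> pd.DataFrame:
    """Coupling of GSL trends to summed in-season weekly GPP trends.

    y = sum of weekly GPP slopes for the weeks between a site's mean SOS and
    mean EOS (weeks partially covered are included); x = the site's GSL trend
    in days/decade.  OLS across sites per threshold/derivative cell.
    """
    rows = []
    cells = (
        trend_table[["method", "threshold"]]
        .drop_duplicates()
        .itertuples(index=False)
    )
    for method, threshold in cells:
        points = []
        for site, weekly in weekly_tables.items():
            tsel = trend_table[
                (trend_table["site"] == site)
                & (trend_table["metric"] == "GSL")
                & (trend_table["method"] == method)
            ]
            msel = mean_ptd_table[
                (mean_ptd_table["site"] == site) & (mean_ptd_table["method"] == method)
            ]
            if threshold is not None and not (isinstance(threshold, float) and np.isnan(threshold)):
                tsel = tsel[np.isclose(tsel["threshold"].astype(float), float(threshold))]
                msel = msel[np.isclose(msel["threshold"].astype(float), float(threshold))]
            if tsel.empty or msel.empty or not np.isfinite(tsel["slope_per_decade"].iloc[0]):
                continue
            lo, hi = float(msel["mean_sos"].iloc[0]), float(msel["mean_eos"].iloc[0])
            slopes = _site_week_slopes(weekly, _weeks_in_window(lo, hi))
            if len(slopes) == 0:
                continue
            points.append((float(tsel["slope_per_decade"].iloc[0]), float(np.sum(slopes))))
        fit = _fit_across_sites(points)
        rows.append({"metric": "GSL", "method": method, "threshold": threshold, **fit})
    return pd.DataFrame(rows)
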