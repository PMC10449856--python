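"""Phenological transition dates from smoothed annual GPP curves.

Two extraction families are implemented:

* **Threshold method** — the smoothed year is min-max normalized to [0, 1];
  SOS is the upward crossing of a fixed threshold nearest to (and before) the
  seasonal peak, EOS the downward crossing nearest to (and after) it.  The
  default grid runs 0.1 to 0.7 in steps of 0.05 (13 thresholds).  Crossings
  are located at fractional days by linear interpolation between bracketing
  days; an integer-day mode is available.
* **Derivative method** — SOS/EOS are the days of the maximum/minimum of the
  first derivative of the smoothed curve, searched on the rise and fall of
  the governing season.

Years whose season straddles the calendar boundary (e.g. southern-hemisphere
sites) are handled by continuing the crossing search into the neighbouring
year's normalized curve; the resulting day coordinate is signed relative to
Jan 1 of the focal year (<= 0 means the previous year, > days-in-year the
next).  Search depth is one neighbour.  Bimodal years get a single SOS/EOS
assigned to the most productive growing season, where seasons are maximal
runs of normalized GPP above a floor (default 0.2) and productivity is the
integral of smoothed GPP over the run; ties go to the earliest run.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .flux_io import DailyFluxSeries, days_in_year
from .smoothing import (
    DEFAULT_KNOTS,
    DEFAULT_PAD_DAYS,
    SmoothedYear,
    direct_smooth,
    integral_smooth,
)

__all__ = [
    "DEFAULT_THRESHOLDS",
    "NormalizedYear",
    "PTDRecord",
    "PtdConfig",
    "DegenerateYearError",
    "NoSeasonError",
    "normalize_year",
    "governing_peak",
    "threshold_ptd",
    "derivative_ptd",
    "extract_all",
]

#: the default threshold grid: 0.1 to 0.7 every 0.05
DEFAULT_THRESHOLDS: tuple[float, ...] = tuple(
    np.round(np.arange(0.10, 0.7001, 0.05), 2)
)


class DegenerateYearError(ValueError):
    """The smoothed year is flat (or has no growing season) — no PTDs exist."""


class NoSeasonError(ValueError):
    """A threshold is never crossed in the focal or neighbouring years."""


@dataclass
class NormalizedYear:
    """Min-max normalized smoothed GPP for one calendar year."""

    site_id: str
    year: int
    doy: np.ndarray
    gpp_norm: np.ndarray
    peak_doy: int
    year_min: float
    year_max: float


@dataclass(frozen=True)
class PTDRecord:
    """SOS/EOS/GSL for one (site, year, method, threshold).

    ``sos``/``eos`` are signed day coordinates relative to Jan 1 of the focal
    year; sos <= 0 places the start of season in the previous calendar year,
    eos > days-in-year in the next.  ``gsl = eos - sos`` by construction.
    """

    site_id: str
    year: int
    method: str  # "threshold" | "derivative"
    threshold: float | None
    sos: float
    eos: float

    def __post_init__(self) -> None:
        if self.eos <= self.sos:
            raise ValueError(f"EOS ({self.eos}) must exceed SOS ({self.sos})")

    @property
    def gsl(self) -> float:
        return self.eos - self.sos


def governing_peak(
    doy: np.ndarray,
    gpp_norm: np.ndarray,
    gpp_smooth: np.ndarray,
    season_floor: float = 0.2,
) -> int:
    """Day of the peak of the most productive growing season.

    Growing seasons are maximal runs with ``gpp_norm >= season_floor``; the
    run with the largest integral of smoothed GPP governs (ties: earliest
    run).  Unimodal years reduce to the global argmax.
    """
    above = gpp_norm >= season_floor
    if not above.any():
        raise DegenerateYearError(f"no day reaches the season floor {season_floor}")
    # maximal runs of True
    edges = np.flatnonzero(np.diff(np.concatenate(([0], above.view(np.int8), [0]))))
    starts, stops = edges[::2], edges[1::2]
    best, best_integral = None, -np.inf
    for a, b in zip(starts, stops):
        integral = float(np.sum(gpp_smooth[a:b]))
        if integral > best_integral + 1e-12:
            best, best_integral = (a, b), integral
    a, b = best
    return int(doy[a + int(np.argmax(gpp_norm[a:b]))])


def normalize_year(smooth: SmoothedYear, season_floor: float = 0.2) -> NormalizedYear:
    """Min-max normalize a smoothed year and locate its governing peak."""
    g = np.asarray(smooth.gpp_smooth, dtype=float)
    mn, mx = float(g.min()), float(g.max())
    if mx - mn <= 1e-9 * max(abs(mx), 1.0):
        raise DegenerateYearError(
            f"{smooth.site_id} {smooth.year}: flat smoothed year (max == min)"
        )
    norm = (g - mn) / (mx - mn)
    peak = governing_peak(smooth.doy, norm, g, season_floor)
    return NormalizedYear(
        site_id=smooth.site_id,
        year=smooth.year,
        doy=np.asarray(smooth.doy),
        gpp_norm=norm,
        peak_doy=peak,
        year_min=mn,
        year_max=mx,
    )


def _crossings(values: np.ndarray, threshold: float, interpolate: bool) -> tuple[list[float], list[float]]:
    """(upward, downward) crossing day coordinates on a 1..n daily grid."""
    v = np.asarray(values, dtype=float)
    ups: list[float] = []
    downs: list[float] = []
    for i in range(len(v) - 1):
        a, b = v[i], v[i + 1]
        day = float(i + 1)
        if a < threshold <= b:
            frac = (threshold - a) / (b - a)
            ups.append(day + frac if interpolate else round(day + frac))
        elif a >= threshold > b:
            frac = (a - threshold) / (a - b)
            downs.append(day + frac if interpolate else round(day + frac))
    return ups, downs


def threshold_ptd(
    norm: NormalizedYear,
    threshold: float,
    prev: NormalizedYear | None = None,
    nxt: NormalizedYear | None = None,
    interpolate: bool = True,
) -> PTDRecord:
    """Threshold-method SOS/EOS for one normalized year.

    When the curve is above the threshold already at the year boundary (the
    crossing happened in a neighbouring year) the search continues into the
    previous/next year's normalized curve and the crossing day is reported as
    a signed coordinate of the focal year.
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError(f"threshold must be in (0, 1), got {threshold}")
    ups, downs = _crossings(norm.gpp_norm, threshold, interpolate)
    peak = norm.peak_doy
    n_focal = days_in_year(norm.year)

    sos_candidates = [u for u in ups if u <= peak]
    if sos_candidates:
        sos = max(sos_candidates)  # nearest upward crossing before the peak
    elif prev is not None:
        prev_ups, _ = _crossings(prev.gpp_norm, threshold, interpolate)
        if not prev_ups:
            raise NoSeasonError(
                f"{norm.site_id} {norm.year}: threshold {threshold} has no SOS "
                "crossing in focal or previous year"
            )
        sos = max(prev_ups) - days_in_year(prev.year)  # signed: <= 0
    else:
        raise NoSeasonError(
            f"{norm.site_id} {norm.year}: no SOS crossing before the peak and "
            "no previous year to search"
        )

    eos_candidates = [d for d in downs if d >= peak]
    if eos_candidates:
        eos = min(eos_candidates)  # nearest downward crossing after the peak
    elif nxt is not None:
        _, nxt_downs = _crossings(nxt.gpp_norm, threshold, interpolate)
        if not nxt_downs:
            raise NoSeasonError(
                f"{norm.site_id} {norm.year}: threshold {threshold} has no EOS "
                "crossing in focal or next year"
            )
        eos = min(nxt_downs) + n_focal  # signed: > days-in-year
    else:
        raise NoSeasonError(
            f"{norm.site_id} {norm.year}: no EOS crossing after the peak and "
            "no next year to search"
        )
    return PTDRecord(
        site_id=norm.site_id,
        year=norm.year,
        method="threshold",
        threshold=float(threshold),
        sos=float(sos),
        eos=float(eos),
    )


def derivative_ptd(smooth: SmoothedYear, season_floor: float = 0.2) -> PTDRecord:
    """Derivative-method SOS/EOS: extrema of d(GPP)/d(day).

    The search runs on the focal year's daily grid, restricted to the rise
    (days up to the governing peak) for SOS and the fall (days from the peak)
    for EOS.  Curves with near-constant derivative on a flank (linear ramps)
    make these extrema ill-defined; results there are boundary artefacts.
    """
    norm = normalize_year(smooth, season_floor)
    deriv = smooth.gpp_deriv
    if deriv is None:
        deriv = np.gradient(smooth.gpp_smooth, smooth.doy)
    doy = np.asarray(smooth.doy)
    rise = doy <= norm.peak_doy
    fall = doy >= norm.peak_doy
    sos = float(doy[rise][np.argmax(deriv[rise])])
    eos = float(doy[fall][np.argmin(deriv[fall])])
    if eos <= sos:
        raise DegenerateYearError(
            f"{smooth.site_id} {smooth.year}: derivative extrema collapse "
            "(flat or non-seasonal year)"
        )
    return PTDRecord(
        site_id=smooth.site_id,
        year=smooth.year,
        method="derivative",
        threshold=None,
        sos=sos,
        eos=eos,
    )


@dataclass(frozen=True)
class PtdConfig:
    """Configuration for whole-series PTD extraction."""

    thresholds: tuple[float, ...] = DEFAULT_THRESHOLDS
    smoothing: str = "integral"  # "integral" | "spline" | "lowess"
    knots: int = DEFAULT_KNOTS
    lowess_frac: float = 0.5
    pad_days: int = DEFAULT_PAD_DAYS
    season_floor: float = 0.2
    include_derivative: bool = True
    interpolate: bool = True


def _smooth_year(series: DailyFluxSeries, year: int, config: PtdConfig) -> SmoothedYear:
    if config.smoothing == "integral":
        return integral_smooth(series, year, config.knots, config.pad_days)
    if config.smoothing == "spline":
        return direct_smooth(series, year, "spline", config.knots, config.pad_days)
    if config.smoothing == "lowess":
        return direct_smooth(series, year, "lowess", config.lowess_frac, config.pad_days)
    raise ValueError(f"unknown smoothing {config.smoothing!r}")


def extract_all(
    series: DailyFluxSeries,
    config: PtdConfig | None = None,
    years: Sequence[int] | None = None,
) -> pd.DataFrame:
    """PTD table for a whole series: one row per (year, threshold) + derivative.

    Per-year failures (flat years, uncrossable thresholds) are recorded in an
    ``issues`` column with NaN dates rather than aborting the site.  Columns:
    site, year, method, threshold, sos, eos, gsl, issues.
    """
    config = config or PtdConfig()
    if years is None:
        years = series.full_years()
    rows: list[dict] = []

    def _row(year: int, method: str, threshold: float | None, rec: PTDRecord | None, issue: str = "") -> dict:
        return {
            "site": series.site_id,
            "year": year,
            "method": method,
            "threshold": threshold,
            "sos": rec.sos if rec else np.nan,
            "eos": rec.eos if rec else np.nan,
            "gsl": rec.gsl if rec else np.nan,
            "issues": issue,
        }

    normalized: dict[int, NormalizedYear | None] = {}
    smoothed: dict[int, SmoothedYear | None] = {}
    for year in years:
        try:
            sm = _smooth_year(series, year, config)
            smoothed[year] = sm
            normalized[year] = normalize_year(sm, config.season_floor)
        except (ValueError, DegenerateYearError) as exc:
            smoothed[year] = None
            normalized[year] = None
            rows.append(_row(year, "all", None, None, f"smoothing failed: {exc}"))

    for year in years:
        norm = normalized.get(year)
        if norm is None:
            continue
        prev = normalized.get(year - 1)
        nxt = normalized.get(year + 1)
        for threshold in config.thresholds:
            try:
                rec = threshold_ptd(norm, threshold, prev, nxt, config.interpolate)
                rows.append(_row(year, "threshold", threshold, rec))
            except (NoSeasonError, ValueError) as exc:
                rows.append(_row(year, "threshold", threshold, None, str(exc)))
        if config.include_derivative:
            try:
                rec = derivative_ptd(smoothed[year], config.season_floor)
                rows.append(_row(year, "derivative", None, rec))
            except (DegenerateYearError, ValueError) as exc:
                rows.append(_row(year, "derivative", None, None, str(exc)))
    return pd.DataFrame(rows)
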