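"""Synthetic multi-year daily GPP series with known phenology.

The seasonal cycle is a double logistic — the difference of two rising
logistic branches,

    bump(t) = 1/(1 + exp(-k_sos (t - t_sos))) - 1/(1 + exp(-k_eos (t - t_eos))),

whose inflection points ``t_sos`` / ``t_eos`` are the analytic half-height
days of the rise and fall.  That makes exact oracles available: the day where
the normalized curve crosses a threshold comes from inverting one logistic
branch in closed form (:func:`true_ptd`), so downstream extraction code can be
checked against ground truth instead of against itself.

Year-over-year change is imposed linearly: inflection days shift by
``sos_shift_rate`` / ``eos_shift_rate`` days per year, the amplitude by
``amplitude_rate``, and individual calendar weeks can be given additive GPP
trends (``weekly_trend_overrides``) to emulate localized productivity change.
Noise is Gaussian and heteroscedastic (sd proportional to the instantaneous
noise-free signal, floored at 5% of the amplitude, as flux noise scales with
flux magnitude), and a fraction of days can be flagged poor-quality.

A circular phase shift of the day-of-year axis emulates southern-hemisphere
sites whose growing season straddles the calendar-year boundary.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .flux_io import DailyFluxSeries, days_in_year, write_daily_flux

__all__ = [
    "SeasonSpec",
    "TrendSpec",
    "NoiseSpec",
    "NoCrossingError",
    "generate_series",
    "true_ptd",
    "write_with_sidecar",
]

_PERIOD = 365.0  # wrap period for the circular phase shift


class NoCrossingError(ValueError):
    """The requested threshold is never reached by the seasonal curve."""


@dataclass(frozen=True)
class SeasonSpec:
    """Shape of the noise-free seasonal GPP cycle.

    amplitude_gpp : peak GPP above baseline, gC m-2 d-1
    baseline_gpp : off-season GPP, gC m-2 d-1
    sos_inflection_doy / eos_inflection_doy : half-height days of the rise and
        fall of the double logistic (before any phase shift), day of year
    sos_slope / eos_slope : logistic steepness, d-1
    phase_shift_doy : circular shift of the DOY axis; ~182 puts the peak near
        the year boundary (southern hemisphere), 0 is northern
    """

    amplitude_gpp: float = 8.0
    baseline_gpp: float = 0.5
    sos_inflection_doy: float = 120.0
    eos_inflection_doy: float = 280.0
    sos_slope: float = 0.06
    eos_slope: float = 0.06
    phase_shift_doy: float = 0.0

    def __post_init__(self) -> None:
        if self.amplitude_gpp <= 0:
            raise ValueError("amplitude_gpp must be > 0")
        if self.baseline_gpp < 0:
            raise ValueError("baseline_gpp must be >= 0")
        if self.eos_inflection_doy <= self.sos_inflection_doy:
            raise ValueError("eos_inflection_doy must exceed sos_inflection_doy")
        if self.sos_slope <= 0 or self.eos_slope <= 0:
            raise ValueError("logistic slopes must be > 0")


@dataclass(frozen=True)
class TrendSpec:
    """Linear year-over-year change imposed on the seasonal cycle."""

    sos_shift_rate: float = 0.0  # days yr-1; negative = advancing spring
    eos_shift_rate: float = 0.0  # days yr-1
    amplitude_rate: float = 0.0  # gC m-2 d-1 yr-1
    weekly_trend_overrides: dict[int, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        bad = [w for w in self.weekly_trend_overrides if not 1 <= int(w) <= 52]
        if bad:
            raise ValueError(f"weekly overrides only for weeks 1-52, got {bad}")


@dataclass(frozen=True)
class NoiseSpec:
    """Observation noise and data gaps."""

    noise_sd_frac: float = 0.0  # sd as a fraction of the daily signal
    gap_frac: float = 0.0  # fraction of days flagged poor-quality
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.gap_frac < 1:
            raise ValueError("gap_frac must be in [0, 1)")
        if self.noise_sd_frac < 0:
            raise ValueError("noise_sd_frac must be >= 0")


def _logistic(x: np.ndarray | float) -> np.ndarray | float:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -500, 500)))


def _bump(u: np.ndarray, t_sos: float, t_eos: float, k_sos: float, k_eos: float) -> np.ndarray:
    return _logistic(k_sos * (u - t_sos)) - _logistic(k_eos * (u - t_eos))


def _season_support(season: SeasonSpec) -> float:
    # span between the days where each branch is within ~exp(-6) of saturation
    return (
        season.eos_inflection_doy
        - season.sos_inflection_doy
        + 6.0 / season.sos_slope
        + 6.0 / season.eos_slope
    )


def _year_params(season: SeasonSpec, trend: TrendSpec, k: int) -> tuple[float, float, float]:
    """(t_sos, t_eos, amplitude) for year index k."""
    t_sos = season.sos_inflection_doy + k * trend.sos_shift_rate
    t_eos = season.eos_inflection_doy + k * trend.eos_shift_rate
    amp = season.amplitude_gpp + k * trend.amplitude_rate
    if t_eos <= t_sos:
        raise ValueError(f"year {k}: trend pushed EOS inflection before SOS")
    if amp <= 0:
        raise ValueError(f"year {k}: trend drove amplitude non-positive")
    return t_sos, t_eos, amp


def _wrapped_bump(
    doy: np.ndarray, season: SeasonSpec, t_sos: float, t_eos: float
) -> np.ndarray:
    """Seasonal bump on the calendar-day grid with circular phase shift.

    The bump is evaluated at the shifted coordinate and at its +-1-period
    images, so a season centred on the year boundary contributes its tail ends
    to both edges of the calendar year.
    """
    u = doy - season.phase_shift_doy
    total = np.zeros_like(u, dtype=float)
    for m in (-1.0, 0.0, 1.0):
        total += _bump(u + m * _PERIOD, t_sos, t_eos, season.sos_slope, season.eos_slope)
    return total


def noise_free_year(
    season: SeasonSpec, trend: TrendSpec, year_index: int, n_days: int = 365
) -> np.ndarray:
    """Noise-free daily GPP for year ``year_index`` on a 1..n_days grid.

    Rescaled so the grid maximum equals baseline + amplitude exactly.
    Weekly overrides are added after rescaling.
    """
    t_sos, t_eos, amp = _year_params(season, trend, year_index)
    doy = np.arange(1, n_days + 1, dtype=float)
    bump = _wrapped_bump(doy, season, t_sos, t_eos)
    peak = bump.max()
    if peak <= 0:
        raise ValueError("seasonal curve has no positive support inside the year")
    gpp = season.baseline_gpp + amp * bump / peak
    if trend.weekly_trend_overrides:
        week = ((doy - 1) // 7 + 1).astype(int)  # week 1 = DOY 1-7
        for w, rate in trend.weekly_trend_overrides.items():
            gpp[week == int(w)] += year_index * rate
    return gpp


def generate_series(
    season: SeasonSpec,
    trend: TrendSpec | None = None,
    noise: NoiseSpec | None = None,
    n_years: int = 1,
    start_year: int = 2000,
    site_id: str = "SYN-001",
    second_season: SeasonSpec | None = None,
) -> DailyFluxSeries:
    """Generate a multi-year daily GPP series with known phenology.

    ``second_season`` adds a smaller second growing season (bimodal years);
    its seasonal integral must be strictly smaller than the primary one so the
    "most productive season" is unambiguous.  Trends apply to the primary
    season only.
    """
    trend = trend or TrendSpec()
    noise = noise or NoiseSpec()
    if n_years < 1:
        raise ValueError("n_years must be >= 1")
    if season.phase_shift_doy % _PERIOD != 0 and _season_support(season) > 366:
        raise ValueError(
            "phase-shifted season support exceeds 366 days; the seasonal cycle "
            "would overlap its own wrap image"
        )
    if second_season is not None:
        primary_integral = season.amplitude_gpp * (
            season.eos_inflection_doy - season.sos_inflection_doy
        )
        second_integral = second_season.amplitude_gpp * (
            second_season.eos_inflection_doy - second_season.sos_inflection_doy
        )
        if second_integral >= primary_integral:
            raise ValueError("second season integral must be strictly smaller")

    rng = np.random.default_rng(noise.rng_seed)
    frames = []
    for k in range(n_years):
        year = start_year + k
        n_days = days_in_year(year)
        gpp = noise_free_year(season, trend, k, n_days)
        if second_season is not None:
            doy = np.arange(1, n_days + 1, dtype=float)
            bump2 = _wrapped_bump(
                doy,
                second_season,
                second_season.sos_inflection_doy,
                second_season.eos_inflection_doy,
            )
            peak2 = bump2.max()
            if peak2 > 0:
                gpp = gpp + second_season.amplitude_gpp * bump2 / peak2
        if noise.noise_sd_frac > 0:
            # sd scales with the instantaneous signal, floored at 5% of the
            # amplitude: partitioned GPP stays noisy even in the dormant season
            amp_k = season.amplitude_gpp + k * trend.amplitude_rate
            sd = np.maximum(noise.noise_sd_frac * gpp, 0.05 * amp_k)
            gpp = gpp + rng.normal(0.0, 1.0, n_days) * sd
        qc = np.ones(n_days)
        if noise.gap_frac > 0:
            gaps = rng.random(n_days) < noise.gap_frac
            qc[gaps] = 0.0
            gpp = np.where(gaps, np.nan, gpp)
        frames.append(
            pd.DataFrame(
                {
                    "date": pd.date_range(f"{year}-01-01", periods=n_days, freq="D"),
                    "gpp": gpp,
                    "nee_qc": qc,
                }
            )
        )
    return DailyFluxSeries(site_id, pd.concat(frames, ignore_index=True))


def true_ptd(
    season: SeasonSpec,
    trend: TrendSpec | None = None,
    year_index: int = 0,
    threshold: float = 0.5,
) -> tuple[float, float]:
    """Closed-form threshold-crossing days of the noise-free seasonal curve.

    Each logistic branch is inverted analytically: the rising branch gives
    SOS, the falling branch EOS, both as signed day coordinates of the focal
    year (a southern-hemisphere SOS may be <= 0, i.e. in the previous
    calendar year).  At threshold 0.5 the crossings are the inflection days
    themselves.
    """
    trend = trend or TrendSpec()
    if not 0.0 < threshold < 1.0:
        raise NoCrossingError(f"threshold must be in (0, 1), got {threshold}")
    t_sos, t_eos, _ = _year_params(season, trend, year_index)
    # reject thresholds above what either branch attains at the peak
    mid = 0.5 * (t_sos + t_eos)
    rise_max = float(_logistic(season.sos_slope * (mid - t_sos)))
    fall_max = float(1.0 - _logistic(season.eos_slope * (mid - t_eos)))
    if threshold >= min(rise_max, fall_max):
        raise NoCrossingError(
            f"threshold {threshold} is not reached by the seasonal curve "
            f"(branch maxima ~{min(rise_max, fall_max):.4f})"
        )
    logit = math.log(threshold / (1.0 - threshold))
    sos = t_sos + logit / season.sos_slope
    eos = t_eos - logit / season.eos_slope
    # apply the phase shift, mapped so the season peak lands inside the year
    peak = mid + season.phase_shift_doy
    m = math.floor((peak - 1.0) / _PERIOD) if (peak < 1 or peak > _PERIOD) else 0
    offset = season.phase_shift_doy - m * _PERIOD
    return sos + offset, eos + offset


def write_with_sidecar(
    series: DailyFluxSeries,
    path: str | Path,
    season: SeasonSpec,
    trend: TrendSpec,
    noise: NoiseSpec,
) -> tuple[Path, Path]:
    """Write the series as FULLSET CSV plus a key-value parameter sidecar."""
    csv_path = write_daily_flux(series, path)
    sidecar = csv_path.with_suffix(".params.txt")
    lines = [f"site_id = {series.site_id}"]
    for name, spec in (("season", season), ("trend", trend), ("noise", noise)):
        for key, val in vars(spec).items():
            lines.append(f"{name}.{key} = {val}")
    sidecar.write_text("\n".join(lines) + "\n")
    return csv_path, sidecar
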