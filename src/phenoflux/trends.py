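"""Robust trends of phenological transition dates.

Trends are Theil-Sen slopes: the median of all pairwise slopes
(y_j - y_i)/(t_j - t_i) over years t, which is resistant to the outliers that
short eddy-covariance records are prone to.  Confidence intervals come from
Sen's rank-based procedure (order statistics of the enumerated pairwise
slopes, ranks set by the normal approximation of the Mann-Kendall statistic
with tie correction) and p-values from the two-sided Mann-Kendall test.
Slopes are reported both per year and per decade (x10).

The growing-season-length trend is deliberately the trend OF the per-year
difference EOS - SOS, not the difference of the two trends: with a median
estimator those are not the same quantity.

Because the trend of a site can vary with the threshold the PTDs were
extracted at, a site's trend is classified *uncertain* when the standard
deviation of its per-threshold slopes exceeds a cutoff (0.5 days/decade for
SOS and EOS, 1 day/decade for GSL); the derivative-method trend is reported
alongside but excluded from that spread.  A year-resampling bootstrap puts a
confidence interval on the spread itself.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "TrendResult",
    "UncertaintyFlag",
    "DEFAULT_SIGMA_CUTOFFS",
    "theil_sen",
    "mann_kendall",
    "gsl_trend",
    "trends_by_threshold",
    "classify_uncertainty",
]

#: uncertainty cutoffs on the across-threshold std of trends, days/decade
DEFAULT_SIGMA_CUTOFFS: Mapping[str, float] = {"SOS": 0.5, "EOS": 0.5, "GSL": 1.0}


@dataclass(frozen=True)
class TrendResult:
    """Theil-Sen trend of one annual metric series."""

    slope: float  # days yr-1
    ci_low: float
    ci_high: float
    p_value: float
    n_pairs: int
    n_years: int

    @property
    def slope_per_decade(self) -> float:
        return 10.0 * self.slope

    def __post_init__(self) -> None:
        if np.isfinite(self.ci_low) and not (
            self.ci_low - 1e-12 <= self.slope <= self.ci_high + 1e-12
        ):
            raise ValueError("slope outside its confidence interval")


@dataclass(frozen=True)
class UncertaintyFlag:
    """Threshold-dependence classification of one site's metric trend."""

    site_id: str
    metric: str
    sigma_trend: float  # std of per-threshold slopes, days/decade
    flag: bool | None  # None when undefined
    bootstrap_ci: tuple[float, float] | None
    n_thresholds: int
    reason: str = ""


def mann_kendall(values: Sequence[float]) -> tuple[float, float]:
    """Two-sided Mann-Kendall trend test.

    Returns (S, p) using the normal approximation with tie correction and
    continuity correction; the series is assumed ordered by time.
    """
    y = np.asarray(values, dtype=float)
    n = len(y)
    if n < 2:
        raise ValueError("Mann-Kendall needs at least 2 observations")
    s = 0.0
    for i in range(n - 1):
        s += np.sign(y[i + 1 :] - y[i]).sum()
    _, counts = np.unique(y, return_counts=True)
    ties = counts[counts > 1]
    var = (n * (n - 1) * (2 * n + 5) - np.sum(ties * (ties - 1) * (2 * ties + 5))) / 18.0
    if var <= 0:
        return float(s), 1.0
    if s > 0:
        z = (s - 1) / np.sqrt(var)
    elif s < 0:
        z = (s + 1) / np.sqrt(var)
    else:
        z = 0.0
    return float(s), float(2.0 * stats.norm.sf(abs(z)))


def _pairwise_slopes(years: np.ndarray, values: np.ndarray) -> np.ndarray:
    """All (y_j - y_i)/(t_j - t_i) for i<j with distinct years."""
    dy = values[:, None] - values[None, :]
    dt = years[:, None] - years[None, :]
    iu = np.triu_indices(len(years), k=1)
    dy, dt = dy[iu], dt[iu]
    ok = dt != 0
    return dy[ok] / dt[ok]


def theil_sen(
    years: Sequence[float],
    values: Sequence[float],
    confidence: float = 0.95,
) -> TrendResult:
    """Theil-Sen slope, Sen confidence interval and Mann-Kendall p.

    Missing values are dropped pairwise; slopes use the actual calendar-year
    gaps, so series with missing years remain valid.
    """
    t = np.asarray(years, dtype=float)
    y = np.asarray(values, dtype=float)
    ok = np.isfinite(t) & np.isfinite(y)
    t, y = t[ok], y[ok]
    if len(t) < 2:
        raise ValueError("need at least 2 observations")
    if np.ptp(t) == 0:
        raise ValueError("all observations share one year; slope undefined")
    order = np.argsort(t, kind="stable")
    t, y = t[order], y[order]
    slope, _, lo, hi = stats.theilslopes(y, t, alpha=confidence)
    _, p = mann_kendall(y)
    n_pairs = int(np.sum((t[:, None] != t[None, :])[np.triu_indices(len(t), k=1)]))
    return TrendResult(
        slope=float(slope),
        ci_low=float(lo),
        ci_high=float(hi),
        p_value=p,
        n_pairs=n_pairs,
        n_years=len(t),
    )


def _metric_series(
    ptd_table: pd.DataFrame, site: str, method: str, threshold: float | None
) -> pd.DataFrame:
    sub = ptd_table[(ptd_table["site"] == site) & (ptd_table["method"] == method)]
    if threshold is not None:
        sub = sub[np.isclose(sub["threshold"].astype(float), threshold)]
    return sub.dropna(subset=["sos", "eos"]).sort_values("year")


def gsl_trend(
    ptd_table: pd.DataFrame,
    site: str,
    threshold: float | None,
    method: str = "threshold",
) -> TrendResult:
    """Trend of the per-year difference EOS - SOS over common years."""
    sub = _metric_series(ptd_table, site, method, threshold)
    if len(sub) < 2:
        raise ValueError(f"{site}: <2 years with both SOS and EOS")
    return theil_sen(sub["year"].to_numpy(), (sub["eos"] - sub["sos"]).to_numpy())


def trends_by_threshold(ptd_table: pd.DataFrame, site: str | None = None) -> pd.DataFrame:
    """Theil-Sen trend table: one row per site x metric x (threshold|derivative).

    Columns: site, metric, method, threshold, slope (days yr-1),
    slope_per_decade, ci_low, ci_high (days yr-1), p_value, n_years, issues.
    Per-cell failures are recorded, not fatal.
    """
    sites = [site] if site is not None else sorted(ptd_table["site"].unique())
    rows: list[dict] = []
    for s in sites:
        site_tab = ptd_table[ptd_table["site"] == s]
        cells: list[tuple[str, float | None]] = [
            ("threshold", float(t))
            for t in sorted(site_tab.loc[site_tab["method"] == "threshold", "threshold"].dropna().unique())
        ]
        if (site_tab["method"] == "derivative").any():
            cells.append(("derivative", None))
        for method, threshold in cells:
            sub = _metric_series(ptd_table, s, method, threshold)
            for metric in ("SOS", "EOS", "GSL"):
                row = {
                    "site": s,
                    "metric": metric,
                    "method": method,
                    "threshold": threshold,
                    "slope": np.nan,
                    "slope_per_decade": np.nan,
                    "ci_low": np.nan,
                    "ci_high": np.nan,
                    "p_value": np.nan,
                    "n_years": len(sub),
                    "issues": "",
                }
                try:
                    if metric == "SOS":
                        vals = sub["sos"].to_numpy()
                    elif metric == "EOS":
                        vals = sub["eos"].to_numpy()
                    else:  # trend of the difference, not difference of trends
                        vals = (sub["eos"] - sub["sos"]).to_numpy()
                    res = theil_sen(sub["year"].to_numpy(), vals)
                    row.update(
                        slope=res.slope,
                        slope_per_decade=res.slope_per_decade,
                        ci_low=res.ci_low,
                        ci_high=res.ci_high,
                        p_value=res.p_value,
                    )
                except ValueError as exc:
                    row["issues"] = str(exc)
                rows.append(row)
    return pd.DataFrame(rows)


def _sen_slope(t: np.ndarray, y: np.ndarray) -> float:
    slopes = _pairwise_slopes(t, y)
    return float(np.median(slopes)) if len(slopes) else np.nan


def classify_uncertainty(
    ptd_table: pd.DataFrame,
    cutoffs: Mapping[str, float] = DEFAULT_SIGMA_CUTOFFS,
    n_boot: int = 1000,
    seed: int | None = None,
    confidence: float = 0.95,
) -> list[UncertaintyFlag]:
    """Flag sites whose trends depend strongly on the threshold choice.

    ``sigma_trend`` is the sample standard deviation (ddof=1) of the
    per-threshold Theil-Sen slopes in days/decade (derivative excluded); the
    flag is strict ``sigma_trend > cutoff``.  The bootstrap resamples whole
    years with replacement, recomputes every per-threshold slope and its
    spread, and reports the percentile confidence interval of the spread.
    """
    rng = np.random.default_rng(seed)
    out: list[UncertaintyFlag] = []
    thresh_tab = ptd_table[ptd_table["method"] == "threshold"].dropna(subset=["sos", "eos"])
    for site in sorted(ptd_table["site"].unique()):
        site_tab = thresh_tab[thresh_tab["site"] == site]
        thresholds = sorted(site_tab["threshold"].astype(float).unique())
        # wide per-metric matrices: years x thresholds
        years = np.array(sorted(site_tab["year"].unique()), dtype=float)
        mats: dict[str, np.ndarray] = {}
        for metric, col in (("SOS", "sos"), ("EOS", "eos"), ("GSL", None)):
            wide = np.full((len(years), len(thresholds)), np.nan)
            for j, th in enumerate(thresholds):
                sub = site_tab[np.isclose(site_tab["threshold"].astype(float), th)]
                vals = sub["eos"] - sub["sos"] if col is None else sub[col]
                lookup = dict(zip(sub["year"].astype(float), vals.astype(float)))
                wide[:, j] = [lookup.get(yr, np.nan) for yr in years]
            mats[metric] = wide
        for metric in ("SOS", "EOS", "GSL"):
            wide = mats[metric]
            slopes = np.array(
                [
                    10.0 * _sen_slope(years[np.isfinite(wide[:, j])], wide[np.isfinite(wide[:, j]), j])
                    if np.isfinite(wide[:, j]).sum() >= 2
                    else np.nan
                    for j in range(len(thresholds))
                ]
            )
            valid = np.isfinite(slopes)
            if valid.sum() < 2:
                out.append(
                    UncertaintyFlag(
                        site_id=site,
                        metric=metric,
                        sigma_trend=np.nan,
                        flag=None,
                        bootstrap_ci=None,
                        n_thresholds=int(valid.sum()),
                        reason="fewer than 2 valid per-threshold trends",
                    )
                )
                continue
            sigma = float(np.std(slopes[valid], ddof=1))
            boot_sigmas = []
            for _ in range(n_boot):
                pick = rng.integers(0, len(years), size=len(years))
                t_b = years[pick]
                if np.ptp(t_b) == 0:
                    continue
                sig_slopes = []
                for j in np.flatnonzero(valid):
                    col_b = wide[pick, j]
                    ok = np.isfinite(col_b)
                    if ok.sum() >= 2 and np.ptp(t_b[ok]) > 0:
                        sig_slopes.append(10.0 * _sen_slope(t_b[ok], col_b[ok]))
                if len(sig_slopes) >= 2:
                    boot_sigmas.append(np.std(sig_slopes, ddof=1))
            ci = None
            if boot_sigmas:
                lo, hi = np.percentile(boot_sigmas, [50 * (1 - confidence), 100 - 50 * (1 - confidence)])
                ci = (float(lo), float(hi))
            out.append(
                UncertaintyFlag(
                    site_id=site,
                    metric=metric,
                    sigma_trend=sigma,
                    flag=bool(sigma > cutoffs[metric]),
                    bootstrap_ci=ci,
                    n_thresholds=int(valid.sum()),
                )
            )
    return out
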