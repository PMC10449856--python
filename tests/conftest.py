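"""Shared fixtures: synthetic flux series used across the test modules."""

import numpy as np
import pandas as pd
import pytest

from phenoflux import DailyFluxSeries, NoiseSpec, SeasonSpec, TrendSpec, generate_series


@pytest.fixture(scope="session")
def default_season() -> SeasonSpec:
    """Broad temperate season: slow green-up resolvable by a 10-knot fit."""
    return SeasonSpec()


@pytest.fixture(scope="session")
def steep_season() -> SeasonSpec:
    """Well-separated steep logistic branches for closed-form oracle work."""
    return SeasonSpec(sos_slope=0.15, eos_slope=0.15)


@pytest.fixture(scope="session")
def noisefree_series(default_season) -> DailyFluxSeries:
    """Three noise-free trend-free years of the default season."""
    return generate_series(default_season, TrendSpec(), NoiseSpec(), n_years=3, start_year=2000)


@pytest.fixture(scope="session")
def noisy_trended_series(default_season) -> DailyFluxSeries:
    """Twelve years with advancing spring, delayed autumn and 10% noise."""
    return generate_series(
        default_season,
        TrendSpec(sos_shift_rate=-0.3, eos_shift_rate=0.2),
        NoiseSpec(noise_sd_frac=0.1, rng_seed=42),
        n_years=12,
        start_year=2000,
    )


def series_from_arrays(site_id: str, start_year: int, gpp_by_year, qc_by_year=None) -> DailyFluxSeries:
    """Build a DailyFluxSeries from per-year value arrays (test helper)."""
    frames = []
    for i, gpp in enumerate(gpp_by_year):
        year = start_year + i
        dates = pd.date_range(f"{year}-01-01", f"{year}-12-31", freq="D")
        if len(gpp) != len(dates):
            raise ValueError(f"year {year}: need {len(dates)} values, got {len(gpp)}")
        qc = qc_by_year[i] if qc_by_year is not None else np.ones(len(dates))
        frames.append(pd.DataFrame({"date": dates, "gpp": np.asarray(gpp, float), "nee_qc": qc}))
    return DailyFluxSeries(site_id, pd.concat(frames, ignore_index=True))
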