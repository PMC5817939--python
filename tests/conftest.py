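"""Shared fixtures: small deterministic synthetic worlds."""

import numpy as np
import pandas as pd
import pytest
import xarray as xr

from reefbleach.synthetic import SyntheticScenario, generate_sst


@pytest.fixture(scope="session")
def quiet_scenario() -> SyntheticScenario:
    """Noise-free, trend-free world: climatologies are exactly computable."""
    return SyntheticScenario(
        grid_shape=(3, 3),
        years=(1990, 1995),
        seasonal_amplitude=4.5,
        amplitude_gradient=0.0,
        trend=0.0,
        interannual_sd=0.0,
        noise_sd=0.0,
        seed=7,
    )


@pytest.fixture(scope="session")
def noisy_scenario() -> SyntheticScenario:
    """Small realistic world with noise, trend and interannual variability."""
    return SyntheticScenario(grid_shape=(4, 4), years=(1990, 2000), seed=11)


@pytest.fixture(scope="session")
def quiet_sst(quiet_scenario) -> xr.DataArray:
    return generate_sst(quiet_scenario)


@pytest.fixture(scope="session")
def noisy_sst(noisy_scenario) -> xr.DataArray:
    return generate_sst(noisy_scenario)


def make_monthly(values_by_year: dict[int, list[float]]) -> xr.DataArray:
    """Single-cell monthly field from {year: [12 values]} (helper, not fixture)."""
    times, vals = [], []
    for year in sorted(values_by_year):
        for m, v in enumerate(values_by_year[year], start=1):
            times.append(pd.Timestamp(year=year, month=m, day=1))
            vals.append(v)
    return xr.DataArray(
        np.asarray(vals, dtype=float),
        coords={"time": pd.DatetimeIndex(times)},
        dims=("time",),
    )
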