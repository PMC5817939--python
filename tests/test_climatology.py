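"""Climatology arithmetic against hand-computed and generator ground truth."""

import numpy as np
import pandas as pd
import pytest
import xarray as xr

from reefbleach.climatology import (
    RecenterSpec,
    bilinear_interpolate,
    build_climatology,
    compute_mmm,
    compute_mmm_max,
    compute_sigma_m,
    harmonize_products,
    idw_interpolate,
    monthly_aggregate,
    monthly_climatology,
)
from conftest import make_monthly


def daily_cube(values, start="2000-01-01"):
    time = pd.date_range(start, periods=len(values), freq="D")
    return xr.DataArray(
        np.asarray(values, dtype=float), coords={"time": time}, dims=("time",)
    )


class TestMonthlyAggregate:
    def test_constant_cube(self):
        m = monthly_aggregate(daily_cube([28.0] * 90))
        assert (m.values == 28.0).all()

    def test_january_mixed_days_mean(self):
        vals = [27.0, 29.0] * 16  # 32 days: 16 full alternating pairs
        m = monthly_aggregate(daily_cube(vals[:31]))
        expected = (16 * 27 + 15 * 29) / 31
        assert float(m.isel(time=0)) == pytest.approx(expected)

    def test_fully_missing_month_is_flagged_not_zero(self):
        cube = daily_cube([28.0] * 59)
        cube[:31] = np.nan  # January entirely missing
        m = monthly_aggregate(cube)
        assert np.isnan(float(m.isel(time=0)))
        assert float(m.isel(time=1)) == 28.0

    def test_empty_cube_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            monthly_aggregate(daily_cube([])[0:0])


class TestHarmonize:
    def test_identity_for_identical_products(self):
        m = make_monthly({2002: list(range(12)), 2003: list(range(12))})
        out = harmonize_products(m, m, (2002, 2003))
        assert np.allclose(out.values, m.values)

    def test_constant_offset_recovered(self):
        fine = make_monthly({2002: [20 + i for i in range(12)]})
        coarse = fine - 0.3
        out = harmonize_products(coarse, fine, (2002, 2002))
        assert np.allclose(out.values, fine.values)

    def test_month_dependent_offsets_recovered(self):
        fine = make_monthly(
            {2002: [20.0] * 12, 2003: [20.0] * 12}
        )
        offsets = np.zeros(12)
        offsets[0], offsets[6] = -0.2, 0.1  # coarse too cold in Jan, warm in Jul
        coarse = fine.copy()
        coarse.values = fine.values + np.tile(offsets, 2)
        out = harmonize_products(coarse, fine, (2002, 2003))
        assert np.allclose(out.values, fine.values, atol=1e-12)

    def test_empty_overlap_rejected(self):
        m = make_monthly({2002: list(range(12))})
        with pytest.raises(ValueError, match="overlap"):
            harmonize_products(m, m, (1990, 1991))


class TestMMM:
    def test_zero_slope_recentering_is_identity(self):
        vals = [20, 21, 23, 25, 27, 28, 29, 29.5, 28, 26, 23, 21]
        m = make_monthly({y: vals for y in (2000, 2001, 2002)})
        mmm, slope = compute_mmm(m)
        assert float(slope) == pytest.approx(0.0, abs=1e-9)
        assert float(mmm) == pytest.approx(29.5)

    def test_recentering_shift_is_slope_times_center_gap(self):
        """slope 0.02 °C/yr over an 11.5-yr center gap lowers MMM by 0.23."""
        vals = np.array([20, 21, 23, 25, 27, 28, 29, 29.5, 28, 26, 23, 21])
        years = range(2000, 2010)
        data = {}
        for i, y in enumerate(years):
            data[y] = list(vals + 0.02 * i)  # exact 0.02 °C/yr trend
        m = make_monthly(data)
        spec = RecenterSpec(full_span_center=2016.0, heritage_center=2004.5)
        mmm_recentered, slope = compute_mmm(m, spec)
        clim_max = float(monthly_climatology(m).max("month"))
        assert float(slope) == pytest.approx(0.02, abs=1e-6)
        assert clim_max - float(mmm_recentered) == pytest.approx(
            0.02 * 11.5, abs=1e-6
        )

    def test_mmm_matches_generator_ground_truth(self, quiet_scenario, quiet_sst):
        """Noise- and trend-free cube: MMM equals the warmest monthly mean of
        the seasonal cosine."""
        monthly = monthly_aggregate(quiet_sst)
        mmm, _ = compute_mmm(monthly)
        clim = monthly_climatology(monthly)
        assert np.allclose(mmm.values, clim.max("month").values, atol=1e-9)
        # August (containing the peak day-of-year 227) is the warmest month
        assert int(clim.isel(lat=0, lon=0).idxmax("month")) == 8

    def test_single_year_rejected(self):
        m = make_monthly({2000: list(range(12))})
        with pytest.raises(ValueError, match="two years"):
            compute_mmm(m)

    def test_default_recenter_spec_centers(self):
        spec = RecenterSpec.default()
        assert spec.full_span_center == pytest.approx(2000.5)
        assert spec.heritage_center == pytest.approx(1988.7857, abs=1e-3)
        assert spec.heritage_center < spec.full_span_center


class TestMMMMax:
    def test_mean_of_annual_maxima(self):
        data = {}
        for y, peak in zip((2000, 2001, 2002), (29.0, 30.0, 31.0)):
            data[y] = [20.0] * 7 + [peak] + [20.0] * 4
        m = make_monthly(data)
        assert float(compute_mmm_max(m)) == pytest.approx(30.0)

    def test_alternating_warmest_month_makes_mmm_max_exceed_mmm(self):
        """When the warmest month flips between July and August, averaging
        each year's own maximum exceeds the maximum of the climatology."""
        data = {
            2000: [20.0] * 6 + [29.0, 27.0] + [20.0] * 4,
            2001: [20.0] * 6 + [27.0, 29.0] + [20.0] * 4,
        }
        m = make_monthly(data)
        mmm, _ = compute_mmm(m, RecenterSpec(2000.0, 2000.0))
        assert float(compute_mmm_max(m)) > float(mmm)

    def test_single_year(self):
        m = make_monthly({2000: [20.0] * 11 + [28.5]})
        assert float(compute_mmm_max(m)) == pytest.approx(28.5)

    def test_mmm_max_ge_mmm_on_noisy_world(self, noisy_sst):
        clim = build_climatology(monthly_aggregate(noisy_sst))
        assert (clim.mmm_max >= clim.mmm - 1e-9).all()


class TestSigmaM:
    def test_sd_of_arithmetic_progression(self):
        data = {}
        for y, peak in zip((2000, 2001, 2002), (29.0, 30.0, 31.0)):
            data[y] = [20.0] * 7 + [peak] + [20.0] * 4
        assert float(compute_sigma_m(make_monthly(data))) == pytest.approx(1.0)

    def test_identical_years_give_zero(self):
        m = make_monthly({y: [20.0] * 12 for y in (2000, 2001)})
        assert float(compute_sigma_m(m)) == pytest.approx(0.0)

    def test_matches_brute_force_on_noisy_world(self, noisy_sst):
        monthly = monthly_aggregate(noisy_sst)
        sigma = compute_sigma_m(monthly)
        # brute force: extract annual maxima per cell explicitly
        years = np.unique(monthly.indexes["time"].year)
        maxima = np.stack(
            [monthly.sel(time=str(y)).max("time").values for y in years]
        )
        assert np.allclose(sigma.values, maxima.std(axis=0, ddof=1), atol=1e-9)

    def test_chi_square_interval_coverage(self):
        """31 years of N(29, 0.5^2) annual peaks: the sample SD falls in
        [0.35, 0.65] (the ~98% chi-square band) in >= 95 of 100 seeds."""
        hits = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            data = {
                1985 + i: [20.0] * 7 + [29.0 + rng.normal(0, 0.5)] + [20.0] * 4
                for i in range(31)
            }
            s = float(compute_sigma_m(make_monthly(data)))
            hits += 0.35 <= s <= 0.65
        assert hits >= 95

    def test_fewer_than_two_years_rejected(self):
        with pytest.raises(ValueError, match="two complete years"):
            compute_sigma_m(make_monthly({2000: [20.0] * 12}))


class TestInterpolation:
    def test_idw_exact_at_coincident_point(self):
        out = idw_interpolate([123.0, 124.0], [24.0, 24.0], [10.0, 20.0],
                              [123.0], [24.0])
        assert out[0] == 10.0

    def test_idw_symmetric_pair_gives_midpoint(self):
        for power in (1.0, 2.0, 3.0):
            out = idw_interpolate(
                [123.0, 123.2], [24.0, 24.0], [10.0, 20.0], [123.1], [24.0],
                power=power,
            )
            assert out[0] == pytest.approx(15.0, abs=1e-6)

    def test_idw_hand_weighted_example(self):
        """Sources 10 at distance d and 20 at 2d, power 2:
        (10*1 + 20*0.25)/1.25 = 12."""
        out = idw_interpolate(
            [123.1, 123.2], [24.0, 24.0], [10.0, 20.0], [123.0], [24.0], power=2
        )
        assert out[0] == pytest.approx(12.0, abs=1e-3)

    def test_idw_within_source_range(self):
        rng = np.random.default_rng(0)
        src_lon = rng.uniform(123, 124, 30)
        src_lat = rng.uniform(24, 25, 30)
        vals = rng.uniform(5, 9, 30)
        out = idw_interpolate(src_lon, src_lat, vals,
                              rng.uniform(123, 124, 50), rng.uniform(24, 25, 50))
        assert (out >= vals.min() - 1e-12).all() and (out <= vals.max() + 1e-12).all()

    def test_idw_no_finite_sources_rejected(self):
        with pytest.raises(ValueError, match="finite"):
            idw_interpolate([123.0], [24.0], [np.nan], [123.5], [24.0])

    def _grid(self):
        return xr.DataArray(
            [[10.0, 20.0], [30.0, 40.0]],
            coords={"lat": [24.0, 25.0], "lon": [123.0, 124.0]},
            dims=("lat", "lon"),
        )

    def test_bilinear_exact_at_node(self):
        assert bilinear_interpolate(self._grid(), [123.0], [25.0])[0] == 30.0

    def test_bilinear_cell_center(self):
        grid = xr.DataArray(
            [[0.0, 0.0], [1.0, 1.0]],
            coords={"lat": [24.0, 25.0], "lon": [123.0, 124.0]},
            dims=("lat", "lon"),
        )
        assert bilinear_interpolate(grid, [123.5], [24.5])[0] == pytest.approx(0.5)

    def test_bilinear_hand_example(self):
        """Corners 10/20/30/40, fractional offsets (0.25 lon, 0.75 lat)."""
        out = bilinear_interpolate(self._grid(), [123.25], [24.75])
        assert out[0] == pytest.approx(27.5)

    def test_bilinear_outside_hull_flagged_missing(self):
        out = bilinear_interpolate(self._grid(), [122.0], [24.5])
        assert np.isnan(out[0])
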