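"""Covariate preparation, the observation join, and collinearity screening."""

import numpy as np
import pandas as pd
import pytest
import xarray as xr

from reefbleach.climatology import build_climatology, monthly_aggregate
from reefbleach.covariates import (
    coastal_fill,
    collinearity_screen,
    current_speed,
    extract_at_records,
    seasonal_composite,
    typhoon_calm_index,
)
from reefbleach.indices import IndexSpec, degree_heating_week, hotspots
from reefbleach.synthetic import generate_covariates


class TestCurrentSpeed:
    @pytest.mark.parametrize(
        "u,v,expected",
        [(0.0, 0.0, 0.0), (3.0, 4.0, 5.0), (-1.0, 1.0, np.sqrt(2))],
    )
    def test_magnitude(self, u, v, expected):
        assert current_speed(u, v) == pytest.approx(expected)


class TestSeasonalComposite:
    def _monthly(self, july, aug, sep, years=(2000,)):
        times, vals = [], []
        for y in years:
            for m in range(1, 13):
                times.append(pd.Timestamp(y, m, 1))
                vals.append({7: july, 8: aug, 9: sep}.get(m, -99.0))
        return xr.DataArray(
            np.asarray(vals), coords={"time": pd.DatetimeIndex(times)}, dims="time"
        )

    def test_constant_field(self):
        out = seasonal_composite(self._monthly(5.0, 5.0, 5.0))
        assert float(out) == 5.0

    def test_median_robust_to_outlier(self):
        out = seasonal_composite(self._monthly(1.0, 2.0, 9.0))
        assert float(out) == 2.0

    def test_two_year_six_value_median(self):
        out = seasonal_composite(self._monthly(1.0, 2.0, 9.0, years=(2000, 2001)))
        assert float(out) == 2.0

    def test_no_target_months_rejected(self):
        da = xr.DataArray(
            [1.0], coords={"time": pd.DatetimeIndex(["2000-01-01"])}, dims="time"
        )
        with pytest.raises(ValueError, match="target months"):
            seasonal_composite(da)


class TestTyphoonCalmIndex:
    SEASON = ("2016-07-01", "2016-08-01")  # 31 days = 744 h

    def test_no_tracks_full_duration(self):
        assert typhoon_calm_index(
            pd.DataFrame(), 123.0, 24.0, self.SEASON
        ) == pytest.approx(744.0)

    def test_single_24h_passage(self):
        track = pd.DataFrame(
            {
                "time": pd.date_range("2016-07-10", periods=4, freq="6h"),
                "lat": 24.0,
                "lon": 123.0,
                "max_wind_ms": 20.0,
            }
        )
        out = typhoon_calm_index(track, 123.0, 24.0, self.SEASON)
        assert out == pytest.approx(744.0 - 24.0)

    def test_overlapping_passages_counted_once(self):
        t1 = pd.date_range("2016-07-10", periods=4, freq="6h")
        t2 = pd.date_range("2016-07-10 12:00", periods=4, freq="6h")
        track = pd.DataFrame(
            {
                "time": t1.append(t2),
                "lat": 24.0,
                "lon": 123.0,
                "max_wind_ms": 20.0,
            }
        )
        # union spans 36 h, not 48
        out = typhoon_calm_index(track, 123.0, 24.0, self.SEASON)
        assert out == pytest.approx(744.0 - 36.0)

    def test_weak_or_distant_winds_ignored(self):
        track = pd.DataFrame(
            {
                "time": pd.date_range("2016-07-10", periods=4, freq="6h"),
                "lat": [24.0, 24.0, 60.0, 60.0],
                "max_wind_ms": [10.0, 10.0, 30.0, 30.0],
                "lon": 123.0,
            }
        )
        assert typhoon_calm_index(track, 123.0, 24.0, self.SEASON) == 744.0

    def test_never_exceeds_season_duration(self):
        track = pd.DataFrame(
            {
                "time": pd.date_range("2016-07-01", periods=200, freq="6h"),
                "lat": 24.0,
                "lon": 123.0,
                "max_wind_ms": 25.0,
            }
        )
        out = typhoon_calm_index(track, 123.0, 24.0, self.SEASON)
        assert 0.0 <= out <= 744.0


class TestCoastalFill:
    def _field(self, vals):
        vals = np.asarray(vals, dtype=float)
        return xr.DataArray(
            vals,
            coords={
                "lat": 24.0 + 0.01 * np.arange(vals.shape[0]),
                "lon": 123.0 + 0.01 * np.arange(vals.shape[1]),
            },
            dims=("lat", "lon"),
        )

    def test_identity_when_complete(self):
        f = self._field([[1.0, 2.0], [3.0, 4.0]])
        out = coastal_fill(f)
        assert (out.values == f.values).all()

    def test_single_gap_among_constant_neighbors(self):
        f = self._field([[5.0, 5.0, 5.0], [5.0, np.nan, 5.0], [5.0, 5.0, 5.0]])
        assert coastal_fill(f).values[1, 1] == pytest.approx(5.0)

    def test_equidistant_pair_gives_midpoint(self):
        f = self._field([[10.0, np.nan, 20.0]])
        assert coastal_fill(f).values[0, 1] == pytest.approx(15.0, abs=1e-6)

    def test_idempotent(self):
        f = self._field([[1.0, np.nan], [np.nan, 4.0]])
        once = coastal_fill(f)
        twice = coastal_fill(once)
        assert np.allclose(once.values, twice.values)

    def test_all_missing_rejected(self):
        with pytest.raises(ValueError, match="all-missing"):
            coastal_fill(self._field([[np.nan, np.nan]]))


class TestExtractAtRecords:
    @pytest.fixture(scope="class")
    def world(self, quiet_scenario, quiet_sst):
        monthly = monthly_aggregate(quiet_sst)
        clim = build_climatology(monthly)
        fields = generate_covariates(quiet_scenario)
        k = seasonal_composite(fields["k490"])
        s = current_speed(fields["u_current"], fields["v_current"])
        return quiet_sst, clim, fields, k, s

    def _extract(self, world, records, spec=IndexSpec(alpha=0.5)):
        sst, clim, fields, k, s = world
        return extract_at_records(records, sst, clim, spec, fields["uvb"], k, s)

    def test_cell_center_takes_grid_value_and_window_math(self, world):
        sst, clim, fields, k, s = world
        records = pd.DataFrame(
            {
                "lon": [float(sst.lon[1])],
                "lat": [float(sst.lat[1])],
                "date": [pd.Timestamp("1995-09-15")],
                "depth_m": [6.0],
            }
        )
        table, excluded = self._extract(world, records)
        assert len(table) == 1 and len(excluded) == 0
        assert table.loc[0, "k"] == pytest.approx(float(k.values[1, 1]))
        assert table.loc[0, "v"] == pytest.approx(float(clim.sigma_m.values[1, 1]))
        assert table.loc[0, "d"] == 6.0
        # independent window oracle for the DHW value
        it = sst.indexes["time"].searchsorted(pd.Timestamp("1995-09-15"), "right")
        hs = hotspots(sst.values[:it, 1, 1], float(clim.mmm.values[1, 1]))
        assert table.loc[0, "dhw"] == pytest.approx(degree_heating_week(hs, 0.5))

    def test_records_outside_domain_excluded_with_reason(self, world):
        records = pd.DataFrame(
            {
                "lon": [150.0],
                "lat": [24.0],
                "date": [pd.Timestamp("1995-09-15")],
                "depth_m": [5.0],
            }
        )
        table, excluded = self._extract(world, records)
        assert len(table) == 0
        assert excluded.loc[0, "reason"] == "outside domain"

    def test_dates_sixty_days_apart_get_different_dhw(self, world):
        sst, clim, *_ = world
        records = pd.DataFrame(
            {
                "lon": [float(sst.lon[0])] * 2,
                "lat": [float(sst.lat[0])] * 2,
                "date": [pd.Timestamp("1995-07-15"), pd.Timestamp("1995-09-13")],
                "depth_m": [5.0, 5.0],
            }
        )
        spec = IndexSpec(alpha=0.0)
        table, _ = self._extract(world, records, spec)
        assert table.loc[0, "dhw"] != table.loc[1, "dhw"]


class TestCollinearityScreen:
    def test_duplicated_column_dropped(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=100)
        t = pd.DataFrame({"a": x, "b": x.copy(), "c": rng.normal(size=100)})
        retained, report = collinearity_screen(t, ["a", "b", "c"])
        assert retained == ["a", "c"]
        assert report.dropped == ["b"]

    def test_independent_columns_all_retained(self):
        rng = np.random.default_rng(1)
        t = pd.DataFrame(rng.normal(size=(1000, 4)), columns=list("abcd"))
        retained, report = collinearity_screen(t, list("abcd"))
        assert retained == list("abcd")
        assert not report.pairs["flagged"].any()

    def test_constructed_r079_pair_dropped(self):
        """A pair built with r = 0.79 (the UV-B/PAR situation) is flagged and
        the lower-priority member dropped."""
        rng = np.random.default_rng(2)
        n = 20000
        x = rng.normal(size=n)
        r = 0.79
        y = r * x + np.sqrt(1 - r**2) * rng.normal(size=n)
        t = pd.DataFrame({"uvb": x, "par": y, "z": rng.normal(size=n)})
        retained, report = collinearity_screen(
            t, ["uvb", "par", "z"], priority=["uvb", "par", "z"]
        )
        assert "par" not in retained and "uvb" in retained
        pair = report.pairs.query("var_a == 'uvb' and var_b == 'par'")
        assert pair["r"].iloc[0] == pytest.approx(0.79, abs=0.02)

    def test_constant_column_flagged_not_correlated(self):
        t = pd.DataFrame({"a": [1.0, 2.0, 3.0, 4.0], "b": [5.0] * 4})
        retained, report = collinearity_screen(t, ["a", "b"])
        assert report.constant == ["b"]
        assert retained == ["a"]

    def test_no_retained_pair_exceeds_cutoff(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=500)
        t = pd.DataFrame(
            {
                "a": x,
                "b": 0.95 * x + 0.3 * rng.normal(size=500),
                "c": -0.9 * x + 0.4 * rng.normal(size=500),
                "d": rng.normal(size=500),
            }
        )
        retained, _ = collinearity_screen(t, list("abcd"))
        corr = t[retained].corr().abs().values
        np.fill_diagonal(corr, 0.0)
        assert corr.max() <= 0.7
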