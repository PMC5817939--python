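"""SST climatologies: monthly aggregation, product harmonization, MMM,
MMM_max, historical variability and trend, plus the two interpolators used
for downscaling and coastal gap-filling.

The maximum monthly mean (MMM) follows the NOAA Coral Reef Watch
convention: the 12 climatological monthly means are recentered in time by
subtracting the per-cell linear trend times the gap between the temporal
midpoints of the full climatology span (1985–2015) and of the heritage
baseline years (1985–1990 and 1993); MMM is the warmest recentered monthly
mean.  MMM_max instead averages each year's warmest monthly mean, and is
therefore never smaller than MMM.  sigma_m is the sample standard deviation
of the annual maximum monthly SST.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import xarray as xr
from scipy.spatial import cKDTree

__all__ = [
    "RecenterSpec",
    "ClimatologySet",
    "monthly_aggregate",
    "harmonize_products",
    "monthly_climatology",
    "trend_slope",
    "compute_mmm",
    "compute_mmm_max",
    "compute_sigma_m",
    "build_climatology",
    "idw_interpolate",
    "bilinear_interpolate",
]

EARTH_RADIUS_KM = 6371.0
#: a month whose day coverage is below this fraction is flagged missing
MIN_MONTH_COVERAGE = 0.5


def month_midpoint_center(years: Iterable[int]) -> float:
    """Mean of the month-midpoint decimal years of the given calendar years.

    The mean of the 12 midpoints (y + (m - 0.5)/12) of a year is y + 0.5,
    so this is the mean of (year + 0.5) over the set.
    """
    ys = np.asarray(list(years), dtype=float)
    return float(ys.mean() + 0.5)


@dataclass(frozen=True)
class RecenterSpec:
    """Temporal midpoints used to recenter the MMM climatology."""

    full_span_center: float
    heritage_center: float

    @classmethod
    def default(cls) -> "RecenterSpec":
        return cls(
            full_span_center=month_midpoint_center(range(1985, 2016)),  # 2000.5
            heritage_center=month_midpoint_center(list(range(1985, 1991)) + [1993]),
        )

    @property
    def center_gap(self) -> float:
        return self.full_span_center - self.heritage_center


@dataclass
class ClimatologySet:
    """Per-cell historical baselines derived from a monthly SST field."""

    mmm: xr.DataArray  # °C, recentered warmest climatological monthly mean
    mmm_max: xr.DataArray  # °C, mean of annual warmest monthly means
    sigma_m: xr.DataArray  # °C, SD of annual max monthly SST
    monthly_clim: xr.DataArray  # (month, lat, lon) climatological means
    slope: xr.DataArray  # °C / yr linear trend of monthly SST
    span: tuple[int, int]

    def to_dataset(self) -> xr.Dataset:
        ds = xr.Dataset(
            {
                "mmm": self.mmm,
                "mmm_max": self.mmm_max,
                "sigma_m": self.sigma_m,
                "monthly_clim": self.monthly_clim,
                "slope": self.slope,
            }
        )
        ds.attrs["span"] = list(self.span)
        return ds

    @classmethod
    def from_dataset(cls, ds: xr.Dataset) -> "ClimatologySet":
        span = tuple(int(v) for v in ds.attrs.get("span", (0, 0)))
        return cls(
            mmm=ds["mmm"],
            mmm_max=ds["mmm_max"],
            sigma_m=ds["sigma_m"],
            monthly_clim=ds["monthly_clim"],
            slope=ds["slope"],
            span=span,  # type: ignore[arg-type]
        )


# ---------------------------------------------------------------------------
# monthly aggregation and product harmonization
# ---------------------------------------------------------------------------

def monthly_aggregate(sst: xr.DataArray) -> xr.DataArray:
    """Monthly mean of a daily cube; under-covered months flagged missing.

    A month with fewer than ``MIN_MONTH_COVERAGE`` of its days present is
    set to NaN rather than averaged from a thin sample.
    """
    if sst.sizes.get("time", 0) == 0:
        raise ValueError("empty SST cube")
    valid = sst.notnull()
    monthly_sum = sst.fillna(0.0).resample(time="MS").sum()
    n_valid = valid.resample(time="MS").sum()
    days_in_month = xr.DataArray(
        monthly_sum["time"].dt.days_in_month, coords={"time": monthly_sum["time"]}
    )
    mean = monthly_sum / n_valid.where(n_valid > 0)
    covered = n_valid >= MIN_MONTH_COVERAGE * days_in_month
    out = mean.where(covered)
    out.name = "sst_monthly"
    out.attrs = dict(sst.attrs)
    return out


def harmonize_products(
    coarse_monthly: xr.DataArray,
    fine_monthly: xr.DataArray,
    overlap: tuple[int, int],
) -> xr.DataArray:
    """Bias-correct one monthly product against another on their overlap.

    For each calendar month m, corrected = coarse + [clim_fine(m) −
    clim_coarse(m)] where both climatologies are computed on the overlap
    years.  The coarse field must already be on the fine grid.
    """
    y0, y1 = overlap
    sel = dict(time=slice(f"{y0}-01-01", f"{y1}-12-31"))
    co, fo = coarse_monthly.sel(**sel), fine_monthly.sel(**sel)
    if co.sizes.get("time", 0) == 0 or fo.sizes.get("time", 0) == 0:
        raise ValueError(f"empty overlap {overlap}")
    bias = fo.groupby("time.month").mean("time") - co.groupby("time.month").mean(
        "time"
    )
    corrected = coarse_monthly.groupby("time.month") + bias
    if "month" in corrected.coords:
        corrected = corrected.drop_vars("month")
    corrected.name = coarse_monthly.name
    return corrected


# ---------------------------------------------------------------------------
# climatological statistics
# ---------------------------------------------------------------------------

def _decimal_year(time: pd.DatetimeIndex) -> np.ndarray:
    """Month-midpoint decimal years for a monthly time axis."""
    return time.year.to_numpy() + (time.month.to_numpy() - 0.5) / 12.0


def monthly_climatology(monthly: xr.DataArray) -> xr.DataArray:
    """Per-cell mean over years for each calendar month -> (month, ...)."""
    return monthly.groupby("time.month").mean("time")


def trend_slope(monthly: xr.DataArray) -> xr.DataArray:
    """Per-cell linear trend (°C/yr) of the monthly series.

    Fitted with calendar-month fixed effects (x and y demeaned within each
    calendar month before pooled least squares), so the seasonal cycle
    cannot alias into the slope: a trend-free periodic series has slope
    exactly 0 and a planted trend is recovered exactly.
    """
    if monthly.sizes.get("time", 0) < 2:
        raise ValueError("trend requires at least two monthly values")
    t = _decimal_year(monthly.indexes["time"])
    x = xr.DataArray(t, coords={"time": monthly["time"]}, dims=("time",))
    xa = x.groupby("time.month") - x.groupby("time.month").mean("time")
    ya = monthly.groupby("time.month") - monthly.groupby("time.month").mean("time")
    denom = (xa**2).sum("time")
    slope = xr.where(denom > 0, (xa * ya).sum("time") / denom, np.nan)
    if "month" in slope.coords:
        slope = slope.drop_vars("month")
    slope.name = "slope"
    slope.attrs = {"units": "degC yr-1"}
    return slope


def compute_mmm(
    monthly: xr.DataArray, spec: RecenterSpec | None = None
) -> tuple[xr.DataArray, xr.DataArray]:
    """Recentered MMM and the per-cell trend slope.

    Each of the 12 climatological monthly means is shifted by
    −slope·(full_span_center − heritage_center); MMM is the maximum of the
    recentered means.
    """
    years = np.unique(monthly.indexes["time"].year)
    if len(years) < 2:
        raise ValueError("recentered MMM requires at least two years of data")
    spec = spec or RecenterSpec.default()
    clim = monthly_climatology(monthly)
    slope = trend_slope(monthly)
    recentered = clim - slope * spec.center_gap
    mmm = recentered.max("month")
    mmm.name = "mmm"
    mmm.attrs = {"units": "degC"}
    return mmm, slope


def _complete_years(monthly: xr.DataArray) -> xr.DataArray:
    """Restrict a monthly field to years with all 12 months present."""
    time = monthly.indexes["time"]
    counts = pd.Series(1, index=time).groupby(time.year).sum()
    full = counts[counts == 12].index
    keep = time.year.isin(full)
    return monthly.isel(time=keep)


def compute_mmm_max(monthly: xr.DataArray) -> xr.DataArray:
    """Mean over years of each year's warmest monthly mean (no recentering)."""
    sub = _complete_years(monthly)
    if sub.sizes.get("time", 0) == 0:
        raise ValueError("MMM_max requires at least one complete year")
    annual_max = sub.groupby("time.year").max("time")
    out = annual_max.mean("year")
    out.name = "mmm_max"
    out.attrs = {"units": "degC"}
    return out


def compute_sigma_m(monthly: xr.DataArray) -> xr.DataArray:
    """Sample SD (n−1) of the annual maximum monthly SST per cell."""
    sub = _complete_years(monthly)
    years = np.unique(sub.indexes["time"].year) if sub.sizes.get("time", 0) else []
    if len(years) < 2:
        raise ValueError("sigma_m requires at least two complete years")
    annual_max = sub.groupby("time.year").max("time")
    out = annual_max.std("year", ddof=1)
    out.name = "sigma_m"
    out.attrs = {"units": "degC"}
    return out


def build_climatology(
    monthly: xr.DataArray, spec: RecenterSpec | None = None
) -> ClimatologySet:
    """All historical baselines from one monthly SST field."""
    mmm, slope = compute_mmm(monthly, spec)
    years = monthly.indexes["time"].year
    return ClimatologySet(
        mmm=mmm,
        mmm_max=compute_mmm_max(monthly),
        sigma_m=compute_sigma_m(monthly),
        monthly_clim=monthly_climatology(monthly),
        slope=slope,
        span=(int(years.min()), int(years.max())),
    )


# ---------------------------------------------------------------------------
# interpolation
# ---------------------------------------------------------------------------

def _to_unit_sphere(lon: np.ndarray, lat: np.ndarray) -> np.ndarray:
    lam, phi = np.radians(lon), np.radians(lat)
    return np.column_stack(
        [np.cos(phi) * np.cos(lam), np.cos(phi) * np.sin(lam), np.sin(phi)]
    )


def idw_interpolate(
    src_lon: np.ndarray,
    src_lat: np.ndarray,
    src_val: np.ndarray,
    tgt_lon: np.ndarray,
    tgt_lat: np.ndarray,
    power: float = 2.0,
    k: int = 12,
) -> np.ndarray:
    """Inverse-distance-weighted interpolation on great-circle distances.

    Weights are distance^(−power) over the k nearest finite sources; a
    target coincident with a source takes that source's value exactly.
    """
    src_lon = np.asarray(src_lon, dtype=float).ravel()
    src_lat = np.asarray(src_lat, dtype=float).ravel()
    src_val = np.asarray(src_val, dtype=float).ravel()
    finite = np.isfinite(src_val)
    if not finite.any():
        raise ValueError("no finite source values for IDW")
    src_lon, src_lat, src_val = src_lon[finite], src_lat[finite], src_val[finite]

    tgt_lon = np.asarray(tgt_lon, dtype=float).ravel()
    tgt_lat = np.asarray(tgt_lat, dtype=float).ravel()
    tree = cKDTree(_to_unit_sphere(src_lon, src_lat))
    kk = min(k, len(src_val))
    chord, idx = tree.query(_to_unit_sphere(tgt_lon, tgt_lat), k=kk)
    chord = np.atleast_2d(chord)
    idx = np.atleast_2d(idx)
    # chord -> great-circle arc length (km)
    arc = 2.0 * EARTH_RADIUS_KM * np.arcsin(np.clip(chord / 2.0, 0.0, 1.0))

    out = np.empty(len(tgt_lon))
    exact = arc[:, 0] < 1e-9
    out[exact] = src_val[idx[exact, 0]]
    rest = ~exact
    if rest.any():
        w = arc[rest] ** (-power)
        out[rest] = (w * src_val[idx[rest]]).sum(axis=1) / w.sum(axis=1)
    return out


def bilinear_interpolate(
    field: xr.DataArray, tgt_lon: np.ndarray, tgt_lat: np.ndarray
) -> np.ndarray:
    """Standard bilinear blend of the 4 surrounding nodes; NaN outside hull."""
    tgt_lon = np.asarray(tgt_lon, dtype=float).ravel()
    tgt_lat = np.asarray(tgt_lat, dtype=float).ravel()
    out = field.interp(
        lon=xr.DataArray(tgt_lon, dims="points"),
        lat=xr.DataArray(tgt_lat, dims="points"),
        method="linear",
        kwargs={"fill_value": np.nan},
    )
    return out.values
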