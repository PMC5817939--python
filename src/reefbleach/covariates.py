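"""Non-thermal covariates and the observation/covariate join.

Prepares UV-B, turbidity (K490), surface-current speed and the typhoon
calm-duration index; fills coastal gaps by inverse-distance weighting;
extracts everything at observation points into the model design table; and
screens collinear covariate pairs (|r| > 0.7) before modelling.

Covariate-table column aliases follow the field's one-letter convention:
c = DCW, d = depth, k = turbidity, u = UV-B, s = current speed,
v = historical SST variability (sigma_m).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import xarray as xr

from . import indices as idx
from .climatology import EARTH_RADIUS_KM, ClimatologySet, idw_interpolate

__all__ = [
    "current_speed",
    "seasonal_composite",
    "typhoon_calm_index",
    "coastal_fill",
    "extract_at_records",
    "collinearity_screen",
    "CollinearityReport",
]

TYPHOON_WIND_CUTOFF = 15.0  # m/s
TYPHOON_RADIUS_KM = 100.0
COMPOSITE_MONTHS = (7, 8, 9)  # July–September


def current_speed(u, v):
    """Euclidean magnitude of the surface-current components (m/s)."""
    return np.sqrt(u**2 + v**2)


def seasonal_composite(
    monthly_field: xr.DataArray,
    months: Sequence[int] = COMPOSITE_MONTHS,
    statistic: str = "median",
) -> xr.DataArray:
    """Climatological per-cell statistic over the target months of all years."""
    sel = monthly_field.sel(time=monthly_field["time"].dt.month.isin(list(months)))
    if sel.sizes.get("time", 0) == 0:
        raise ValueError(f"no data in target months {tuple(months)}")
    if statistic == "median":
        out = sel.median("time")
    elif statistic == "mean":
        out = sel.mean("time")
    else:
        raise ValueError(f"unknown statistic {statistic!r}")
    out.name = monthly_field.name
    out.attrs = dict(monthly_field.attrs)
    return out


def _haversine_km(lon1, lat1, lon2, lat2):
    lam1, phi1, lam2, phi2 = map(np.radians, (lon1, lat1, lon2, lat2))
    a = (
        np.sin((phi2 - phi1) / 2) ** 2
        + np.cos(phi1) * np.cos(phi2) * np.sin((lam2 - lam1) / 2) ** 2
    )
    return 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0, 1)))


def _union_hours(intervals: list[tuple[pd.Timestamp, pd.Timestamp]]) -> float:
    """Total length (hours) of a union of time intervals."""
    if not intervals:
        return 0.0
    intervals = sorted(intervals)
    total = pd.Timedelta(0)
    cur_start, cur_end = intervals[0]
    for s, e in intervals[1:]:
        if s <= cur_end:
            cur_end = max(cur_end, e)
        else:
            total += cur_end - cur_start
            cur_start, cur_end = s, e
    total += cur_end - cur_start
    return total.total_seconds() / 3600.0


def typhoon_calm_index(
    tracks: pd.DataFrame,
    cell_lon: float,
    cell_lat: float,
    season: tuple[str, str],
    wind_cutoff: float = TYPHOON_WIND_CUTOFF,
    radius_km: float = TYPHOON_RADIUS_KM,
    step_hours: float = 6.0,
) -> float:
    """Hours of the season a cell spends without typhoon-force winds.

    A track point with wind above ``wind_cutoff`` within ``radius_km`` of
    the cell exposes it for [t, t + step_hours); overlapping exposures are
    counted once (interval union).
    """
    t0, t1 = pd.Timestamp(season[0]), pd.Timestamp(season[1])
    season_hours = (t1 - t0).total_seconds() / 3600.0
    if tracks is None or len(tracks) == 0:
        return season_hours
    d = _haversine_km(
        tracks["lon"].to_numpy(), tracks["lat"].to_numpy(), cell_lon, cell_lat
    )
    hit = (
        (tracks["max_wind_ms"].to_numpy() > wind_cutoff)
        & (d <= radius_km)
        & (tracks["time"] >= t0).to_numpy()
        & (tracks["time"] < t1).to_numpy()
    )
    step = pd.Timedelta(hours=step_hours)
    intervals = [
        (t, min(t + step, t1)) for t in pd.to_datetime(tracks.loc[hit, "time"])
    ]
    return season_hours - _union_hours(intervals)


def coastal_fill(field: xr.DataArray) -> xr.DataArray:
    """Fill missing cells by IDW from finite neighbours; finite cells untouched."""
    vals = field.values.astype(float)
    if not np.isfinite(vals).any():
        raise ValueError("cannot fill an all-missing field")
    if np.isfinite(vals).all():
        return field.copy()
    LA, LO = np.meshgrid(field["lat"].values, field["lon"].values, indexing="ij")
    missing = ~np.isfinite(vals)
    filled = vals.copy()
    filled[missing] = idw_interpolate(
        LO[~missing], LA[~missing], vals[~missing], LO[missing], LA[missing]
    )
    out = field.copy(data=filled)
    return out


# ---------------------------------------------------------------------------
# observation/covariate join
# ---------------------------------------------------------------------------

def _nearest_index(grid: np.ndarray, x: np.ndarray) -> np.ndarray:
    i = np.clip(np.searchsorted(grid, x), 1, len(grid) - 1)
    left = grid[i - 1]
    right = grid[i]
    return np.where(np.abs(x - left) <= np.abs(right - x), i - 1, i)


def extract_at_records(
    records: pd.DataFrame,
    sst: xr.DataArray,
    clim: ClimatologySet,
    spec: idx.IndexSpec,
    uvb_monthly: xr.DataArray,
    k490_composite: xr.DataArray,
    speed_composite: xr.DataArray,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Join thermal indices and environmental covariates to observation records.

    Per record: the thermal index with its trailing window ending on the
    record date; c = DCW; u = UV-B at the record's month; k and s from the
    July–September composites; v = sigma_m at the cell; d = the observer-
    reported depth.  Records outside the domain or with an uncovered index
    window are excluded and returned separately with the reason.

    Returns (covariate table, excluded records).
    """
    lats = sst["lat"].values
    lons = sst["lon"].values
    time_index = sst.indexes["time"]
    rows, excluded = [], []

    baseline_field = clim.mmm if spec.baseline == "mmm" else clim.mmm_max
    for rec in records.itertuples():
        lon, lat = float(rec.lon), float(rec.lat)
        date = pd.Timestamp(rec.date)
        if not (
            lons.min() - 1e-9 <= lon <= lons.max() + 1e-9
            and lats.min() - 1e-9 <= lat <= lats.max() + 1e-9
        ):
            excluded.append({**rec._asdict(), "reason": "outside domain"})
            continue
        iy = int(_nearest_index(lats, np.array([lat]))[0])
        ix = int(_nearest_index(lons, np.array([lon]))[0])
        if date < time_index[0] or date > time_index[-1]:
            excluded.append({**rec._asdict(), "reason": "date outside SST span"})
            continue
        it = time_index.searchsorted(date, side="right")
        series = sst.values[:it, iy, ix]
        mmm = float(clim.mmm.values[iy, ix])
        sigma = float(clim.sigma_m.values[iy, ix])
        baseline = float(baseline_field.values[iy, ix])
        threshold = spec.threshold(sigma)
        try:
            hs = idx.hotspots(series, baseline)
            if spec.kind == "dhw":
                index_value = idx.degree_heating_week(hs, threshold)
            elif spec.kind == "dhm":
                monthly = (
                    pd.Series(series, index=time_index[:it]).resample("MS").mean()
                )
                hs_m = idx.hotspots(monthly.to_numpy(), baseline)
                index_value = idx.degree_heating_month(hs_m, threshold)
            elif spec.kind == "weekly_sst":
                index_value = idx.trailing_mean_sst(series, 7)
            elif spec.kind == "monthly_sst":
                index_value = idx.trailing_mean_sst(series, 30)
            else:
                raise ValueError(f"unsupported index kind {spec.kind!r}")
            dcw = idx.degree_cooling_week(series, mmm)
        except ValueError as err:
            excluded.append({**rec._asdict(), "reason": str(err)})
            continue
        u = float(
            uvb_monthly.sel(time=date.strftime("%Y-%m-01")).values[iy, ix]
        )
        row = {
            "lon": lon,
            "lat": lat,
            "date": date,
            "depth_m": float(getattr(rec, "depth_m")),
            spec.column: index_value,
            "c": dcw,
            "u": u,
            "k": float(k490_composite.values[iy, ix]),
            "d": float(getattr(rec, "depth_m")),
            "s": float(speed_composite.values[iy, ix]),
            "v": sigma,
        }
        for extra in ("bleached", "severity", "nonthermal_flag", "source"):
            if hasattr(rec, extra):
                row[extra] = getattr(rec, extra)
        rows.append(row)

    table = pd.DataFrame(rows)
    excluded_df = pd.DataFrame(excluded)
    return table, excluded_df


# ---------------------------------------------------------------------------
# collinearity screening
# ---------------------------------------------------------------------------

@dataclass
class CollinearityReport:
    pairs: pd.DataFrame  # all pairs with |r|
    dropped: list[str] = field(default_factory=list)
    constant: list[str] = field(default_factory=list)


def collinearity_screen(
    table: pd.DataFrame,
    variables: Sequence[str],
    cutoff: float = 0.7,
    priority: Sequence[str] | None = None,
) -> tuple[list[str], CollinearityReport]:
    """Drop the lower-priority member of each highly correlated pair.

    Pairwise Pearson |r| is computed over ``variables``; for any pair with
    |r| > cutoff the variable later in ``priority`` (default: the given
    column order, thermal indices first) is dropped.  Constant columns have
    undefined correlations and are flagged, not dropped.
    """
    if len(table) < 3:
        raise ValueError("need at least 3 rows to screen collinearity")
    variables = list(variables)
    priority = list(priority) if priority is not None else variables
    rank = {v: priority.index(v) if v in priority else len(priority) for v in variables}

    constant = [v for v in variables if table[v].nunique() <= 1]
    usable = [v for v in variables if v not in constant]
    corr = table[usable].corr(method="pearson")

    pairs = []
    dropped: set[str] = set()
    for i, a in enumerate(usable):
        for b in usable[i + 1 :]:
            r = float(corr.loc[a, b])
            pairs.append({"var_a": a, "var_b": b, "r": r, "flagged": abs(r) > cutoff})
    # resolve worst pairs first so one drop can clear several conflicts
    for p in sorted(pairs, key=lambda q: -abs(q["r"])):
        if not p["flagged"]:
            continue
        a, b = p["var_a"], p["var_b"]
        if a in dropped or b in dropped:
            continue
        dropped.add(a if rank[a] > rank[b] else b)
    retained = [v for v in usable if v not in dropped]
    report = CollinearityReport(
        pairs=pd.DataFrame(pairs), dropped=sorted(dropped), constant=constant
    )
    return retained, report
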