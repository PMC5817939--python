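"""Synthetic ocean and observation generator.

Every downstream stage of the bleaching pipeline (climatology, thermal
indices, covariate extraction, model fitting, threshold searches) is
exercised against data from this module, so the generating process is fully
known: daily SST is a seasonal cosine plus a linear warming trend, smooth
spatial structure, optional heat-wave anomalies and white noise; covariate
fields are smooth positive surfaces; bleaching outcomes are Bernoulli draws
from a logistic model with known coefficients.  Nothing here attempts ocean
dynamics — only the statistical structure the analysis assumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import xarray as xr

__all__ = [
    "AnomalyEvent",
    "SyntheticScenario",
    "generate_sst",
    "generate_covariates",
    "sample_observation_sites",
    "generate_observations",
    "generate_typhoon_tracks",
]

# substream tags: one independent bit-generator per generator function, so
# adding a generator never perturbs the draws of another
_STREAM_SST = 0
_STREAM_COVARIATES = 1
_STREAM_SITES = 2
_STREAM_OBSERVATIONS = 3
_STREAM_TYPHOONS = 4


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(stream,)))


@dataclass(frozen=True)
class AnomalyEvent:
    """A transient marine heat wave: a Gaussian bump in space and time."""

    start: str  # ISO date of onset
    duration_days: int
    peak: float  # °C at the spatial/temporal centre
    center_lon: float | None = None  # default: domain centre
    center_lat: float | None = None
    sigma_deg: float = 0.5  # spatial footprint (Gaussian SD, degrees)


@dataclass(frozen=True)
class SyntheticScenario:
    """Parameters of the synthetic world.

    Defaults describe a subtropical reef domain (Ryukyu-like): mean SST
    25 °C with a 4 °C seasonal swing peaking mid-August, a 0.02 °C/yr
    warming trend, 0.3 °C daily noise and modest interannual variability
    in the summer maximum.
    """

    grid_shape: tuple[int, int] = (6, 6)  # (n_lat, n_lon)
    cell_size: float = 0.01  # degrees (1 km-scale cells)
    lat0: float = 24.0
    lon0: float = 123.0
    years: tuple[int, int] = (1985, 2016)  # inclusive span
    seasonal_mean: float = 25.0  # °C
    seasonal_amplitude: float = 4.0  # °C
    amplitude_gradient: float = 0.5  # °C change in amplitude across the domain
    peak_doy: float = 227.0  # mid-August seasonal maximum
    trend: float = 0.02  # °C per year
    interannual_sd: float = 0.2  # °C SD of per-year summer-peak anomalies
    noise_sd: float = 0.3  # °C daily white noise
    anomaly_events: tuple[AnomalyEvent, ...] = ()
    # generating logistic model: intercept + slope per covariate column
    true_coefficients: Mapping[str, float] = field(
        default_factory=lambda: {"intercept": -1.0, "dhw": 0.9}
    )
    n_observations: int = 668
    obs_months: tuple[int, int] = (7, 10)  # July–October bleaching season
    nonthermal_fraction: float = 0.0  # fraction of bleached records flagged
    n_typhoons: int = 3
    typhoon_wind: float = 25.0  # m/s, above the 15 m/s exposure cutoff
    seed: int = 0

    def validate(self) -> None:
        if self.grid_shape[0] <= 0 or self.grid_shape[1] <= 0:
            raise ValueError(f"grid_shape must be positive, got {self.grid_shape}")
        if self.years[1] < self.years[0]:
            raise ValueError(f"invalid year span {self.years}")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.interannual_sd < 0:
            raise ValueError("interannual_sd must be >= 0")
        if self.n_observations < 1:
            raise ValueError("n_observations must be >= 1")
        if "intercept" not in self.true_coefficients:
            raise ValueError("true_coefficients must include an 'intercept'")

    # --- coordinate helpers -------------------------------------------------
    @property
    def lats(self) -> np.ndarray:
        return self.lat0 + self.cell_size * np.arange(self.grid_shape[0])

    @property
    def lons(self) -> np.ndarray:
        return self.lon0 + self.cell_size * np.arange(self.grid_shape[1])

    @property
    def n_years(self) -> int:
        return self.years[1] - self.years[0] + 1


def _smooth_field(
    rng: np.random.Generator,
    lats: np.ndarray,
    lons: np.ndarray,
    mean: float,
    rel_amplitude: float = 0.2,
    n_modes: int = 3,
) -> np.ndarray:
    """Smooth positive field: mean modulated by random low-order sinusoids."""
    la = (lats - lats.min()) / max(np.ptp(lats), 1e-12)
    lo = (lons - lons.min()) / max(np.ptp(lons), 1e-12)
    LA, LO = np.meshgrid(la, lo, indexing="ij")
    f = np.zeros_like(LA)
    for _ in range(n_modes):
        kx, ky = rng.integers(1, 3, size=2)
        phx, phy = rng.uniform(0, 2 * np.pi, size=2)
        f += rng.normal(0, 1) * np.sin(kx * np.pi * LA + phx) * np.sin(
            ky * np.pi * LO + phy
        )
    f /= max(np.abs(f).max(), 1e-12)
    out = mean * (1.0 + rel_amplitude * f)
    return np.maximum(out, 0.05 * mean)


def generate_sst(scenario: SyntheticScenario, land_mask: bool = False) -> xr.DataArray:
    """Daily SST cube on (time, lat, lon).

    SST(t, x) = seasonal_mean + A(x) * cos(2π (doy − peak_doy)/365.25)
                + trend * (t − t0)  + interannual peak anomaly
                + heat-wave anomalies + N(0, noise_sd).
    """
    scenario.validate()
    rng = _rng(scenario.seed, _STREAM_SST)
    y0, y1 = scenario.years
    time = pd.date_range(f"{y0}-01-01", f"{y1}-12-31", freq="D")
    lats, lons = scenario.lats, scenario.lons
    nt, ny, nx = len(time), len(lats), len(lons)

    # leap-adjusted day-of-year so each calendar date repeats its seasonal
    # value exactly across years (Feb 29 mirrors Feb 28)
    doy = time.dayofyear.to_numpy(dtype=float)
    leap_shift = np.asarray(time.is_leap_year) & (doy > 59)
    doy = doy - leap_shift
    t_years = (time - time[0]).days.to_numpy(dtype=float) / 365.25
    seasonal_shape = np.cos(2 * np.pi * (doy - scenario.peak_doy) / 365.0)

    # amplitude varies smoothly across the domain (SW–NE gradient)
    gy = np.linspace(0, 1, ny)[:, None]
    gx = np.linspace(0, 1, nx)[None, :]
    amplitude = scenario.seasonal_amplitude + scenario.amplitude_gradient * (
        gy + gx
    ) / 2.0

    sst = (
        scenario.seasonal_mean
        + seasonal_shape[:, None, None] * amplitude[None, :, :]
        + (scenario.trend * t_years)[:, None, None]
    )

    # interannual variability of the summer maximum: a per-year amplitude
    # anomaly acting on the positive phase of the seasonal cycle, with a
    # smooth spatial modulation so sigma_m varies across the domain
    if scenario.interannual_sd > 0:
        eps = rng.normal(0.0, scenario.interannual_sd, size=scenario.n_years)
        year_idx = time.year.to_numpy() - y0
        spatial_mod = 0.5 + (gy + gx) / 2.0  # in [0.5, 1.5]
        pos_phase = np.maximum(seasonal_shape, 0.0)
        sst += (eps[year_idx] * pos_phase)[:, None, None] * spatial_mod[None, :, :]

    for ev in scenario.anomaly_events:
        start = pd.Timestamp(ev.start)
        tt = (time - start).days.to_numpy(dtype=float)
        inside = (tt >= 0) & (tt < ev.duration_days)
        if not inside.any():
            continue
        # half-sine temporal profile peaking mid-event
        temporal = np.zeros(nt)
        temporal[inside] = np.sin(np.pi * tt[inside] / ev.duration_days)
        clon = ev.center_lon if ev.center_lon is not None else lons.mean()
        clat = ev.center_lat if ev.center_lat is not None else lats.mean()
        LA, LO = np.meshgrid(lats, lons, indexing="ij")
        footprint = np.exp(
            -((LA - clat) ** 2 + (LO - clon) ** 2) / (2 * ev.sigma_deg**2)
        )
        sst += ev.peak * temporal[:, None, None] * footprint[None, :, :]

    if scenario.noise_sd > 0:
        sst += rng.normal(0.0, scenario.noise_sd, size=(nt, ny, nx))

    da = xr.DataArray(
        sst,
        coords={"time": time, "lat": lats, "lon": lons},
        dims=("time", "lat", "lon"),
        name="sst",
        attrs={"units": "degC", "long_name": "sea surface temperature"},
    )
    if land_mask:
        # mask the NW corner cell as land
        da = da.where(~((da.lat == lats[-1]) & (da.lon == lons[0])))
    return da


def generate_covariates(
    scenario: SyntheticScenario,
    constants: Mapping[str, float] | None = None,
) -> xr.Dataset:
    """Smooth covariate fields: UV-B (monthly), K490 (monthly), currents, depth.

    Units: uvb W m-2, k490 m-1, u/v current m s-1, depth m.  ``constants``
    pins any variable to a spatially/temporally constant value.
    """
    scenario.validate()
    constants = dict(constants or {})
    rng = _rng(scenario.seed, _STREAM_COVARIATES)
    lats, lons = scenario.lats, scenario.lons
    y0, y1 = scenario.years
    months = pd.date_range(f"{y0}-01-01", f"{y1}-12-01", freq="MS")

    def static(name: str, mean: float, rel: float = 0.2) -> xr.DataArray:
        if name in constants:
            vals = np.full(scenario.grid_shape, float(constants[name]))
        else:
            vals = _smooth_field(rng, lats, lons, mean, rel)
        return xr.DataArray(
            vals, coords={"lat": lats, "lon": lons}, dims=("lat", "lon"), name=name
        )

    # monthly UV-B: smooth spatial base with a summer-peaked seasonal cycle
    uvb_base = static("uvb", 5.0, 0.15)
    season = 1.0 + 0.6 * np.cos(2 * np.pi * (months.month - 8) / 12.0)
    uvb = uvb_base.expand_dims(time=months) * xr.DataArray(
        season, coords={"time": months}, dims=("time",)
    )
    if "uvb" in constants:
        uvb = xr.full_like(uvb, float(constants["uvb"]))
    uvb.name = "uvb"
    uvb.attrs = {"units": "W m-2", "long_name": "UV-B irradiance"}

    k_base = static("k490", 0.05, 0.3)
    k_season = 1.0 + 0.2 * np.cos(2 * np.pi * (months.month - 7) / 12.0)
    k490 = k_base.expand_dims(time=months) * xr.DataArray(
        k_season, coords={"time": months}, dims=("time",)
    )
    if "k490" in constants:
        k490 = xr.full_like(k490, float(constants["k490"]))
    k490.name = "k490"
    k490.attrs = {"units": "m-1", "long_name": "diffuse attenuation at 490 nm"}

    u = static("u_current", 0.2, 0.5)
    v = static("v_current", 0.2, 0.5)
    if "u_current" not in constants:
        u = abs(u)
    if "v_current" not in constants:
        v = abs(v)
    depth = static("depth", 8.0, 0.5)

    u.attrs = {"units": "m s-1"}
    v.attrs = {"units": "m s-1"}
    depth.attrs = {"units": "m"}
    return xr.Dataset(
        {"uvb": uvb, "k490": k490, "u_current": u, "v_current": v, "depth": depth}
    )


def sample_observation_sites(
    scenario: SyntheticScenario,
    years: Sequence[int] | None = None,
) -> pd.DataFrame:
    """Random observation sites and dates within the bleaching season.

    Dates fall in ``scenario.obs_months`` (July–October by default) of the
    requested years (default: the last 5 years of the scenario span, leaving
    the earlier years for the climatology).
    """
    scenario.validate()
    rng = _rng(scenario.seed, _STREAM_SITES)
    if years is None:
        y1 = scenario.years[1]
        years = list(range(max(scenario.years[0], y1 - 4), y1 + 1))
    lats, lons = scenario.lats, scenario.lons
    n = scenario.n_observations
    lat = rng.uniform(lats.min(), lats.max(), size=n)
    lon = rng.uniform(lons.min(), lons.max(), size=n)
    year = rng.choice(np.asarray(years), size=n)
    m0, m1 = scenario.obs_months
    month = rng.integers(m0, m1 + 1, size=n)
    day = rng.integers(1, 29, size=n)  # avoid month-length bookkeeping
    date = pd.to_datetime(
        {"year": year, "month": month, "day": day}
    )
    depth = np.round(rng.uniform(1.0, 15.0, size=n), 1)
    return pd.DataFrame(
        {"lon": lon, "lat": lat, "date": date, "depth_m": depth}
    )


def generate_observations(
    scenario: SyntheticScenario, covariates: pd.DataFrame
) -> pd.DataFrame:
    """Draw bleached/nonbleached outcomes from the known logistic model.

    ``covariates`` has one row per prospective record with the columns named
    by ``scenario.true_coefficients`` (minus the intercept), plus
    lon/lat/date/depth_m carried through.  Returns the record table with
    ``bleached`` in {0,1}, a severity label, a nonthermal flag and a source
    tag.
    """
    scenario.validate()
    coeffs = dict(scenario.true_coefficients)
    intercept = coeffs.pop("intercept")
    missing = [c for c in coeffs if c not in covariates.columns]
    if missing:
        raise ValueError(
            f"true_coefficients refer to covariates absent from the table: {missing}"
        )
    rng = _rng(scenario.seed, _STREAM_OBSERVATIONS)
    eta = np.full(len(covariates), float(intercept))
    for name, slope in coeffs.items():
        eta = eta + slope * covariates[name].to_numpy(dtype=float)
    p = 1.0 / (1.0 + np.exp(-eta))
    bleached = (rng.uniform(size=len(p)) < p).astype(int)

    severity = np.where(bleached == 1, "low", "none").astype(object)
    strong = bleached == 1
    if strong.any():
        draws = rng.uniform(size=strong.sum())
        labels = np.where(draws < 0.33, "high", np.where(draws < 0.66, "medium", "low"))
        severity[strong] = labels

    nonthermal = np.zeros(len(p), dtype=bool)
    if scenario.nonthermal_fraction > 0:
        nonthermal = (rng.uniform(size=len(p)) < scenario.nonthermal_fraction) & (
            bleached == 1
        )

    out = covariates.copy()
    out["bleached"] = bleached
    out["severity"] = severity
    out["nonthermal_flag"] = nonthermal
    out["source"] = "synthetic"
    return out


def generate_typhoon_tracks(
    scenario: SyntheticScenario,
    season: tuple[str, str] | None = None,
    step_hours: float = 6.0,
    duration_days: float = 3.0,
) -> pd.DataFrame:
    """Typhoon track points: (track_id, time, lat, lon, max_wind_ms).

    Tracks start south of the domain and move northward with a random
    eastward drift; winds are constant at ``scenario.typhoon_wind``.  Only
    the statistical structure needed for the calm-duration index is
    emulated.
    """
    scenario.validate()
    rng = _rng(scenario.seed, _STREAM_TYPHOONS)
    if season is None:
        y = scenario.years[1]
        season = (f"{y}-07-01", f"{y}-10-31")
    t0, t1 = pd.Timestamp(season[0]), pd.Timestamp(season[1])
    rows = []
    n_steps = int(duration_days * 24 / step_hours)
    lats, lons = scenario.lats, scenario.lons
    for tid in range(scenario.n_typhoons):
        start = t0 + pd.Timedelta(
            seconds=float(rng.uniform(0, max((t1 - t0).total_seconds() - 1, 1)))
        )
        lat = lats.min() - 1.0 + rng.uniform(-0.5, 0.5)
        lon = rng.uniform(lons.min() - 0.5, lons.max() + 0.5)
        dlat = rng.uniform(0.1, 0.3)  # degrees per step, northward
        dlon = rng.uniform(-0.1, 0.1)
        for k in range(n_steps):
            rows.append(
                {
                    "track_id": tid,
                    "time": start + pd.Timedelta(hours=k * step_hours),
                    "lat": lat + k * dlat,
                    "lon": lon + k * dlon,
                    "max_wind_ms": scenario.typhoon_wind,
                }
            )
    if not rows:
        return pd.DataFrame(columns=["track_id", "time", "lat", "lon", "max_wind_ms"])
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# planted-ground-truth statistical worlds
# ---------------------------------------------------------------------------

@dataclass
class PlantedFilterWorld:
    """Per-record daily HotSpot series whose bleaching outcomes depend on
    DHW computed at one known filtering threshold.

    Each record carries an 84-day HotSpot window split into "signal" days
    (HS just above the planted threshold, uniform on [alpha, 1.6*alpha])
    and "nuisance" days (HS just below it, uniform on [0.6*alpha, alpha)).
    Signal-day counts drive the bleaching probability through
    logistic(intercept + slope * DHW(alpha_true)); nuisance-day counts are
    independent of the outcome and highly variable across records.
    Under-filtering (threshold below alpha_true) therefore floods the
    predictor with uncorrelated noise, while over-filtering discards
    signal days — the test-TSS profile of a threshold search peaks at the
    planted value by construction.
    """

    hs: np.ndarray  # (n_records, 84)
    bleached: np.ndarray
    alpha_true: float
    intercept: float
    slope: float

    def build_table(self, threshold: float) -> pd.DataFrame:
        from .indices import degree_heating_week

        dhw = np.array(
            [degree_heating_week(row, threshold) for row in self.hs]
        )
        return pd.DataFrame({"dhw": dhw, "bleached": self.bleached})


def planted_filter_world(
    n: int = 668,
    alpha_true: float = 0.5,
    slope: float = 3.0,
    seed: int = 0,
) -> PlantedFilterWorld:
    """Synthetic cohort with a known optimal DHW filtering threshold."""
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(5,)))
    hs = np.zeros((n, 84))
    for i in range(n):
        n_signal = rng.integers(0, 29)
        n_nuisance = rng.integers(0, 57)  # high-variance, outcome-independent
        days = rng.permutation(84)
        hs[i, days[:n_signal]] = rng.uniform(alpha_true, 1.6 * alpha_true, n_signal)
        hs[i, days[n_signal : n_signal + n_nuisance]] = rng.uniform(
            0.6 * alpha_true, 0.999 * alpha_true, n_nuisance
        )
    signal_dhw = np.array(
        [row[row >= alpha_true].sum() / 7.0 for row in hs]
    )
    intercept = -float(slope * signal_dhw.mean())  # balanced cohort
    p = 1.0 / (1.0 + np.exp(-(intercept + slope * signal_dhw)))
    bleached = (rng.uniform(size=n) < p).astype(int)
    return PlantedFilterWorld(
        hs=hs, bleached=bleached, alpha_true=alpha_true,
        intercept=intercept, slope=slope,
    )


def planted_support_table(
    n: int = 668,
    seed: int = 0,
    slopes: Mapping[str, float] | None = None,
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Covariate table whose response uses only part of the covariate set.

    Default generating model uses the thermal index (dhw), cooling (c),
    UV-B (u) and turbidity (k); historical variability (v), depth (d) and
    current speed (s) are pure noise.  The intercept is chosen to centre
    the linear predictor, giving a roughly balanced cohort.  Returns the
    table and the full coefficient dictionary (zeros included).
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(6,)))
    table = pd.DataFrame(
        {
            "dhw": rng.gamma(2.0, 1.5, n),  # °C-weeks
            "c": rng.gamma(1.5, 0.8, n),  # DCW °C-weeks
            "u": rng.normal(5.0, 0.8, n),  # UV-B W/m2
            "k": np.clip(rng.normal(0.05, 0.012, n), 1e-3, None),  # K490 1/m
            "d": rng.uniform(1.0, 15.0, n),  # depth m
            "s": np.abs(rng.normal(0.3, 0.15, n)),  # current m/s
            "v": rng.uniform(0.36, 0.71, n),  # sigma_m °C
        }
    )
    if slopes is None:
        slopes = {"dhw": 0.9, "c": -0.6, "u": 1.2, "k": -100.0,
                  "d": 0.0, "s": 0.0, "v": 0.0}
    eta = np.zeros(n)
    for name, b in slopes.items():
        eta += b * table[name].to_numpy()
    intercept = -float(eta.mean())
    p = 1.0 / (1.0 + np.exp(-(intercept + eta)))
    table["bleached"] = (rng.uniform(size=n) < p).astype(int)
    coeffs = {"intercept": intercept, **slopes}
    return table, coeffs
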