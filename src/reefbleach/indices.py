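"""HotSpots and accumulated thermal stress / cooling indices.

Definitions (all trailing windows end on the evaluation date):

* HotSpot:  HS_i = max(SST_i − baseline, 0), baseline MMM or MMM_max.
* DHW  = (1/7) Σ over the trailing 84 days of HS_i where HS_i ≥ threshold
  (°C-weeks).  The full HS value is accumulated once it passes the filter,
  not the excess above it.
* DHM  = Σ over the trailing 12 months of monthly HS_i ≥ threshold
  (°C-months).
* DCW  = (1/7) Σ over the trailing 84 days of max(MMM − SST_i, 0)
  (°C-weeks); the cool-spot filter is fixed at 0.
* Weekly / monthly SST: trailing arithmetic means.

Standard alert rules: monthly SST > 30 °C, weekly SST > 31.5 °C, DHW > 4,
DHM > 1, and the variability-scaled rule DHW > 2.45·sigma_m (2.45 °C⁻¹
being the reciprocal of the global median sigma_m).  Filter comparisons are
``>=``; alert comparisons are strict ``>``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
import xarray as xr

__all__ = [
    "IndexSpec",
    "DHW_WINDOW_DAYS",
    "DHM_WINDOW_MONTHS",
    "SIGMA_ALERT_COEF",
    "hotspots",
    "degree_heating_week",
    "degree_heating_month",
    "degree_cooling_week",
    "trailing_mean_sst",
    "standard_alert",
    "dhw_cube",
    "dhm_cube",
    "dcw_cube",
]

DHW_WINDOW_DAYS = 84
DHM_WINDOW_MONTHS = 12
#: reciprocal of the global median sigma_m, used by the sigma-scaled alert
SIGMA_ALERT_COEF = 2.45
#: fraction of an accumulation window that must be present; shorter gaps
#: are renormalized by (window / valid days)
MIN_VALID_FRACTION = 0.9

ALERT_MONTHLY_SST = 30.0
ALERT_WEEKLY_SST = 31.5
ALERT_DHW = 4.0
ALERT_DHM = 1.0


@dataclass(frozen=True)
class IndexSpec:
    """Declarative description of a thermal index variant.

    ``filter_mode`` selects between a constant filtering threshold alpha
    (°C) and a threshold scaled to local historical variability,
    beta·sigma_m.  The degree-cooling-week filter is fixed at 0 regardless.
    """

    kind: Literal["monthly_sst", "weekly_sst", "dhm", "dhw", "dcw"] = "dhw"
    baseline: Literal["mmm", "mmm_max"] = "mmm"
    filter_mode: Literal["constant_alpha", "sigma_scaled_beta"] = "constant_alpha"
    alpha: float = 1.0
    beta: float = 1.0
    alert_rule: Literal["fixed_value", "sigma_scaled"] = "fixed_value"

    def __post_init__(self) -> None:
        if self.filter_mode == "constant_alpha" and not (0.0 <= self.alpha <= 1.5):
            raise ValueError(f"alpha must lie in [0, 1.5], got {self.alpha}")
        if self.filter_mode == "sigma_scaled_beta" and not (0.1 <= self.beta <= 2.5):
            raise ValueError(f"beta must lie in [0.1, 2.5], got {self.beta}")

    def threshold(self, sigma_m: float | np.ndarray | xr.DataArray = np.nan):
        """Effective filtering threshold (°C) for this spec."""
        if self.kind == "dcw":
            return 0.0
        if self.filter_mode == "constant_alpha":
            return self.alpha
        return self.beta * sigma_m

    @property
    def column(self) -> str:
        """Covariate-table column this index populates."""
        return {"dhw": "dhw", "dhm": "dhm", "dcw": "c", "monthly_sst": "sst_month",
                "weekly_sst": "sst_week"}[self.kind]


# ---------------------------------------------------------------------------
# pointwise / series operations
# ---------------------------------------------------------------------------

def hotspots(sst, baseline):
    """Positive-only SST anomaly above the baseline climatology."""
    if isinstance(sst, xr.DataArray):
        return xr.where(sst > baseline, sst - baseline, 0.0).where(sst.notnull())
    sst = np.asarray(sst, dtype=float)
    hs = np.where(sst > baseline, sst - baseline, 0.0)
    hs[~np.isfinite(sst)] = np.nan
    return hs


def _accumulate(values: np.ndarray, threshold: float, window: int, scale: float,
                allow_missing: bool) -> float:
    """Filtered trailing accumulation shared by DHW/DHM/DCW."""
    values = np.asarray(values, dtype=float)
    if len(values) < window:
        raise ValueError(
            f"need at least {window} trailing values, got {len(values)}"
        )
    tail = values[-window:]
    valid = np.isfinite(tail)
    n_valid = int(valid.sum())
    if n_valid < window:
        if not allow_missing or n_valid < MIN_VALID_FRACTION * window:
            raise ValueError(
                f"window has {window - n_valid} missing values "
                f"(max allowed {(1 - MIN_VALID_FRACTION) * window:.0f})"
            )
    kept = tail[valid]
    total = kept[kept >= threshold].sum()
    if n_valid < window:  # renormalize a lightly gappy window
        total *= window / n_valid
    return float(total * scale)


def degree_heating_week(
    hs: np.ndarray, threshold: float = 1.0, allow_missing: bool = True
) -> float:
    """DHW (°C-weeks) from a daily HotSpot series ending on the target date."""
    return _accumulate(hs, threshold, DHW_WINDOW_DAYS, 1.0 / 7.0, allow_missing)


def degree_heating_month(
    hs_monthly: np.ndarray, threshold: float = 1.0, allow_missing: bool = False
) -> float:
    """DHM (°C-months) from a monthly HotSpot series ending on the target month."""
    return _accumulate(hs_monthly, threshold, DHM_WINDOW_MONTHS, 1.0, allow_missing)


def degree_cooling_week(sst: np.ndarray, mmm: float, allow_missing: bool = True) -> float:
    """DCW (°C-weeks): accumulated non-negative (MMM − SST) over 84 days."""
    sst = np.asarray(sst, dtype=float)
    cool = np.where(np.isfinite(sst), np.maximum(mmm - sst, 0.0), np.nan)
    return _accumulate(cool, 0.0, DHW_WINDOW_DAYS, 1.0 / 7.0, allow_missing)


def trailing_mean_sst(sst: np.ndarray, window: int) -> float:
    """Arithmetic mean of the trailing ``window`` values (7 d or ~1 month)."""
    sst = np.asarray(sst, dtype=float)
    if len(sst) < window:
        raise ValueError(f"need {window} trailing values, got {len(sst)}")
    tail = sst[-window:]
    if not np.isfinite(tail).all():
        raise ValueError("incomplete trailing window (missing values)")
    return float(tail.mean())


def standard_alert(
    kind: str,
    value: float,
    sigma_m: float | None = None,
    rule: str = "fixed_value",
) -> bool:
    """Bleaching alert decision (strict > comparisons).

    Fixed rules: monthly SST > 30, weekly SST > 31.5, DHW > 4, DHM > 1.
    Sigma-scaled rule (DHW only): DHW > 2.45 · sigma_m.
    """
    if rule == "sigma_scaled":
        if sigma_m is None:
            raise ValueError("sigma_scaled alert requires sigma_m")
        return bool(value > SIGMA_ALERT_COEF * sigma_m)
    cutoff = {
        "monthly_sst": ALERT_MONTHLY_SST,
        "weekly_sst": ALERT_WEEKLY_SST,
        "dhw": ALERT_DHW,
        "dhm": ALERT_DHM,
    }.get(kind)
    if cutoff is None:
        raise ValueError(f"no fixed alert rule for index kind {kind!r}")
    return bool(value > cutoff)


# ---------------------------------------------------------------------------
# vectorized cube operations
# ---------------------------------------------------------------------------

def _rolling_filtered_sum(da: xr.DataArray, threshold, window: int) -> xr.DataArray:
    filtered = xr.where(da >= threshold, da, 0.0).where(da.notnull())
    total = filtered.rolling(time=window, min_periods=window).sum()
    return total


def dhw_cube(hs: xr.DataArray, threshold=1.0) -> xr.DataArray:
    """Rolling DHW over a daily HotSpot cube (NaN until the window fills).

    ``threshold`` may be a scalar (constant alpha) or a per-cell field
    (beta·sigma_m).
    """
    out = _rolling_filtered_sum(hs, threshold, DHW_WINDOW_DAYS) / 7.0
    out.name = "dhw"
    out.attrs = {"units": "degC weeks"}
    return out


def dhm_cube(hs_monthly: xr.DataArray, threshold=1.0) -> xr.DataArray:
    """Rolling DHM over a monthly HotSpot field."""
    out = _rolling_filtered_sum(hs_monthly, threshold, DHM_WINDOW_MONTHS)
    out.name = "dhm"
    out.attrs = {"units": "degC months"}
    return out


def dcw_cube(sst: xr.DataArray, mmm: xr.DataArray) -> xr.DataArray:
    """Rolling DCW over a daily SST cube against the MMM baseline."""
    cool = xr.where(mmm - sst > 0, mmm - sst, 0.0).where(sst.notnull())
    out = cool.rolling(time=DHW_WINDOW_DAYS, min_periods=DHW_WINDOW_DAYS).sum() / 7.0
    out.name = "dcw"
    out.attrs = {"units": "degC weeks"}
    return out
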