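"""Bleaching observation records: parsing, validation, quality control and
the spatial-autocorrelation check on model residuals.

Records are point observations (lon, lat, date, depth, severity, 0/1
bleached flag).  Quality control reclassifies small non-thermal bleaching
events (microatolls, disease, predation) as nonbleaching wherever the
local DHW is zero — bleaching without any accumulated thermal stress is
not the signal the thermal model should learn.  Moran's I on residuals
guards against spatially clustered data inflating false positives.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .covariates import _haversine_km

__all__ = [
    "REQUIRED_COLUMNS",
    "SEVERITY_LEVELS",
    "ParseReport",
    "parse_records",
    "qc_reclassify",
    "MoransResult",
    "morans_i",
]

REQUIRED_COLUMNS = ("lon", "lat", "date", "depth_m", "severity", "bleached")
SEVERITY_LEVELS = ("high", "medium", "low", "none", "NA")
STUDY_ERA = (pd.Timestamp("2004-01-01"), pd.Timestamp("2016-12-31"))


@dataclass
class ParseReport:
    n_read: int = 0
    n_valid: int = 0
    rejected: list[dict] = field(default_factory=list)  # line number + reason


def parse_records(
    path: str | Path,
    study_era: tuple[pd.Timestamp, pd.Timestamp] | None = STUDY_ERA,
) -> tuple[pd.DataFrame, ParseReport]:
    """Read and validate a bleaching-record CSV.

    Malformed rows are reported with their (1-based, header-inclusive) line
    numbers and excluded; a missing mandatory column rejects the file.
    """
    path = Path(path)
    df = pd.read_csv(path)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing mandatory columns {missing}")
    report = ParseReport(n_read=len(df))

    def reject(mask: pd.Series, reason: str) -> None:
        for i in df.index[mask]:
            report.rejected.append({"line": int(i) + 2, "reason": reason})

    df["date"] = pd.to_datetime(df["date"], errors="coerce")
    bad_date = df["date"].isna()
    reject(bad_date, "unparseable date")

    lon = pd.to_numeric(df["lon"], errors="coerce")
    lat = pd.to_numeric(df["lat"], errors="coerce")
    bad_lon = ~lon.between(-180, 180)
    bad_lat = ~lat.between(-90, 90)
    reject(bad_lon & ~bad_date, "longitude outside [-180, 180]")
    reject(bad_lat & ~bad_date & ~bad_lon, "latitude outside [-90, 90]")

    bad_sev = ~df["severity"].astype(str).isin(SEVERITY_LEVELS)
    reject(bad_sev & ~bad_date & ~bad_lon & ~bad_lat, "unknown severity level")

    bleached = pd.to_numeric(df["bleached"], errors="coerce")
    bad_flag = ~bleached.isin([0, 1])
    inconsistent = (df["severity"].astype(str) == "none") & (bleached == 1)
    prior = bad_date | bad_lon | bad_lat | bad_sev
    reject(bad_flag & ~prior, "bleached flag not in {0, 1}")
    reject(inconsistent & ~prior & ~bad_flag, "severity 'none' with bleached=1")

    bad = prior | bad_flag | inconsistent
    if study_era is not None:
        out_of_era = ~df["date"].between(*study_era) & ~bad_date
        reject(out_of_era & ~bad, "date outside the study era")
        bad = bad | out_of_era

    clean = df[~bad].copy()
    clean["lon"] = lon[~bad]
    clean["lat"] = lat[~bad]
    clean["bleached"] = bleached[~bad].astype(int)
    if "nonthermal_flag" in clean.columns:
        clean["nonthermal_flag"] = clean["nonthermal_flag"].astype(bool)
    else:
        clean["nonthermal_flag"] = False
    if "source" not in clean.columns:
        clean["source"] = ""
    report.n_valid = len(clean)
    return clean.reset_index(drop=True), report


def qc_reclassify(
    records: pd.DataFrame, dhw_at_record: np.ndarray | pd.Series
) -> tuple[pd.DataFrame, int]:
    """Reclassify flagged non-thermal bleaching as nonbleaching when DHW = 0.

    Returns the updated records and the number of reclassifications.  Never
    changes a nonbleached record to bleached, and is idempotent.
    """
    dhw = np.asarray(dhw_at_record, dtype=float)
    if len(dhw) != len(records):
        raise ValueError("dhw_at_record must align with records")
    flagged = records["nonthermal_flag"].to_numpy(dtype=bool)
    if np.isnan(dhw[flagged]).any():
        raise ValueError("missing DHW for a flagged record")
    hit = flagged & (dhw == 0.0) & (records["bleached"].to_numpy() == 1)
    out = records.copy()
    out.loc[hit, "bleached"] = 0
    out.loc[hit, "severity"] = "none"
    return out, int(hit.sum())


# ---------------------------------------------------------------------------
# spatial autocorrelation
# ---------------------------------------------------------------------------

@dataclass
class MoransResult:
    statistic: float
    p_value: float
    n_permutations: int


def _inverse_distance_weights(
    lon: np.ndarray, lat: np.ndarray, cutoff_km: float | None
) -> np.ndarray:
    n = len(lon)
    d = _haversine_km(
        lon[:, None], lat[:, None], lon[None, :], lat[None, :]
    )
    with np.errstate(divide="ignore"):
        w = 1.0 / d
    np.fill_diagonal(w, 0.0)
    w[~np.isfinite(w)] = 0.0  # coincident points carry no self-ish weight
    if cutoff_km is not None:
        w[d > cutoff_km] = 0.0
    # row-standardize where a row has any neighbour
    rs = w.sum(axis=1, keepdims=True)
    nonzero = rs[:, 0] > 0
    w[nonzero] /= rs[nonzero]
    return w


def _morans_statistic(z: np.ndarray, w: np.ndarray) -> float:
    n = len(z)
    W = w.sum()
    return float((n / W) * (z @ w @ z) / (z @ z))


def morans_i(
    residuals: np.ndarray,
    lon: np.ndarray | None = None,
    lat: np.ndarray | None = None,
    weights: np.ndarray | None = None,
    cutoff_km: float | None = None,
    n_permutations: int = 999,
    seed: int = 0,
) -> MoransResult:
    """Moran's I of residuals with a permutation p-value (two-sided).

    Weights default to row-standardized inverse great-circle distance with
    an optional cutoff; an explicit (n, n) weight matrix may be supplied
    instead.  Constant residuals make the statistic undefined and are
    rejected.
    """
    z = np.asarray(residuals, dtype=float)
    if len(z) < 4:
        raise ValueError("Moran's I needs at least 4 points")
    if np.allclose(z, z[0]):
        raise ValueError("Moran's I is undefined for constant residuals")
    z = z - z.mean()
    if weights is None:
        if lon is None or lat is None:
            raise ValueError("either coordinates or an explicit weight matrix")
        weights = _inverse_distance_weights(
            np.asarray(lon, dtype=float), np.asarray(lat, dtype=float), cutoff_km
        )
    w = np.asarray(weights, dtype=float)
    observed = _morans_statistic(z, w)

    rng = np.random.default_rng(seed)
    perm = np.empty(n_permutations)
    for i in range(n_permutations):
        perm[i] = _morans_statistic(rng.permutation(z), w)
    extreme = np.abs(perm - perm.mean()) >= abs(observed - perm.mean()) - 1e-15
    p = (extreme.sum() + 1) / (n_permutations + 1)
    return MoransResult(
        statistic=observed, p_value=float(p), n_permutations=n_permutations
    )
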