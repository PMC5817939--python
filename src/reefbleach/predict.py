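"""Grid-wide bleaching probability maps, multi-year bleaching frequency,
and the UV-screening management scenario.

Probability maps average the predictions of the cross-validation model
ensemble cell by cell; the binary alert map applies the ensemble-mean
evaluation threshold.  The screening scenario rescales UV-B by 0.6 and
turbidity by 1.4 — the effect of shading reefs with fishery nets — and
repredicts.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import xarray as xr

from .models import FittedModel, predict_probability

__all__ = [
    "ScenarioSpec",
    "predict_grid",
    "bleaching_frequency",
    "apply_scenario",
]


@dataclass(frozen=True)
class ScenarioSpec:
    """Multiplicative covariate changes for the UV-screening scenario."""

    uv_factor: float = 0.6  # 40% UV-B reduction
    turbidity_factor: float = 1.4  # 40% turbidity increase

    def __post_init__(self) -> None:
        if self.uv_factor <= 0 or self.turbidity_factor <= 0:
            raise ValueError("scenario factors must be positive")


def _grids_to_table(grids: Mapping[str, xr.DataArray], variables) -> pd.DataFrame:
    missing = [v for v in variables if v not in grids]
    if missing:
        raise ValueError(f"missing covariate layer(s): {missing}")
    ref = grids[variables[0]]
    table = {}
    for v in variables:
        g = grids[v]
        if g.shape != ref.shape:
            raise ValueError(f"covariate layer {v!r} is not co-registered")
        table[v] = np.asarray(g.values, dtype=float).ravel()
    return pd.DataFrame(table)


def predict_grid(
    models: Sequence[FittedModel],
    grids: Mapping[str, xr.DataArray],
    threshold: float | None = None,
    per_member_binary: bool = False,
) -> xr.Dataset:
    """Ensemble-mean bleaching probability and binary alert per cell.

    ``grids`` maps covariate names (the model's variables) to co-registered
    2-D fields.  With ``per_member_binary`` each member votes with its own
    optimized threshold and the alert is the majority; otherwise the
    ensemble-mean probability is cut at ``threshold`` (default: mean of the
    members' evaluation thresholds).
    """
    if not models:
        raise ValueError("empty model ensemble")
    variables = list(models[0].spec.variables)
    ref = grids[variables[0]] if variables[0] in grids else None
    table = _grids_to_table(grids, variables)
    probs = np.stack([predict_probability(m, table) for m in models])
    mean_prob = probs.mean(axis=0)

    if threshold is None:
        member_thr = [
            m.evaluation_threshold for m in models if m.evaluation_threshold is not None
        ]
        threshold = float(np.mean(member_thr)) if member_thr else 0.5

    if per_member_binary:
        votes = np.stack(
            [
                p >= (m.evaluation_threshold if m.evaluation_threshold is not None else threshold)
                for p, m in zip(probs, models)
            ]
        )
        binary = votes.mean(axis=0) >= 0.5
    else:
        binary = mean_prob >= threshold

    shape = ref.shape
    coords = ref.coords
    dims = ref.dims
    ds = xr.Dataset(
        {
            "probability": (dims, mean_prob.reshape(shape)),
            "binary": (dims, binary.reshape(shape).astype(np.int8)),
        },
        coords=coords,
    )
    ds["probability"].attrs = {"long_name": "ensemble-mean bleaching probability"}
    ds.attrs["evaluation_threshold"] = float(threshold)
    return ds


def bleaching_frequency(binary_grids: Sequence[xr.DataArray]) -> xr.DataArray:
    """Percentage of years with a bleaching alert per cell (100 = all years)."""
    if len(binary_grids) == 0:
        raise ValueError("need at least one yearly binary grid")
    stack = xr.concat([g.astype(float) for g in binary_grids], dim="year_index")
    out = 100.0 * stack.mean("year_index")
    out.name = "bleaching_frequency"
    out.attrs = {"units": "%", "n_years": len(binary_grids)}
    return out


def apply_scenario(
    grids: Mapping[str, xr.DataArray],
    scenario: ScenarioSpec = ScenarioSpec(),
    uv_name: str = "u",
    turbidity_name: str = "k",
) -> dict[str, xr.DataArray]:
    """Rescale UV-B and turbidity layers; every other layer is untouched."""
    if uv_name not in grids or turbidity_name not in grids:
        raise ValueError(
            f"scenario needs {uv_name!r} and {turbidity_name!r} layers present"
        )
    out = {}
    for name, g in grids.items():
        if name == uv_name:
            out[name] = g * scenario.uv_factor
        elif name == turbidity_name:
            out[name] = g * scenario.turbidity_factor
        else:
            out[name] = g
    return out
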