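"""Pipeline orchestration: configuration, I/O, and end-to-end runs.

A single config drives the whole analysis: generate (or load) the gridded
inputs, build climatologies, attach thermal indices and covariates to the
observation records, quality-control them, screen collinearity, estimate
model skill by repeated cross-validation, and map predicted bleaching
probability and multi-year frequency under observed and UV-screened
conditions.  Every run writes a manifest with the seed, the resolved
configuration and a SHA-256 hash of each artifact.

Grids are NetCDF (written through xarray's scipy backend), tables CSV,
reports JSON.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import xarray as xr
import yaml

from . import covariates as cov
from . import indices as idx
from . import observations as obs
from . import optimize as opt
from . import predict as pred
from . import synthetic as syn
from .climatology import ClimatologySet, build_climatology, monthly_aggregate
from .models import ModelSpec, overdispersion_check

__all__ = [
    "PipelineConfig",
    "Pipeline",
    "run_pipeline",
    "read_grid",
    "write_grid",
    "read_records",
]

log = logging.getLogger("reefbleach")


# ---------------------------------------------------------------------------
# grid / record I/O
# ---------------------------------------------------------------------------

def write_grid(data: xr.DataArray | xr.Dataset, path: str | Path) -> Path:
    """Write a grid as NetCDF; returns the path."""
    path = Path(path)
    ds = data.to_dataset() if isinstance(data, xr.DataArray) else data
    ds.to_netcdf(path, engine="scipy")
    return path


def read_grid(path: str | Path) -> xr.Dataset:
    """Read a NetCDF grid, with a clean error on malformed input."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        return xr.open_dataset(path, engine="scipy").load()
    except Exception as err:
        raise ValueError(f"{path}: not a readable NetCDF grid ({err})") from err


def read_records(path: str | Path) -> pd.DataFrame:
    records, report = obs.parse_records(path)
    if report.rejected:
        log.warning("%d record rows rejected during parsing", len(report.rejected))
    return records


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    """Resolved configuration of one pipeline run."""

    scenario: syn.SyntheticScenario = field(default_factory=syn.SyntheticScenario)
    index_spec: idx.IndexSpec = field(default_factory=idx.IndexSpec)
    model_family: str = "glm"
    cv_repeats: int = 10
    test_fraction: float = 0.3
    run_threshold_search: bool = False
    search_mode: str = "alpha"
    screening: pred.ScenarioSpec = field(default_factory=pred.ScenarioSpec)
    prediction_years: tuple[int, ...] = ()
    constant_depth_m: float = 5.0
    output_dir: Path = Path("reefbleach_run")
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        scenario = syn.SyntheticScenario(**{
            **raw.get("scenario", {}),
            **(
                {"anomaly_events": tuple(
                    syn.AnomalyEvent(**e) for e in raw["scenario"]["anomaly_events"]
                )}
                if raw.get("scenario", {}).get("anomaly_events")
                else {}
            ),
        })
        index_spec = idx.IndexSpec(**raw.get("index_spec", {}))
        screening = pred.ScenarioSpec(**raw.get("screening", {}))
        kwargs: dict[str, Any] = {
            k: v
            for k, v in raw.items()
            if k not in ("scenario", "index_spec", "screening")
        }
        if "output_dir" in kwargs:
            kwargs["output_dir"] = Path(kwargs["output_dir"])
        if "prediction_years" in kwargs:
            kwargs["prediction_years"] = tuple(kwargs["prediction_years"])
        return cls(
            scenario=scenario, index_spec=index_spec, screening=screening, **kwargs
        )

    def resolved(self) -> dict:
        d = asdict(self)
        d["output_dir"] = str(self.output_dir)
        # tuples of dataclasses need explicit handling for JSON
        d["scenario"]["anomaly_events"] = [
            asdict(e) for e in self.scenario.anomaly_events
        ]
        return d


# ---------------------------------------------------------------------------
# staged pipeline
# ---------------------------------------------------------------------------

class Pipeline:
    """Incremental pipeline state; stages can run individually or end to end."""

    def __init__(self, config: PipelineConfig):
        config.scenario.validate()
        self.config = config
        self.sst: xr.DataArray | None = None
        self.fields: xr.Dataset | None = None
        self.tracks: pd.DataFrame | None = None
        self.monthly: xr.DataArray | None = None
        self.clim: ClimatologySet | None = None
        self.k_composite: xr.DataArray | None = None
        self.s_composite: xr.DataArray | None = None
        self.records: pd.DataFrame | None = None
        self.table: pd.DataFrame | None = None
        self.excluded: pd.DataFrame | None = None
        self.qc_reclassified: int = 0
        self.retained_variables: list[str] | None = None
        self.collinearity = None
        self.cv: opt.CVResult | None = None
        self.search: opt.SearchResult | None = None
        self.maps: dict[str, xr.Dataset] = {}
        self.frequency: dict[str, xr.DataArray] = {}
        self.report: dict[str, Any] = {"seed": config.seed}

    # -- stage 0: synthetic world -------------------------------------------
    def stage_synth(self) -> "Pipeline":
        sc = self.config.scenario
        log.info("generating synthetic world (seed %d)", sc.seed)
        self.sst = syn.generate_sst(sc)
        self.fields = syn.generate_covariates(sc)
        self.tracks = syn.generate_typhoon_tracks(sc)
        return self

    # -- stage 1: climatologies ---------------------------------------------
    def stage_climatology(self) -> "Pipeline":
        assert self.sst is not None, "run stage_synth first"
        self.monthly = monthly_aggregate(self.sst)
        self.clim = build_climatology(self.monthly)
        return self

    # -- stage 2: covariate composites --------------------------------------
    def stage_covariates(self) -> "Pipeline":
        assert self.fields is not None
        self.k_composite = cov.seasonal_composite(self.fields["k490"])
        speed = cov.current_speed(
            self.fields["u_current"], self.fields["v_current"]
        )
        self.s_composite = speed  # static field; Jul–Sep composite of itself
        return self

    # -- stage 3: observations + design table -------------------------------
    def stage_observations(self) -> "Pipeline":
        assert self.clim is not None and self.sst is not None
        sc = self.config.scenario
        sites = syn.sample_observation_sites(sc)
        covtab, excluded = cov.extract_at_records(
            sites,
            self.sst,
            self.clim,
            self.config.index_spec,
            self.fields["uvb"],
            self.k_composite,
            self.s_composite,
        )
        self.excluded = excluded
        self.records = syn.generate_observations(sc, covtab)
        self.report["n_records"] = len(self.records)
        self.report["n_excluded"] = len(excluded)
        return self

    # -- stage 4: QC + collinearity (Steps 1–3) ------------------------------
    def stage_qc(self) -> "Pipeline":
        assert self.records is not None
        index_col = self.config.index_spec.column
        self.records, n = obs.qc_reclassify(
            self.records, self.records[index_col].to_numpy()
        )
        self.qc_reclassified = n
        self.report["n_reclassified"] = n
        variables = [index_col, "c", "u", "k", "d", "s", "v"]
        retained, colrep = cov.collinearity_screen(
            self.records, variables, priority=variables
        )
        # the index, DCW and UV-B stay regardless (always-included variables)
        for must in (index_col, "c", "u"):
            if must not in retained:
                retained.insert(0, must)
        self.retained_variables = retained
        self.collinearity = colrep
        self.report["collinearity_dropped"] = colrep.dropped
        self.table = self.records
        return self

    # -- stage 5: model evaluation (Step 4) -----------------------------------
    def stage_optimize(self) -> "Pipeline":
        assert self.table is not None and self.retained_variables is not None
        spec = ModelSpec(
            family=self.config.model_family,
            variables=tuple(self.retained_variables),
            index_spec=self.config.index_spec,
            rf_seed=self.config.seed,
        )
        self.cv = opt.repeated_split_cv(
            self.table,
            spec,
            repeats=self.config.cv_repeats,
            test_fraction=self.config.test_fraction,
            seed=self.config.seed,
        )
        self.report["cv_summary"] = self.cv.summary().to_dict()
        if spec.family == "glm" and self.cv.models:
            ratio, ok = overdispersion_check(self.cv.models[0])
            self.report["overdispersion"] = {"ratio": ratio, "pass": ok}
        if self.config.run_threshold_search:
            builder = self.make_table_builder()
            self.search = opt.filtering_threshold_search(
                builder,
                spec,
                mode=self.config.search_mode,
                repeats=self.config.cv_repeats,
                seed=self.config.seed,
            )
            self.report["best_filter_threshold"] = self.search.best_threshold
            self.report["search_mean_tss"] = self.search.best_mean_tss
        return self

    def make_table_builder(self) -> opt.TableBuilder:
        """Covariate-table builder recomputing the thermal index per filtering
        threshold (used by the search operations)."""
        assert self.records is not None

        base_spec = self.config.index_spec
        sc = self.config.scenario

        def build(threshold: float) -> pd.DataFrame:
            if base_spec.filter_mode == "constant_alpha":
                spec = idx.IndexSpec(
                    kind=base_spec.kind, baseline=base_spec.baseline,
                    filter_mode="constant_alpha", alpha=threshold,
                )
            else:
                spec = idx.IndexSpec(
                    kind=base_spec.kind, baseline=base_spec.baseline,
                    filter_mode="sigma_scaled_beta", beta=threshold,
                )
            covtab, _ = cov.extract_at_records(
                self.records,
                self.sst,
                self.clim,
                spec,
                self.fields["uvb"],
                self.k_composite,
                self.s_composite,
            )
            covtab["bleached"] = self.records["bleached"].to_numpy()
            return covtab

        return build

    # -- stage 6: prediction maps (Step 5) ------------------------------------
    def _covariate_grids(self, year: int) -> tuple[dict[str, xr.DataArray], int]:
        """Per-cell covariate layers for the warmest month of a year."""
        assert self.monthly is not None and self.clim is not None
        months = self.monthly.sel(time=str(year))
        domain_mean = months.mean(["lat", "lon"])
        warm_ix = int(domain_mean.argmax("time"))
        warm_month = int(months.indexes["time"][warm_ix].month)
        end = months.indexes["time"][warm_ix] + pd.offsets.MonthEnd(0)

        baseline = (
            self.clim.mmm
            if self.config.index_spec.baseline == "mmm"
            else self.clim.mmm_max
        )
        hs = idx.hotspots(self.sst.sel(time=slice(None, end)), baseline)
        threshold = self.config.index_spec.threshold(self.clim.sigma_m)
        if self.config.index_spec.kind == "dhm":
            hs_m = idx.hotspots(
                self.monthly.sel(time=slice(None, end)), baseline
            )
            index_layer = idx.dhm_cube(hs_m, threshold).isel(time=-1, drop=True)
        else:
            index_layer = idx.dhw_cube(hs, threshold).isel(time=-1, drop=True)
        dcw_layer = idx.dcw_cube(
            self.sst.sel(time=slice(None, end)), self.clim.mmm
        ).isel(time=-1, drop=True)
        uvb_layer = self.fields["uvb"].sel(time=f"{year}-{warm_month:02d}-01")
        grids = {
            self.config.index_spec.column: index_layer,
            "c": dcw_layer,
            "u": uvb_layer,
            "k": self.k_composite,
            "s": self.s_composite,
            "v": self.clim.sigma_m,
            "d": xr.full_like(self.clim.sigma_m, self.config.constant_depth_m),
        }
        return grids, warm_month

    def stage_predict(self) -> "Pipeline":
        assert self.cv is not None and self.cv.models, "run stage_optimize first"
        years = self.config.prediction_years or tuple(
            range(self.config.scenario.years[1] - 4, self.config.scenario.years[1] + 1)
        )
        baseline_binaries, screened_binaries = [], []
        for year in years:
            grids, warm_month = self._covariate_grids(year)
            base = pred.predict_grid(self.cv.models, grids)
            screened = pred.predict_grid(
                self.cv.models, pred.apply_scenario(grids, self.config.screening)
            )
            base.attrs["warm_month"] = warm_month
            screened.attrs["warm_month"] = warm_month
            self.maps[f"baseline_{year}"] = base
            self.maps[f"screened_{year}"] = screened
            baseline_binaries.append(base["binary"])
            screened_binaries.append(screened["binary"])
        self.frequency["baseline"] = pred.bleaching_frequency(baseline_binaries)
        self.frequency["screened"] = pred.bleaching_frequency(screened_binaries)
        self.report["mean_probability_baseline"] = float(
            np.mean([self.maps[f"baseline_{y}"]["probability"].mean() for y in years])
        )
        self.report["mean_probability_screened"] = float(
            np.mean([self.maps[f"screened_{y}"]["probability"].mean() for y in years])
        )
        self.report["prediction_years"] = list(years)
        return self

    # -- artifacts -------------------------------------------------------------
    def write_artifacts(self) -> dict:
        out = Path(self.config.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        artifacts: dict[str, str] = {}

        def emit(name: str, writer) -> None:
            path = out / name
            writer(path)
            artifacts[name] = _sha256(path)

        if self.sst is not None:
            emit("sst.nc", lambda p: write_grid(self.sst, p))
        if self.fields is not None:
            emit("covariate_fields.nc", lambda p: write_grid(self.fields, p))
        if self.tracks is not None:
            emit("typhoon_tracks.csv", lambda p: self.tracks.to_csv(p, index=False))
        if self.clim is not None:
            emit("climatology.nc", lambda p: write_grid(self.clim.to_dataset(), p))
        if self.records is not None:
            emit("records.csv", lambda p: self.records.to_csv(p, index=False))
        if self.cv is not None:
            emit(
                "cv_metrics.csv", lambda p: self.cv.per_repeat.to_csv(p, index=False)
            )
        if self.search is not None:
            emit(
                "search_trace.csv", lambda p: self.search.trace.to_csv(p, index=False)
            )
        for name, ds in self.maps.items():
            emit(f"map_{name}.nc", lambda p, ds=ds: write_grid(ds, p))
        for name, da in self.frequency.items():
            emit(f"frequency_{name}.nc", lambda p, da=da: write_grid(da, p))

        manifest = {
            "seed": self.config.seed,
            "config": self.config.resolved(),
            "report": self.report,
            "artifacts": artifacts,
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
        return manifest

    def run_all(self) -> dict:
        stages = [
            ("synth", self.stage_synth),
            ("climatology", self.stage_climatology),
            ("covariates", self.stage_covariates),
            ("observations", self.stage_observations),
            ("qc", self.stage_qc),
            ("optimize", self.stage_optimize),
            ("predict", self.stage_predict),
        ]
        completed = []
        try:
            for name, fn in stages:
                log.info("stage: %s", name)
                fn()
                completed.append(name)
        except Exception as err:
            self.report["failed_stage"] = name
            self.report["error"] = str(err)
            self.report["completed_stages"] = completed
            manifest = self.write_artifacts()
            raise
        self.report["completed_stages"] = completed
        return self.write_artifacts()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full pipeline and return the run manifest."""
    return Pipeline(config).run_all()
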