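"""Bleaching prediction models: binomial-logit GLM and random-forest
regression on the 0/1 response.

The GLM is an ordinary maximum-likelihood binomial-logit fit; its fitted
probability is logistic(intercept + Σ slope·x) and the model can be written
out as a formula.  The random forest follows the regression-on-binary
convention — regression trees on the 0/1 response so the ensemble mean is a
probability in [0, 1] — with 500 trees and p/3 candidate predictors per
split.  Variable importance: Akaike-weight sums over the all-subsets GLM
model set, and permutation importance for the forest; both rescaled so the
top variable reads 100%.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.ensemble import RandomForestRegressor
from sklearn.inspection import permutation_importance

from .indices import IndexSpec

__all__ = [
    "ModelSpec",
    "FittedModel",
    "logistic",
    "fit_glm",
    "fit_rf",
    "fit_model",
    "predict_probability",
    "variable_importance",
    "overdispersion_check",
]

RF_TREES = 500
OVERDISPERSION_LIMIT = 1.5


def logistic(x):
    """Inverse logit, 1 / (1 + exp(−x))."""
    return 1.0 / (1.0 + np.exp(-np.asarray(x, dtype=float)))


@dataclass(frozen=True)
class ModelSpec:
    """Which model family to fit and on which covariate columns."""

    family: str = "glm"  # "glm" | "rf"
    variables: tuple[str, ...] = ("dhw",)
    index_spec: IndexSpec | None = None
    rf_trees: int = RF_TREES
    rf_seed: int = 0

    def __post_init__(self) -> None:
        if self.family not in ("glm", "rf"):
            raise ValueError(f"unknown model family {self.family!r}")
        if not self.variables:
            raise ValueError("a model needs at least one variable")


@dataclass
class FittedModel:
    spec: ModelSpec
    coefficients: pd.Series | None = None  # GLM: intercept first
    forest: RandomForestRegressor | None = None
    residual_deviance_per_df: float | None = None
    evaluation_threshold: float | None = None
    n_train: int = 0
    converged: bool = True
    separation: bool = False

    def formula(self) -> str:
        """Plain-text logistic formula, e.g. logistic(-2.56 + 0.891*dhw)."""
        if self.coefficients is None:
            return f"random forest ({self.spec.rf_trees} trees)"
        terms = [f"{self.coefficients.iloc[0]:.3g}"]
        for name, b in self.coefficients.iloc[1:].items():
            terms.append(f"{'+' if b >= 0 else '-'} {abs(b):.3g}*{name}")
        return "logistic(" + " ".join(terms) + ")"


def _design(table: pd.DataFrame, variables: Sequence[str]) -> pd.DataFrame:
    missing = [v for v in variables if v not in table.columns]
    if missing:
        raise ValueError(f"covariate table lacks columns {missing}")
    X = table[list(variables)].astype(float)
    if X.isna().any().any():
        raise ValueError("missing covariate values in the design matrix")
    return sm.add_constant(X, has_constant="add")


def fit_glm(table: pd.DataFrame, spec: ModelSpec) -> FittedModel:
    """Maximum-likelihood binomial-logit fit."""
    y = table["bleached"].to_numpy(dtype=float)
    X = _design(table, spec.variables)
    if len(table) < 10 * X.shape[1]:
        raise ValueError(
            f"{len(table)} rows is too few for {X.shape[1]} parameters "
            "(need >= 10 per parameter)"
        )
    model = sm.GLM(y, X, family=sm.families.Binomial())
    separation = False
    converged = True
    with np.errstate(all="ignore"):
        try:
            res = model.fit(maxiter=100)
            converged = bool(res.converged)
        except Exception:  # perfect separation raises in some statsmodels paths
            res = model.fit_regularized(alpha=1e-8, maxiter=200)
            separation = True
            converged = False
    params = pd.Series(np.asarray(res.params), index=X.columns)
    fitted = logistic(X.to_numpy() @ params.to_numpy())
    if np.any(fitted > 1 - 1e-10) or np.any(fitted < 1e-10):
        separation = True
    df_resid = max(len(y) - X.shape[1], 1)
    try:
        deviance = float(res.deviance)
    except AttributeError:
        eps = 1e-12
        deviance = float(
            -2
            * np.sum(
                y * np.log(np.clip(fitted, eps, 1))
                + (1 - y) * np.log(np.clip(1 - fitted, eps, 1))
            )
        )
    return FittedModel(
        spec=spec,
        coefficients=params,
        residual_deviance_per_df=deviance / df_resid,
        n_train=len(y),
        converged=converged,
        separation=separation,
    )


def fit_rf(table: pd.DataFrame, spec: ModelSpec) -> FittedModel:
    """Random-forest regression on the 0/1 response (ensemble mean = probability)."""
    y = table["bleached"].to_numpy(dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("response is single-class; nothing to model")
    X = table[list(spec.variables)].astype(float)
    if X.isna().any().any():
        raise ValueError("missing covariate values in the design matrix")
    forest = RandomForestRegressor(
        n_estimators=spec.rf_trees,
        max_features=max(1, len(spec.variables) // 3),
        random_state=spec.rf_seed,
        n_jobs=1,
    )
    forest.fit(X.to_numpy(), y)
    return FittedModel(spec=spec, forest=forest, n_train=len(y))


def fit_model(table: pd.DataFrame, spec: ModelSpec) -> FittedModel:
    return fit_glm(table, spec) if spec.family == "glm" else fit_rf(table, spec)


def predict_probability(model: FittedModel, table: pd.DataFrame) -> np.ndarray:
    """Per-row bleaching probability in [0, 1]."""
    variables = model.spec.variables
    missing = [v for v in variables if v not in table.columns]
    if missing:
        raise ValueError(f"prediction table lacks columns {missing}")
    X = table[list(variables)].astype(float).to_numpy()
    if model.coefficients is not None:
        eta = model.coefficients.iloc[0] + X @ model.coefficients.iloc[1:].to_numpy()
        return logistic(eta)
    if model.forest is None:
        raise ValueError("model carries neither coefficients nor a forest")
    return np.clip(model.forest.predict(X), 0.0, 1.0)


def variable_importance(
    table: pd.DataFrame,
    variables: Sequence[str],
    family: str = "glm",
    seed: int = 0,
    n_repeats: int = 10,
) -> pd.Series:
    """Relative importance per variable, top variable scaled to 100%.

    GLM: each variable's importance is the sum of Akaike weights of the
    all-subsets models containing it.  RF: permutation importance of a
    single full-model forest.
    """
    variables = list(variables)
    if len(variables) < 2:
        raise ValueError("importance needs at least two candidate variables")
    y = table["bleached"].to_numpy(dtype=float)
    if family == "glm":
        aics, members = [], []
        for r in range(len(variables) + 1):
            for subset in itertools.combinations(variables, r):
                X = sm.add_constant(
                    table[list(subset)].astype(float), has_constant="add"
                )
                res = sm.GLM(y, X, family=sm.families.Binomial()).fit(maxiter=100)
                aics.append(res.aic)
                members.append(set(subset))
        aics = np.asarray(aics)
        rel = np.exp(-0.5 * (aics - aics.min()))
        weights = rel / rel.sum()
        imp = pd.Series(
            {v: weights[[v in m for m in members]].sum() for v in variables}
        )
    elif family == "rf":
        spec = ModelSpec(family="rf", variables=tuple(variables), rf_seed=seed)
        model = fit_rf(table, spec)
        X = table[variables].astype(float).to_numpy()
        result = permutation_importance(
            model.forest, X, y, n_repeats=n_repeats, random_state=seed, n_jobs=1
        )
        imp = pd.Series(np.maximum(result.importances_mean, 0.0), index=variables)
    else:
        raise ValueError(f"unknown family {family!r}")
    top = imp.max()
    if top <= 0:
        return imp * 0.0
    return 100.0 * imp / top


def overdispersion_check(model: FittedModel) -> tuple[float, bool]:
    """Residual deviance per degree of freedom; pass iff < 1.5."""
    if model.spec.family != "glm" or model.residual_deviance_per_df is None:
        raise ValueError("overdispersion check applies to fitted GLMs only")
    ratio = model.residual_deviance_per_df
    return ratio, bool(ratio < OVERDISPERSION_LIMIT)
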