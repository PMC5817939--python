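"""Model evaluation and threshold/variable optimization.

Metrics follow the presence/absence convention: ACC, TPR (sensitivity),
TNR (specificity) and the true skill statistic TSS = TPR + TNR − 1, which
is insensitive to class prevalence.  The probability cutoff ("evaluation
threshold") converting model output into bleaching calls is chosen by
TPR–TNR sum maximization over the unique predicted probabilities.

Model skill is estimated by repeated random 70/30 train/test splits
(10 repeats by default).  Two nested searches run on top of that engine:

* filtering-threshold search — the DHW/DHM filtering threshold alpha (grid
  0.00–1.50, 151 values) or its variability-scaled coefficient beta (grid
  0.10–2.50, 241 values) is scanned at 0.01 precision, rebuilding the
  thermal index from cached HotSpot series for each candidate;
* variable-combination search — DCW and UV-B are always kept and the 15
  non-empty subsets of the remaining four covariates are compared,
  optionally jointly with the threshold grid.

Selection is by the highest mean test TSS.  Splits are shared across
candidates (paired comparisons), so candidate differences are not masked
by split noise.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .models import FittedModel, ModelSpec, fit_model, predict_probability

__all__ = [
    "ConfusionCounts",
    "EvaluationMetrics",
    "CVResult",
    "SearchResult",
    "evaluate_at_threshold",
    "optimize_evaluation_threshold",
    "repeated_split_cv",
    "alpha_grid",
    "beta_grid",
    "filtering_threshold_search",
    "variable_combination_search",
]

CV_REPEATS = 10
TEST_FRACTION = 0.3
CORE_VARIABLES = ("c", "u")
OPTIONAL_VARIABLES = ("v", "k", "d", "s")


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class EvaluationMetrics:
    acc: float
    tpr: float
    tnr: float
    tss: float
    threshold: float


def evaluate_at_threshold(
    probabilities: np.ndarray, labels: np.ndarray, threshold: float
) -> tuple[ConfusionCounts, EvaluationMetrics]:
    """Confusion counts and metrics; predicted positive iff p >= threshold."""
    p = np.asarray(probabilities, dtype=float)
    y = np.asarray(labels)
    if not np.isin(y, [0, 1]).all():
        raise ValueError("labels must be binary 0/1")
    if y.min() == y.max():
        raise ValueError("single-class labels: TPR or TNR undefined")
    pred = p >= threshold
    pos, neg = y == 1, y == 0
    counts = ConfusionCounts(
        tp=int((pred & pos).sum()),
        fp=int((pred & neg).sum()),
        tn=int((~pred & neg).sum()),
        fn=int((~pred & pos).sum()),
    )
    tpr = counts.tp / (counts.tp + counts.fn)
    tnr = counts.tn / (counts.tn + counts.fp)
    metrics = EvaluationMetrics(
        acc=(counts.tp + counts.tn) / counts.total,
        tpr=tpr,
        tnr=tnr,
        tss=tpr + tnr - 1.0,
        threshold=float(threshold),
    )
    return counts, metrics


def optimize_evaluation_threshold(
    probabilities: np.ndarray, labels: np.ndarray
) -> EvaluationMetrics:
    """TPR–TNR sum maximization over the unique predicted probabilities.

    Ties are broken toward the smallest candidate threshold (the most
    sensitive rule among the maximizers).
    """
    p = np.asarray(probabilities, dtype=float)
    y = np.asarray(labels)
    if y.min() == y.max():
        raise ValueError("single-class labels: threshold optimization undefined")
    order = np.argsort(p, kind="mergesort")
    ps, ys = p[order], y[order]
    cum_pos = np.cumsum(ys == 1)
    cum_neg = np.cumsum(ys == 0)
    total_pos, total_neg = cum_pos[-1], cum_neg[-1]
    candidates = np.unique(ps)
    first = np.searchsorted(ps, candidates, side="left")
    pos_below = np.where(first > 0, cum_pos[np.maximum(first - 1, 0)], 0)
    neg_below = np.where(first > 0, cum_neg[np.maximum(first - 1, 0)], 0)
    tpr = (total_pos - pos_below) / total_pos
    tnr = neg_below / total_neg
    tss = tpr + tnr - 1.0
    # smallest candidate among the maximizers (ties at float-noise level)
    best_ix = int(np.flatnonzero(tss >= tss.max() - 1e-10)[0])
    t = float(candidates[best_ix])
    _, metrics = evaluate_at_threshold(p, y, t)
    return metrics


# ---------------------------------------------------------------------------
# repeated 70/30 cross-validation
# ---------------------------------------------------------------------------

@dataclass
class CVResult:
    per_repeat: pd.DataFrame  # repeat, threshold, acc, tpr, tnr, tss, n_test
    models: list[FittedModel] = field(default_factory=list)

    @property
    def mean_tss(self) -> float:
        return float(self.per_repeat["tss"].mean())

    def summary(self) -> pd.Series:
        r = self.per_repeat
        n = len(r)
        out = {}
        for col in ("threshold", "acc", "tpr", "tnr", "tss"):
            out[f"{col}_mean"] = float(r[col].mean())
            out[f"{col}_se"] = float(r[col].std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0
        out["repeats"] = n
        return pd.Series(out)


FitFunction = Callable[[pd.DataFrame, ModelSpec], FittedModel]


def _split_indices(
    n: int,
    labels: np.ndarray,
    rng: np.random.Generator,
    test_fraction: float,
    max_tries: int = 100,
) -> tuple[np.ndarray, np.ndarray]:
    n_test = int(np.floor(test_fraction * n))
    for _ in range(max_tries):
        perm = rng.permutation(n)
        test, train = perm[:n_test], perm[n_test:]
        if labels[test].min() != labels[test].max() and (
            labels[train].min() != labels[train].max()
        ):
            return train, test
    raise ValueError(
        "could not draw a split with both classes in train and test; "
        "the response is too unbalanced for this table size"
    )


def repeated_split_cv(
    table: pd.DataFrame,
    spec: ModelSpec,
    repeats: int = CV_REPEATS,
    test_fraction: float = TEST_FRACTION,
    seed: int = 0,
    fit_fn: FitFunction | None = None,
    threshold_on: str = "train",
    keep_models: bool = True,
) -> CVResult:
    """Repeated random 70/30 splits: fit, optimize the evaluation threshold,
    score on the held-out 30%.

    The evaluation threshold is optimized on the training predictions and
    applied unchanged to the test set (``threshold_on="test"`` restores
    in-sample threshold optimization for comparison).  Split draws depend
    only on ``seed``, ``repeats`` and the table length, so two searches over
    the same table share identical splits.
    """
    if threshold_on not in ("train", "test"):
        raise ValueError("threshold_on must be 'train' or 'test'")
    fit = fit_fn or fit_model
    labels = table["bleached"].to_numpy()
    rng = np.random.default_rng(seed)
    rows, fitted_models = [], []
    for rep in range(repeats):
        train_ix, test_ix = _split_indices(len(table), labels, rng, test_fraction)
        train, test = table.iloc[train_ix], table.iloc[test_ix]
        model = fit(train, spec)
        p_train = predict_probability(model, train)
        p_test = predict_probability(model, test)
        if threshold_on == "train":
            thr = optimize_evaluation_threshold(
                p_train, train["bleached"].to_numpy()
            ).threshold
        else:
            thr = optimize_evaluation_threshold(
                p_test, test["bleached"].to_numpy()
            ).threshold
        _, m = evaluate_at_threshold(p_test, test["bleached"].to_numpy(), thr)
        model.evaluation_threshold = thr
        rows.append(
            {
                "repeat": rep,
                "threshold": thr,
                "acc": m.acc,
                "tpr": m.tpr,
                "tnr": m.tnr,
                "tss": m.tss,
                "n_test": len(test),
            }
        )
        if keep_models:
            fitted_models.append(model)
    return CVResult(per_repeat=pd.DataFrame(rows), models=fitted_models)


# ---------------------------------------------------------------------------
# threshold and variable searches
# ---------------------------------------------------------------------------

def alpha_grid() -> np.ndarray:
    """Constant filtering thresholds 0.00–1.50 °C at 0.01 precision (151)."""
    return np.arange(0, 151) / 100.0


def beta_grid() -> np.ndarray:
    """Sigma-scaling coefficients 0.10–2.50 at 0.01 precision (241)."""
    return np.arange(10, 251) / 100.0


@dataclass
class SearchResult:
    best_threshold: float | None
    best_combination: tuple[str, ...] | None
    best_mean_tss: float
    summary: pd.Series  # mean ± SE of thresholds/metrics for the winner
    trace: pd.DataFrame  # one row per repeat × candidate (× combination)
    best_cv: CVResult


TableBuilder = Callable[[float], pd.DataFrame]


def _spec_with_variables(spec: ModelSpec, variables: Sequence[str]) -> ModelSpec:
    return ModelSpec(
        family=spec.family,
        variables=tuple(variables),
        index_spec=spec.index_spec,
        rf_trees=spec.rf_trees,
        rf_seed=spec.rf_seed,
    )


def filtering_threshold_search(
    table_builder: TableBuilder,
    spec: ModelSpec,
    mode: str = "alpha",
    repeats: int = CV_REPEATS,
    seed: int = 0,
    fit_fn: FitFunction | None = None,
    grid: np.ndarray | None = None,
) -> SearchResult:
    """Scan the filtering-threshold grid, rerunning the repeated CV per
    candidate, and return the candidate with the highest mean test TSS.

    ``table_builder(threshold)`` must rebuild the covariate table with the
    thermal index recomputed at that filtering threshold (from cached
    HotSpot series).  All candidates share the same split seed.
    """
    if grid is None:
        if mode == "alpha":
            grid = alpha_grid()
        elif mode == "beta":
            grid = beta_grid()
        else:
            raise ValueError("mode must be 'alpha' or 'beta'")
    if len(grid) == 0:
        raise ValueError("empty threshold grid")
    traces = []
    best: tuple[float, float, CVResult] | None = None  # (tss, thr, cv)
    for thr in grid:
        table = table_builder(float(thr))
        cv = repeated_split_cv(
            table, spec, repeats=repeats, seed=seed, fit_fn=fit_fn,
            keep_models=False,
        )
        t = cv.per_repeat.copy()
        t.insert(0, "filter_threshold", float(thr))
        traces.append(t)
        if best is None or cv.mean_tss > best[0] + 1e-12:
            best = (cv.mean_tss, float(thr), cv)
    assert best is not None
    # refit winner keeping models for downstream prediction
    win_cv = repeated_split_cv(
        table_builder(best[1]), spec, repeats=repeats, seed=seed, fit_fn=fit_fn
    )
    return SearchResult(
        best_threshold=best[1],
        best_combination=tuple(spec.variables),
        best_mean_tss=best[0],
        summary=win_cv.summary(),
        trace=pd.concat(traces, ignore_index=True),
        best_cv=win_cv,
    )


def optional_variable_combinations(
    optional: Sequence[str] = OPTIONAL_VARIABLES,
    include_empty: bool = False,
) -> list[tuple[str, ...]]:
    """The non-empty subsets of the optional covariates (15 for four)."""
    subsets = [
        combo
        for r in range(0 if include_empty else 1, len(optional) + 1)
        for combo in itertools.combinations(optional, r)
    ]
    return subsets


def variable_combination_search(
    table: pd.DataFrame | None,
    spec: ModelSpec,
    index_variable: str = "dhw",
    core: Sequence[str] = CORE_VARIABLES,
    optional: Sequence[str] = OPTIONAL_VARIABLES,
    repeats: int = CV_REPEATS,
    seed: int = 0,
    fit_fn: FitFunction | None = None,
    table_builder: TableBuilder | None = None,
    mode: str | None = None,
    grid: np.ndarray | None = None,
    log_empty_subset: bool = True,
) -> SearchResult:
    """Search the 15 optional-variable subsets (index + DCW + UV-B always in),
    optionally jointly with the filtering-threshold grid.

    With ``table_builder`` and ``mode`` given, the full factorial
    repeats × combinations × grid is evaluated (the paired splits make
    combination contrasts low-variance); otherwise the single fixed
    ``table`` is used.  The empty subset is additionally evaluated and
    logged (``in_search=False``) but never selected.
    """
    combos = optional_variable_combinations(optional)
    if log_empty_subset:
        all_combos = [()] + combos
    else:
        all_combos = list(combos)

    if table_builder is not None:
        if mode is None and grid is None:
            raise ValueError("joint search needs a mode or an explicit grid")
        if grid is None:
            grid = alpha_grid() if mode == "alpha" else beta_grid()
        thresholds = [float(t) for t in grid]
        tables = None
    else:
        if table is None:
            raise ValueError("either a table or a table_builder is required")
        thresholds = [None]
        tables = table

    first_table = tables if tables is not None else table_builder(thresholds[0])
    missing = [
        v
        for v in [index_variable, *core, *optional]
        if v not in first_table.columns
    ]
    if missing:
        raise ValueError(f"covariate table lacks columns {missing}")

    traces = []
    best: tuple[float, float | None, tuple[str, ...], CVResult] | None = None
    for thr in thresholds:
        tab = tables if thr is None else table_builder(thr)
        for combo in all_combos:
            variables = (index_variable, *core, *combo)
            cv = repeated_split_cv(
                tab,
                _spec_with_variables(spec, variables),
                repeats=repeats,
                seed=seed,
                fit_fn=fit_fn,
                keep_models=False,
            )
            t = cv.per_repeat.copy()
            t.insert(0, "combination", "+".join(combo) if combo else "(core only)")
            t.insert(0, "filter_threshold", np.nan if thr is None else thr)
            t.insert(0, "in_search", bool(combo))
            traces.append(t)
            if combo and (best is None or cv.mean_tss > best[0] + 1e-12):
                best = (cv.mean_tss, thr, combo, cv)
    assert best is not None
    best_tss, best_thr, best_combo, _ = best
    win_variables = (index_variable, *core, *best_combo)
    win_tab = tables if best_thr is None else table_builder(best_thr)
    win_cv = repeated_split_cv(
        win_tab,
        _spec_with_variables(spec, win_variables),
        repeats=repeats,
        seed=seed,
        fit_fn=fit_fn,
    )
    return SearchResult(
        best_threshold=best_thr,
        best_combination=best_combo,
        best_mean_tss=best_tss,
        summary=win_cv.summary(),
        trace=pd.concat(traces, ignore_index=True),
        best_cv=win_cv,
    )
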