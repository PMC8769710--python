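"""Nested cross-validation benchmark of filter methods with ridge Cox.

Each filter has a single hyperparameter *prop*, the proportion of features
retained.  It is tuned on an inner event-stratified CV over the squared
grid {0.01^2, ..., 1}: features are ranked on the inner training part, a
ridge Cox model is fitted on the top prop*100% features, and the grid
value minimizing the mean inner-validation IBS wins (ties go to the
smallest prop).  The outer loop then ranks/selects on the outer training
part, fits ridge Cox (penalty by its own inner CV), and records the
validation IBS, the wall-clock runtime of filtering + fitting + predicting
and the selected set.  Two baselines run alongside: ridge Cox on all
features (no prop to tune) and the feature-free Kaplan-Meier curve.

The same fold assignments are consumed by every filter within a run, and
per-(purpose, filter, fold) child seeds keep filters independent: removing
one filter from the config changes no other filter's records.
"""

from __future__ import annotations

import time as _time
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import SurvivalDataset, kaplan_meier, stratified_folds
from .filters.base import FeatureRanking, rank_features
from .filters.importance import (
    BoostingConfig,
    RSFConfig,
    boosting_importance,
    fit_cox_gradient_boosting,
    fit_random_survival_forest,
    rsf_impurity_importance,
    rsf_permutation_importance,
)
from .filters.mi import GREEDY_MI_METHODS, mi_feature_ranking
from .filters.univariate import (
    carss_filter,
    correlation_filter,
    cox_score_filter,
    variance_filter,
)
from .models import (
    fit_ridge_cox,
    integrated_brier_score,
    km_predictor,
    predict_survival,
    select_lambda_cv,
)

__all__ = [
    "FILTER_NAMES",
    "BenchmarkConfig",
    "BenchmarkRecord",
    "prop_grid",
    "n_select",
    "rank_with_filter",
    "tune_prop",
    "run_nested_cv",
    "records_to_frame",
    "pairwise_wins",
    "relative_scores",
    "selected_proportions",
]

FILTER_NAMES = (
    "variance",
    "correlation",
    "cox.score",
    "carss",
    "permutation",
    "impurity",
    "boosting",
    "mim",
    "mrmr",
    "jmi",
    "jmim",
    "disr",
    "njmim",
    "cmim",
)
BASELINES = ("no_filter", "kaplan_meier")


def child_seed(master: int, *keys) -> int:
    """Deterministic sub-seed from a master seed and hashable keys."""
    h = zlib.crc32("|".join(map(str, keys)).encode())
    return int(np.random.SeedSequence((master, h)).generate_state(1)[0] % (2**31))


def prop_grid() -> np.ndarray:
    """The 100 proportions {0.01, ..., 1} squared: denser near zero."""
    return (np.arange(1, 101) / 100.0) ** 2


def n_select(prop: float, p: int) -> int:
    """Number of selected features: max(1, round(prop * p)), half rounds up."""
    if not 0 < prop <= 1:
        raise ValueError("prop must lie in (0, 1]")
    return max(1, int(np.floor(prop * p + 0.5)))


def rank_with_filter(
    dataset: SurvivalDataset, name: str, k_max: int | None = None, seed: int = 0, params=None
) -> FeatureRanking:
    """Full feature ranking of one filter method.

    ``k_max`` bounds the greedy selection depth of the iterative MI
    filters; ``params`` passes filter-specific settings (forest/boosting
    configs).
    """
    params = dict(params or {})
    if name == "variance":
        return rank_features(variance_filter(dataset))
    if name == "correlation":
        return rank_features(correlation_filter(dataset))
    if name == "cox.score":
        return rank_features(cox_score_filter(dataset))
    if name == "carss":
        return rank_features(carss_filter(dataset, **params))
    if name in ("mim",) + GREEDY_MI_METHODS:
        return mi_feature_ranking(dataset, name, k=k_max if name != "mim" else None)
    if name in ("permutation", "impurity"):
        forest = fit_random_survival_forest(
            dataset, RSFConfig(**{"seed": seed, **params})
        )
        if name == "impurity":
            return rank_features(rsf_impurity_importance(forest))
        return rank_features(
            rsf_permutation_importance(forest, dataset, seed=child_seed(seed, "perm"))
        )
    if name == "boosting":
        model = fit_cox_gradient_boosting(
            dataset, BoostingConfig(**{"seed": seed, **params})
        )
        return rank_features(boosting_importance(model))
    raise ValueError(f"unknown filter '{name}'")


@dataclass(frozen=True)
class BenchmarkConfig:
    """Benchmark design: folds, prop grid, filters and seeding.

    ``lambda_folds`` / ``lambda_grid_size`` control the ridge penalty
    search inside every fit; reduced-scale runs set them explicitly.
    """

    outer_folds: int = 10
    inner_folds: int = 10
    grid: tuple = field(default_factory=lambda: tuple(prop_grid()))
    filters: tuple = FILTER_NAMES
    seed: int = 0
    include_baselines: bool = True
    lambda_folds: int = 10
    lambda_grid_size: int = 100
    filter_params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.outer_folds < 2 or self.inner_folds < 2:
            raise ValueError("fold counts must be at least 2")
        if any(not 0 < g <= 1 for g in self.grid):
            raise ValueError("grid values must lie in (0, 1]")


@dataclass
class BenchmarkRecord:
    """One outer-fold result for one method."""

    dataset_id: str
    filter_name: str
    outer_fold: int
    chosen_prop: float | None
    selected: tuple
    ibs: float | None
    runtime: float | None
    inner_selected_sets: tuple = ()
    fold_fingerprint: int = 0
    error: str | None = None


def _fit_and_ibs(train: SurvivalDataset, test: SurvivalDataset, config: BenchmarkConfig, seed: int):
    lam = select_lambda_cv(
        train.features,
        train.time,
        train.event,
        n_folds=config.lambda_folds,
        seed=seed,
        n_lambda=config.lambda_grid_size,
    )
    model = fit_ridge_cox(
        train.features, train.time, train.event, lam, feature_names=train.feature_names
    )
    pred = predict_survival(model, test.features, feature_names=test.feature_names)
    G_hat = kaplan_meier(train.time, 1 - train.event)
    return integrated_brier_score(pred, test.time, test.event, G_hat)


def tune_prop(
    filter_name: str,
    train: SurvivalDataset,
    inner_assignment,
    config: BenchmarkConfig,
    seed: int,
):
    """Choose the best prop by mean inner-validation IBS.

    Returns (chosen prop, per-inner-fold selected sets at that prop) --
    the latter feed the stability analysis.
    """
    grid = np.asarray(config.grid, dtype=float)
    if grid.size == 1:
        prop = float(grid[0])
    k_max = max(n_select(g, train.p) for g in grid)
    mean_ibs = np.zeros(grid.size)
    fold_rankings = []
    for fi, (tr_idx, te_idx) in enumerate(inner_assignment.splits()):
        inner_train, inner_test = train.subset(tr_idx), train.subset(te_idx)
        ranking = rank_with_filter(
            inner_train,
            filter_name,
            k_max=k_max,
            seed=child_seed(seed, "rank", filter_name, fi),
            params=config.filter_params.get(filter_name),
        )
        fold_rankings.append(ranking)
        if grid.size == 1:
            continue
        for gi, prop_value in enumerate(grid):
            names = ranking.top(n_select(prop_value, train.p))
            mean_ibs[gi] += _fit_and_ibs(
                inner_train.select_features(names),
                inner_test.select_features(names),
                config,
                seed=child_seed(seed, "lambda", filter_name, fi, gi),
            )
    if grid.size > 1:
        mean_ibs /= inner_assignment.k
        best = np.flatnonzero(mean_ibs == mean_ibs.min())
        prop = float(np.sort(grid[best])[0])  # ties: smallest prop
    selected_sets = tuple(
        tuple(rk.top(n_select(prop, train.p))) for rk in fold_rankings
    )
    return prop, selected_sets


def run_nested_cv(
    dataset: SurvivalDataset, config: BenchmarkConfig, dataset_id: str = "dataset"
) -> list:
    """Full nested-CV benchmark on one data set.

    A failing method never aborts the others: its record carries the error
    message with missing performance values.
    """
    outer = stratified_folds(dataset, config.outer_folds, child_seed(config.seed, "outer"))
    records = []
    for oi, (tr_idx, val_idx) in enumerate(outer.splits()):
        train, val = dataset.subset(tr_idx), dataset.subset(val_idx)
        fingerprint = int(zlib.crc32(np.sort(val_idx).astype(np.int64).tobytes()))
        inner = stratified_folds(train, config.inner_folds, child_seed(config.seed, "inner", oi))
        methods = tuple(config.filters) + (BASELINES if config.include_baselines else ())
        for name in methods:
            rec = BenchmarkRecord(dataset_id, name, oi, None, (), None, None, (), fingerprint)
            try:
                if name == "kaplan_meier":
                    t0 = _time.perf_counter()
                    pred = km_predictor(train.time, train.event, n_obs=val.n)
                    rec.runtime = _time.perf_counter() - t0
                    G_hat = kaplan_meier(train.time, 1 - train.event)
                    rec.ibs = integrated_brier_score(pred, val.time, val.event, G_hat)
                elif name == "no_filter":
                    t0 = _time.perf_counter()
                    rec.ibs = _fit_and_ibs(
                        train, val, config, seed=child_seed(config.seed, "nf", oi)
                    )
                    rec.runtime = _time.perf_counter() - t0
                    rec.selected = train.feature_names
                else:
                    prop, inner_sets = tune_prop(
                        name, train, inner, config, seed=child_seed(config.seed, name, oi)
                    )
                    rec.chosen_prop = prop
                    rec.inner_selected_sets = inner_sets
                    t0 = _time.perf_counter()
                    ranking = rank_with_filter(
                        train,
                        name,
                        k_max=n_select(prop, train.p),
                        seed=child_seed(config.seed, "rank", name, oi),
                        params=config.filter_params.get(name),
                    )
                    names = ranking.top(n_select(prop, train.p))
                    rec.selected = tuple(names)
                    rec.ibs = _fit_and_ibs(
                        train.select_features(names),
                        val.select_features(names),
                        config,
                        seed=child_seed(config.seed, "outerlam", name, oi),
                    )
                    rec.runtime = _time.perf_counter() - t0
            except Exception as exc:  # noqa: BLE001 - per-record isolation
                rec.error = f"{type(exc).__name__}: {exc}"
            records.append(rec)
    return records


def records_to_frame(records) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "dataset": r.dataset_id,
            "filter": r.filter_name,
            "outer_fold": r.outer_fold,
            "prop": r.chosen_prop,
            "n_selected": len(r.selected),
            "ibs": r.ibs,
            "runtime": r.runtime,
            "error": r.error,
        }
        for r in records
    )


def pairwise_wins(mean_scores: dict) -> pd.DataFrame:
    """Wins matrix: entry (A, B) counts data sets where A's mean IBS is
    lower than B's; rows ordered by descending row sums."""
    filters = sorted({f for f, _ in mean_scores})
    datasets = sorted({d for _, d in mean_scores})
    for f in filters:
        for d in datasets:
            if (f, d) not in mean_scores:
                raise ValueError(f"missing mean score for ({f}, {d})")
    W = np.zeros((len(filters), len(filters)), dtype=int)
    for i, a in enumerate(filters):
        for j, b in enumerate(filters):
            if i != j:
                W[i, j] = sum(
                    mean_scores[(a, d)] < mean_scores[(b, d)] for d in datasets
                )
    order = np.argsort(-W.sum(axis=1), kind="stable")
    labels = [filters[i] for i in order]
    return pd.DataFrame(W[np.ix_(order, order)], index=labels, columns=labels)


def relative_scores(records) -> pd.DataFrame:
    """Per-filter spread of relative mean IBS and relative log10 median
    runtime across data sets.

    Per data set, the best filter's mean IBS is subtracted from every
    filter's mean IBS, and the fastest filter's log10 median runtime from
    every filter's; each filter then reports min/median/max across data
    sets of both relative criteria.
    """
    df = records_to_frame(records).dropna(subset=["ibs"])
    agg = df.groupby(["dataset", "filter"]).agg(
        mean_ibs=("ibs", "mean"), median_runtime=("runtime", "median")
    )
    agg["rel_ibs"] = agg["mean_ibs"] - agg.groupby("dataset")["mean_ibs"].transform("min")
    agg["log_rt"] = np.log10(agg["median_runtime"].clip(lower=1e-12))
    agg["rel_log_runtime"] = agg["log_rt"] - agg.groupby("dataset")["log_rt"].transform("min")
    out = agg.groupby("filter").agg(
        rel_ibs_min=("rel_ibs", "min"),
        rel_ibs_median=("rel_ibs", "median"),
        rel_ibs_max=("rel_ibs", "max"),
        rel_log_runtime_min=("rel_log_runtime", "min"),
        rel_log_runtime_median=("rel_log_runtime", "median"),
        rel_log_runtime_max=("rel_log_runtime", "max"),
    )
    return out


def selected_proportions(records) -> pd.DataFrame:
    """Summary of tuned prop values and selected-set sizes per filter."""
    df = records_to_frame(records).dropna(subset=["prop"])
    return df.groupby("filter").agg(
        prop_median=("prop", "median"),
        prop_mean=("prop", "mean"),
        n_selected_median=("n_selected", "median"),
    )
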