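"""Mutual-information filters on equal-width categorized survival data.

The censored outcome is first turned into martingale residuals, then both
residuals and features are cut into ``q = max(min(floor(n/3), 10), 2)``
equal-width bins.  All information quantities are plug-in estimates from
the empirical contingency tables, in bits (log base 2).

``mim`` scores every feature by its mutual information with the target.
The six greedy filters (mrmr, jmi, jmim, disr, njmim, cmim) start from the
argmax-MI feature and iteratively add the feature maximizing their
criterion relative to the already selected set G; per-iteration scores are
not comparable across iterations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..data import (
    CategorizedVariable,
    SurvivalDataset,
    categorize_equal_width,
    martingale_residuals,
    n_bins,
)
from .base import FeatureRanking, FilterScores

__all__ = [
    "entropy",
    "conditional_entropy",
    "mutual_information",
    "joint_mutual_information",
    "conditional_mutual_information",
    "CategorizedDataset",
    "categorize_dataset",
    "mim_filter",
    "greedy_mi_filter",
    "GreedySelectionTrace",
    "mi_feature_ranking",
    "GREEDY_MI_METHODS",
]

GREEDY_MI_METHODS = ("mrmr", "jmi", "jmim", "disr", "njmim", "cmim")


def _as_codes(x) -> np.ndarray:
    x = np.asarray(x)
    if x.size == 0:
        raise ValueError("empty categorical vector")
    # map arbitrary labels to 0..K-1
    _, codes = np.unique(x, return_inverse=True)
    return codes


def _joint_codes(*vars_) -> np.ndarray:
    """Encode a tuple of categoricals as one composite categorical."""
    lengths = {len(np.asarray(v)) for v in vars_}
    if len(lengths) != 1:
        raise ValueError("categorical vectors must have equal length")
    stacked = np.column_stack([_as_codes(v) for v in vars_])
    _, codes = np.unique(stacked, axis=0, return_inverse=True)
    return codes


def entropy(codes) -> float:
    """Plug-in empirical entropy in bits; 0 log 0 := 0."""
    codes = _as_codes(codes)
    p = np.bincount(codes).astype(float)
    p = p[p > 0] / codes.size
    return float(-np.sum(p * np.log2(p)))


def conditional_entropy(y, x) -> float:
    """Empirical H(Y|X) = H(Y, X) - H(X); lies in [0, H(Y)]."""
    return entropy(_joint_codes(y, x)) - entropy(x)


def mutual_information(y, x) -> float:
    """Plug-in I(Y; X) = H(Y) - H(Y|X); symmetric and nonnegative."""
    return entropy(y) - conditional_entropy(y, x)


def joint_mutual_information(y, xk, xj) -> float:
    """I(Y; Xk, Xj): MI between Y and the composite variable (Xk, Xj)."""
    return mutual_information(y, _joint_codes(xk, xj))


def conditional_mutual_information(y, xk, xj) -> float:
    """I(Y; Xk | Xj) = H(Y|Xj) - H(Y|Xk,Xj); nonnegative for plug-in estimates."""
    return conditional_entropy(y, xj) - conditional_entropy(y, _joint_codes(xk, xj))


@dataclass(frozen=True)
class CategorizedDataset:
    """Categorized target and features sharing the bin count q = n_bins(n)."""

    target: CategorizedVariable
    feature_codes: np.ndarray  # n x p integer codes
    feature_names: tuple
    q: int


def categorize_dataset(dataset: SurvivalDataset) -> CategorizedDataset:
    """Martingale residuals + equal-width categorization of target and features.

    Constant features cannot be binned by range; they are assigned a single
    category (zero MI with everything, so never preferred).
    """
    q = n_bins(dataset.n)
    resid = martingale_residuals(dataset)
    target = categorize_equal_width(resid, q)
    codes = np.empty(dataset.features.shape, dtype=int)
    for j in range(dataset.p):
        col = dataset.features[:, j]
        if np.ptp(col) == 0:
            codes[:, j] = 1
        else:
            codes[:, j] = categorize_equal_width(col, q).codes
    return CategorizedDataset(target, codes, dataset.feature_names, q)


def mim_filter(cdata: CategorizedDataset) -> FilterScores:
    """Mutual information I(Y; Xk) of every feature with the target."""
    y = cdata.target.codes
    scores = np.array(
        [mutual_information(y, cdata.feature_codes[:, j]) for j in range(len(cdata.feature_names))]
    )
    return FilterScores("mim", cdata.feature_names, scores)


@dataclass(frozen=True)
class GreedySelectionTrace:
    """Selection order of a greedy MI filter with per-iteration winning scores."""

    method: str
    selected: tuple
    iteration_scores: np.ndarray


def _greedy_score(method, y, xk, selected_codes):
    """Score of candidate xk against the selected set, per method."""
    if method == "mrmr":
        red = np.mean([mutual_information(xk, xj) for xj in selected_codes])
        return mutual_information(y, xk) - red
    if method == "jmi":
        return sum(joint_mutual_information(y, xk, xj) for xj in selected_codes)
    if method == "jmim":
        return min(joint_mutual_information(y, xk, xj) for xj in selected_codes)
    if method == "disr":
        return sum(
            joint_mutual_information(y, xk, xj) / entropy(_joint_codes(y, xk, xj))
            for xj in selected_codes
        )
    if method == "njmim":
        return min(
            joint_mutual_information(y, xk, xj) / entropy(_joint_codes(y, xk, xj))
            for xj in selected_codes
        )
    if method == "cmim":
        return min(conditional_mutual_information(y, xk, xj) for xj in selected_codes)
    raise ValueError(f"unknown greedy MI method '{method}'")


def greedy_mi_filter(cdata: CategorizedDataset, method: str, k: int) -> GreedySelectionTrace:
    """Greedy forward selection of k features by the given MI criterion.

    The first feature maximizes I(Y; Xj); each later iteration adds the
    unselected feature with the maximal method score given the current set.
    Argmax ties go to the lowest original column index.
    """
    if method not in GREEDY_MI_METHODS:
        raise ValueError(f"unknown greedy MI method '{method}'")
    p = len(cdata.feature_names)
    if not 1 <= k <= p:
        raise ValueError(f"k must lie in 1..{p}")
    y = cdata.target.codes
    relevance = np.array(
        [mutual_information(y, cdata.feature_codes[:, j]) for j in range(p)]
    )
    selected = [int(np.argmax(relevance))]
    scores = [float(relevance[selected[0]])]
    while len(selected) < k:
        best_j, best_s = None, -np.inf
        sel_codes = [cdata.feature_codes[:, j] for j in selected]
        for j in range(p):
            if j in selected:
                continue
            s = _greedy_score(method, y, cdata.feature_codes[:, j], sel_codes)
            if s > best_s:  # strict: ties keep the lowest column index
                best_j, best_s = j, s
        selected.append(best_j)
        scores.append(float(best_s))
    return GreedySelectionTrace(
        method,
        tuple(cdata.feature_names[j] for j in selected),
        np.array(scores),
    )


def mi_feature_ranking(dataset: SurvivalDataset, method: str, k: int | None = None) -> FeatureRanking:
    """Full feature ranking by an MI filter on a raw survival data set.

    ``mim`` ranks by score.  Greedy methods rank the selected prefix (depth
    ``k``, default p) in selection order, followed by the remaining
    features ordered by first-iteration relevance.
    """
    cdata = categorize_dataset(dataset)
    if method == "mim":
        from .base import rank_features

        return rank_features(mim_filter(cdata))
    k = len(dataset.feature_names) if k is None else k
    trace = greedy_mi_filter(cdata, method, k)
    if k == dataset.p:
        return FeatureRanking(method, trace.selected)
    y = cdata.target.codes
    relevance = {
        name: mutual_information(y, cdata.feature_codes[:, j])
        for j, name in enumerate(cdata.feature_names)
    }
    rest = [n for n in cdata.feature_names if n not in set(trace.selected)]
    rest.sort(key=lambda n: -relevance[n])
    return FeatureRanking(method, trace.selected + tuple(rest))
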