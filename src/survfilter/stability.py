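"""Feature-selection stability (SMA-Count) and ranking similarity (OL score).

SMA-Count scores a collection of selected feature sets by pairwise
chance-corrected overlap, additionally crediting selections of distinct
but highly similar features (|Pearson correlation| >= theta): for each
ordered pair of sets, A(Vi, Vj) counts members of Vi \\ Vj with at least
one close partner in Vj \\ Vi, and the adjustment is the minimum of both
directions.  The expectation under random selections of the same
cardinalities is the chance correction; identical sets score exactly 1.

The OL score compares two feature rankings through a weighted sum of
top-k overlaps, k = 1..r, with linearly decreasing weights normalized so
that identical rankings score 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import squareform

__all__ = [
    "SelectedFeatureSets",
    "abs_correlation_matrix",
    "adjustment_count",
    "sma_count",
    "ol_score",
    "ol_similarity_matrix",
    "mean_similarity_matrix",
    "single_linkage_order",
]


def abs_correlation_matrix(features: np.ndarray, names) -> pd.DataFrame:
    """|Pearson correlation| between feature columns, unit diagonal.

    Constant columns get zero off-diagonal similarity.
    """
    X = np.asarray(features, dtype=float)
    sd = X.std(axis=0)
    ok = sd > 0
    Z = np.zeros_like(X)
    Z[:, ok] = (X[:, ok] - X[:, ok].mean(axis=0)) / sd[ok]
    R = np.abs(Z.T @ Z / X.shape[0])
    np.fill_diagonal(R, 1.0)
    return pd.DataFrame(np.clip(R, 0.0, 1.0), index=list(names), columns=list(names))


@dataclass(frozen=True)
class SelectedFeatureSets:
    """m >= 2 selected feature sets over a common universe with a pairwise
    feature-similarity matrix (values in [0, 1], unit diagonal)."""

    sets: tuple
    universe: tuple
    similarity: pd.DataFrame

    def __post_init__(self) -> None:
        sets = tuple(frozenset(map(str, s)) for s in self.sets)
        universe = tuple(map(str, self.universe))
        if len(sets) < 2:
            raise ValueError("need at least two feature sets")
        uni = set(universe)
        for s in sets:
            if not s <= uni:
                raise ValueError("every set must be a subset of the universe")
        sim = self.similarity
        if set(sim.index) < uni or set(sim.columns) < uni:
            raise ValueError("similarity matrix must cover the universe")
        object.__setattr__(self, "sets", sets)
        object.__setattr__(self, "universe", universe)

    @classmethod
    def from_features(cls, sets, features, names) -> "SelectedFeatureSets":
        return cls(tuple(sets), tuple(names), abs_correlation_matrix(features, names))


def adjustment_count(Vi, Vj, sim: pd.DataFrame, theta: float) -> int:
    """Adj(Vi, Vj) = min of the two directed adjustment counts A."""

    def A(a, b):
        only_a = sorted(set(a) - set(b))
        only_b = sorted(set(b) - set(a))
        if not only_a or not only_b:
            return 0
        block = sim.loc[only_a, only_b].to_numpy()
        return int(np.sum(block.max(axis=1) >= theta))

    return min(A(Vi, Vj), A(Vj, Vi))


def _pair_similarity(Vi, Vj, sim, theta, p, rng, n_mc, universe):
    if Vi == Vj:
        # numerator and denominator both equal |V| - E: exactly 1 regardless
        # of the Monte-Carlo estimate of E
        return 1.0
    inter = len(Vi & Vj)
    adj = adjustment_count(Vi, Vj, sim, theta)
    denom_sqrt = np.sqrt(len(Vi) * len(Vj))
    # E[|intersection|] has the closed form |Vi||Vj|/p (hypergeometric mean);
    # the adjustment expectation is estimated by seeded Monte Carlo
    e_inter = len(Vi) * len(Vj) / p
    uni = np.asarray(universe)
    adj_draws = np.empty(n_mc)
    for b in range(n_mc):
        Ri = frozenset(rng.choice(uni, size=len(Vi), replace=False))
        Rj = frozenset(rng.choice(uni, size=len(Vj), replace=False))
        adj_draws[b] = adjustment_count(Ri, Rj, sim, theta)
    expected = e_inter + adj_draws.mean()
    denom = denom_sqrt - expected
    if denom <= 0:
        raise ValueError("degenerate denominator in pairwise stability score")
    return (inter + adj - expected) / denom


def sma_count(
    sets: SelectedFeatureSets, theta: float = 0.9, n_mc: int = 1000, seed: int = 0
) -> float:
    """SMA-Count stability: mean of the pairwise similarity scores over all
    unordered pairs of selected sets.  Maximum value 1 (perfect stability)."""
    if any(len(s) == 0 for s in sets.sets):
        raise ValueError("empty selected set")
    p = len(sets.universe)
    rng = np.random.default_rng(seed)
    m = len(sets.sets)
    total = 0.0
    for i in range(m - 1):
        for j in range(i + 1, m):
            total += _pair_similarity(
                sets.sets[i], sets.sets[j], sets.similarity, theta, p, rng, n_mc, sets.universe
            )
    return float(2.0 / (m * (m - 1)) * total)


def ol_score(Li, Lj, r: int = 100) -> float:
    """OL ranking similarity with linearly decreasing weights.

    OL = sum_{k=1..r} w_k |Li[1..k] n Lj[1..k]|, with
    w_k = (r + 1 - k) / sum_{i=1..r} i (r + 1 - i); identical rankings
    score exactly 1, disjoint top-r lists score 0.
    """
    Li, Lj = list(Li), list(Lj)
    if r > min(len(Li), len(Lj)):
        raise ValueError("r exceeds a ranking length")
    if len(set(Li)) != len(Li) or len(set(Lj)) != len(Lj):
        raise ValueError("rankings must be duplicate-free")
    # integer numerator/denominator, one division: identical rankings give
    # exactly 1.0 (the linear weights are (r+1-k) / sum_i i(r+1-i))
    seen_i, seen_j = set(), set()
    inter = 0
    numerator = 0
    for k in range(1, r + 1):
        a, b = Li[k - 1], Lj[k - 1]
        if a == b:
            inter += 1
        else:
            inter += (a in seen_j) + (b in seen_i)
        seen_i.add(a)
        seen_j.add(b)
        numerator += (r + 1 - k) * inter
    denominator = r * (r + 1) * (r + 2) // 6  # sum_{i=1..r} i (r+1-i)
    return numerator / denominator


def ol_similarity_matrix(rankings, r: int = 100) -> pd.DataFrame:
    """Symmetric matrix of pairwise OL scores between method rankings."""
    rankings = list(rankings)
    if len(rankings) < 2:
        raise ValueError("need at least two rankings")
    universes = [frozenset(rk.ordered_names) for rk in rankings]
    if len(set(universes)) != 1:
        raise ValueError("rankings must cover the same feature universe")
    labels = [rk.method for rk in rankings]
    f = len(rankings)
    M = np.eye(f)
    for i in range(f - 1):
        for j in range(i + 1, f):
            M[i, j] = M[j, i] = ol_score(
                rankings[i].ordered_names, rankings[j].ordered_names, r
            )
    return pd.DataFrame(M, index=labels, columns=labels)


def mean_similarity_matrix(matrices) -> pd.DataFrame:
    """Elementwise arithmetic mean of per-data-set similarity matrices."""
    matrices = list(matrices)
    base = matrices[0]
    out = sum(m.loc[base.index, base.columns].to_numpy() for m in matrices) / len(matrices)
    return pd.DataFrame(out, index=base.index, columns=base.columns)


def single_linkage_order(similarity: pd.DataFrame) -> list:
    """Dendrogram leaf order of single-linkage clustering on distance 1 - OL."""
    D = 1.0 - similarity.to_numpy()
    np.fill_diagonal(D, 0.0)
    D = np.clip((D + D.T) / 2, 0.0, None)
    Z = linkage(squareform(D, checks=False), method="single")
    return [similarity.index[i] for i in leaves_list(Z)]
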