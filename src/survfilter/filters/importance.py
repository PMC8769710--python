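"""Model-based importance filters: random survival forest and Cox boosting.

Random survival forests are bagging ensembles of survival trees whose
splits maximize the two-sample log-rank statistic.  Two importances are
derived: *impurity* (the sum of split log-rank statistics per feature) and
*permutation* (the mean out-of-bag drop in Harrell's C after permuting a
feature).  The *boosting* filter runs first-order gradient boosting on the
Cox partial-likelihood loss with depth-limited least-squares regression
trees as weak learners and sums each feature's split gains.

These are deliberately simplified, self-contained analogues of the ranger
and xgboost algorithms: the importances are defined conceptually (sums of
split statistics / gains, oob accuracy drops), not as numeric replicas of
those packages.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.tree import DecisionTreeRegressor

from ..data import SurvivalDataset, nelson_aalen_cumhaz
from ..models import harrell_c
from ..stepfun import StepFunction
from .base import FilterScores

__all__ = [
    "log_rank_statistic",
    "SurvivalTreeNode",
    "fit_survival_tree",
    "RSFConfig",
    "RandomSurvivalForest",
    "fit_random_survival_forest",
    "rsf_impurity_importance",
    "rsf_permutation_importance",
    "BoostingConfig",
    "BoostingModel",
    "fit_cox_gradient_boosting",
    "boosting_importance",
]


def _logrank_tables(time, event, left_mask):
    """Per-event-time O/E/V ingredients for the two-sample log-rank test."""
    t = np.asarray(time, float)
    e = np.asarray(event, int)
    etimes = np.unique(t[e == 1])
    O = E = V = 0.0
    for tj in etimes:
        at_risk = t >= tj
        r = at_risk.sum()
        r1 = (at_risk & left_mask).sum()
        d = ((t == tj) & (e == 1)).sum()
        d1 = ((t == tj) & (e == 1) & left_mask).sum()
        O += d1
        E += d * r1 / r
        if r > 1:
            V += d * (r1 / r) * (1 - r1 / r) * (r - d) / (r - 1)
    return O, E, V


def log_rank_statistic(time, event, group) -> float:
    """Two-sample log-rank chi-square statistic (O - E)^2 / V.

    ``group`` is a boolean mask (or two-level labels) assigning each
    observation to one of the two groups.
    """
    group = np.asarray(group)
    if group.dtype != bool:
        levels = np.unique(group)
        if len(levels) != 2:
            raise ValueError("group must have exactly two levels")
        group = group == levels[0]
    if group.all() or not group.any():
        raise ValueError("both groups must be nonempty")
    if np.sum(np.asarray(event) == 1) < 1:
        raise ValueError("log-rank test needs at least one event")
    O, E, V = _logrank_tables(time, event, group)
    return float((O - E) ** 2 / V) if V > 0 else 0.0


@dataclass
class SurvivalTreeNode:
    """Node of a log-rank-split survival tree.

    Internal nodes carry the split (feature index, threshold) and its
    log-rank statistic; leaves carry the Nelson-Aalen cumulative hazard of
    their members.
    """

    n_samples: int
    split_feature: int | None = None
    split_value: float | None = None
    log_rank_statistic: float = 0.0
    left: "SurvivalTreeNode | None" = None
    right: "SurvivalTreeNode | None" = None
    leaf_cumhaz: StepFunction | None = None

    @property
    def is_leaf(self) -> bool:
        return self.split_feature is None

    def predict_cumhaz(self, x: np.ndarray) -> StepFunction:
        node = self
        while not node.is_leaf:
            node = node.left if x[node.split_feature] <= node.split_value else node.right
        return node.leaf_cumhaz

    def walk(self):
        yield self
        if not self.is_leaf:
            yield from self.left.walk()
            yield from self.right.walk()


def _best_split_for_feature(x, time, event, min_node_size):
    """Best midpoint threshold of one feature by the log-rank statistic.

    All candidate thresholds are scored at once: at-risk and event counts
    of the left group are prefix sums over the rows sorted by the feature.
    """
    n = x.size
    order = np.argsort(x, kind="stable")
    xs, ts, es = x[order], time[order], event[order]
    distinct = np.flatnonzero(np.diff(xs) > 0)  # split after these positions
    if distinct.size == 0:
        return None
    sizes = distinct + 1
    ok = (sizes >= min_node_size) & (n - sizes >= min_node_size)
    if not ok.any():
        return None
    distinct = distinct[ok]
    etimes = np.unique(ts[es == 1])
    if etimes.size == 0:
        return None
    at_risk = ts[None, :] >= etimes[:, None]  # (m_times, n) in x-order
    is_event = (ts[None, :] == etimes[:, None]) & (es[None, :] == 1)
    r1 = np.cumsum(at_risk, axis=1)[:, distinct]
    d1 = np.cumsum(is_event, axis=1)[:, distinct]
    r = at_risk.sum(axis=1).astype(float)[:, None]
    d = is_event.sum(axis=1).astype(float)[:, None]
    O = d1.sum(axis=0)
    E = (d * r1 / r).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        vterm = d * (r1 / r) * (1 - r1 / r) * (r - d) / np.maximum(r - 1, 1)
    V = np.where(r > 1, vterm, 0.0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        stats = np.where(V > 0, (O - E) ** 2 / V, 0.0)
    best = int(np.argmax(stats))
    if stats[best] <= 0:
        return None
    cut_pos = distinct[best]
    threshold = 0.5 * (xs[cut_pos] + xs[cut_pos + 1])
    return float(stats[best]), threshold


def fit_survival_tree(
    dataset: SurvivalDataset, mtry: int, min_node_size: int, seed: int
) -> SurvivalTreeNode:
    """Greedy recursive partitioning by maximal log-rank statistic.

    At each node, ``mtry`` features are sampled without replacement; the
    best admissible (feature, midpoint threshold) split is taken.  A node
    becomes a leaf when it is smaller than ``2 * min_node_size`` or no
    split with a positive statistic leaves both children with at least
    ``min_node_size`` rows; leaves store the Nelson-Aalen cumulative
    hazard of their members.
    """
    if mtry > dataset.p:
        raise ValueError("mtry cannot exceed the number of features")
    rng = np.random.default_rng(seed)
    X, time, event = dataset.features, dataset.time, dataset.event

    def build(rows: np.ndarray) -> SurvivalTreeNode:
        node = SurvivalTreeNode(n_samples=rows.size)
        t, e = time[rows], event[rows]
        if rows.size >= 2 * min_node_size and np.sum(e == 1) >= 1:
            candidates = rng.choice(dataset.p, size=mtry, replace=False)
            best = None
            for j in sorted(candidates):  # deterministic tie-break by column
                found = _best_split_for_feature(X[rows, j], t, e, min_node_size)
                if found is not None and (best is None or found[0] > best[0]):
                    best = (found[0], j, found[1])
            if best is not None:
                stat, j, thr = best
                node.split_feature = int(j)
                node.split_value = float(thr)
                node.log_rank_statistic = float(stat)
                left_rows = rows[X[rows, j] <= thr]
                right_rows = rows[X[rows, j] > thr]
                node.left = build(left_rows)
                node.right = build(right_rows)
                return node
        node.leaf_cumhaz = (
            nelson_aalen_cumhaz(t, e)
            if np.sum(e == 1) >= 1
            else StepFunction(np.array([]), np.array([]), 0.0)
        )
        return node

    return build(np.arange(dataset.n))


@dataclass(frozen=True)
class RSFConfig:
    """Random survival forest configuration (defaults mirror the common
    survival-forest defaults: 500 trees, mtry = floor(sqrt(p)), minimum
    node size 3)."""

    num_trees: int = 500
    mtry: int | None = None
    min_node_size: int = 3
    seed: int = 0


@dataclass
class RandomSurvivalForest:
    trees: list
    bootstrap_indices: list
    oob_indices: list
    config: RSFConfig
    feature_names: tuple
    event_times: np.ndarray


def fit_random_survival_forest(dataset: SurvivalDataset, config: RSFConfig) -> RandomSurvivalForest:
    """Bagging ensemble of survival trees: each tree is grown on n bootstrap
    draws with replacement; rows absent from a tree's bootstrap sample form
    its out-of-bag set."""
    mtry = config.mtry if config.mtry is not None else max(1, int(np.sqrt(dataset.p)))
    ss = np.random.SeedSequence(config.seed)
    trees, boots, oobs = [], [], []
    for child in ss.spawn(config.num_trees):
        rng = np.random.default_rng(child)
        idx = rng.integers(0, dataset.n, dataset.n)
        tree_seed = int(rng.integers(0, 2**31 - 1))
        trees.append(
            fit_survival_tree(dataset.subset(idx), mtry, config.min_node_size, tree_seed)
        )
        boots.append(idx)
        oobs.append(np.setdiff1d(np.arange(dataset.n), idx))
    return RandomSurvivalForest(
        trees,
        boots,
        oobs,
        config,
        dataset.feature_names,
        np.unique(dataset.time[dataset.event == 1]),
    )


def rsf_impurity_importance(forest: RandomSurvivalForest) -> FilterScores:
    """Sum of split log-rank statistics per feature over all trees."""
    scores = np.zeros(len(forest.feature_names))
    for tree in forest.trees:
        for node in tree.walk():
            if not node.is_leaf:
                scores[node.split_feature] += node.log_rank_statistic
    return FilterScores("impurity", forest.feature_names, scores)


def _tree_risks(tree: SurvivalTreeNode, X: np.ndarray, event_times: np.ndarray) -> np.ndarray:
    """Per-row risk: the predicted cumulative hazard summed over the
    training event times (ensemble-mortality construction)."""
    return np.array(
        [np.sum(tree.predict_cumhaz(row)(event_times)) for row in X]
    )


def rsf_permutation_importance(
    forest: RandomSurvivalForest, dataset: SurvivalDataset, seed: int
) -> FilterScores:
    """Mean out-of-bag decrease of Harrell's C after permuting each feature.

    One permutation per (tree, feature), seeded from (seed, tree index,
    feature index).  Trees whose oob set has no comparable pair are
    skipped; if all are skipped, an error is raised.
    """
    p = len(forest.feature_names)
    sums = np.zeros(p)
    used = 0
    for ti, (tree, oob) in enumerate(zip(forest.trees, forest.oob_indices)):
        if oob.size < 2:
            continue
        t_oob, e_oob = dataset.time[oob], dataset.event[oob]
        X_oob = dataset.features[oob]
        try:
            c_orig = harrell_c(t_oob, e_oob, _tree_risks(tree, X_oob, forest.event_times))
        except ValueError:
            continue
        used += 1
        tree_features = {
            node.split_feature for node in tree.walk() if not node.is_leaf
        }
        for j in range(p):
            if j not in tree_features:
                continue  # predictions unchanged, contributes exactly 0
            rng = np.random.default_rng(np.random.SeedSequence((seed, ti, j)))
            Xp = X_oob.copy()
            Xp[:, j] = Xp[rng.permutation(oob.size), j]
            c_perm = harrell_c(t_oob, e_oob, _tree_risks(tree, Xp, forest.event_times))
            sums[j] += c_orig - c_perm
    if used == 0:
        raise ValueError("no tree had out-of-bag observations with comparable pairs")
    return FilterScores("permutation", forest.feature_names, sums / used)


@dataclass(frozen=True)
class BoostingConfig:
    """Cox gradient-boosting configuration (defaults: 2000 rounds, step
    size 0.05, maximum tree depth 10)."""

    n_rounds: int = 2000
    learning_rate: float = 0.05
    max_depth: int = 10
    seed: int = 0


@dataclass
class BoostingModel:
    trees: list
    config: BoostingConfig
    feature_names: tuple
    split_gains: np.ndarray  # per-feature summed squared-error gains
    train_loglik_trace: np.ndarray  # partial log-likelihood after each round

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        score = np.zeros(X.shape[0])
        for tree in self.trees:
            score += self.config.learning_rate * tree.predict(X)
        return score


def _breslow_cumhaz_at(time, event, score) -> np.ndarray:
    """H0(T_i) under current scores (Breslow), evaluated at each row's time."""
    t = np.asarray(time, float)
    e = np.asarray(event, int)
    c = score.max()
    w = np.exp(score - c)
    etimes = np.unique(t[e == 1])
    inc = np.zeros(etimes.size)
    for j, tj in enumerate(etimes):
        d = np.sum((t == tj) & (e == 1))
        inc[j] = d / w[t >= tj].sum() * np.exp(-c)
    H = np.cumsum(inc)
    idx = np.searchsorted(etimes, t, side="right") - 1
    return np.where(idx >= 0, H[np.clip(idx, 0, None)], 0.0)


def _tree_split_gains(tree: DecisionTreeRegressor, p: int) -> np.ndarray:
    """Squared-error reduction of each split, summed per feature."""
    tt = tree.tree_
    gains = np.zeros(p)
    for node in range(tt.node_count):
        left, right = tt.children_left[node], tt.children_right[node]
        if left == -1:
            continue
        gain = (
            tt.weighted_n_node_samples[node] * tt.impurity[node]
            - tt.weighted_n_node_samples[left] * tt.impurity[left]
            - tt.weighted_n_node_samples[right] * tt.impurity[right]
        )
        gains[tt.feature[node]] += max(gain, 0.0)
    return gains


def fit_cox_gradient_boosting(dataset: SurvivalDataset, config: BoostingConfig) -> BoostingModel:
    """First-order gradient boosting on the Cox partial-likelihood loss.

    Each round fits a depth-limited least-squares regression tree to the
    current martingale-type gradients g_i = Delta_i - H0(T_i) exp(f_i) and
    advances the scores by ``learning_rate`` times the tree's prediction.
    """
    if dataset.event.sum() < 1:
        raise ValueError("boosting needs at least one event")
    X, time, event = dataset.features, dataset.time, dataset.event
    f = np.zeros(dataset.n)
    trees = []
    gains = np.zeros(dataset.p)
    trace = []
    for m in range(config.n_rounds):
        g = event - _breslow_cumhaz_at(time, event, f) * np.exp(f)
        tree = DecisionTreeRegressor(
            max_depth=config.max_depth, random_state=config.seed + m
        )
        tree.fit(X, g)
        gains += _tree_split_gains(tree, dataset.p)
        f = f + config.learning_rate * tree.predict(X)
        trees.append(tree)
        trace.append(_offset_loglik(time, event, f))
    return BoostingModel(trees, config, dataset.feature_names, gains, np.array(trace))


def _offset_loglik(time, event, f) -> float:
    """Cox partial log-likelihood of fixed scores f (no free parameters)."""
    t = np.asarray(time, float)
    e = np.asarray(event, int)
    c = f.max()
    w = np.exp(f - c)
    ll = 0.0
    for tj in np.unique(t[e == 1]):
        rows = (t == tj) & (e == 1)
        d = rows.sum()
        ll += f[rows].sum() - d * (np.log(w[t >= tj].sum()) + c)
    return float(ll)


def boosting_importance(model: BoostingModel) -> FilterScores:
    """Per-feature sum of recorded split gains over all boosting trees."""
    return FilterScores("boosting", model.feature_names, model.split_gains.copy())
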