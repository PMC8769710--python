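"""Entropy/MI machinery and the seven mutual-information filters.

The greedy selectors are checked against a deliberately naive oracle that
rebuilds every probability table from scratch with ``collections.Counter``
each iteration.
"""

import math
from collections import Counter

import numpy as np
import pytest
from hypothesis import given, strategies as st

import survfilter as sf
from survfilter.filters.mi import (
    GREEDY_MI_METHODS,
    categorize_dataset,
    greedy_mi_filter,
    mim_filter,
)

# ---------------------------------------------------------------------------
# naive contingency-table oracle (independent of the package implementation)


def oracle_entropy(*cols):
    n = len(cols[0])
    counts = Counter(zip(*cols))
    return -sum(c / n * math.log2(c / n) for c in counts.values())


def oracle_mi(y, x):
    return oracle_entropy(y) + oracle_entropy(x) - oracle_entropy(y, x)


def oracle_joint_mi(y, xk, xj):
    hy = oracle_entropy(y)
    hx = oracle_entropy(xk, xj)
    hyx = oracle_entropy(y, xk, xj)
    return hy + hx - hyx


def oracle_cmi(y, xk, xj):
    return (
        oracle_entropy(y, xj)
        + oracle_entropy(xk, xj)
        - oracle_entropy(xj)
        - oracle_entropy(y, xk, xj)
    )


def oracle_greedy(y, X_codes, method, k):
    """Greedy forward selection recomputed from raw tables every iteration."""
    p = X_codes.shape[1]
    cols = [tuple(X_codes[:, j]) for j in range(p)]
    y = tuple(y)
    rel = [oracle_mi(y, c) for c in cols]
    selected = [max(range(p), key=lambda j: (rel[j], -j))]
    while len(selected) < k:
        best, best_score = None, None
        for j in range(p):
            if j in selected:
                continue
            if method == "mrmr":
                s = oracle_mi(y, cols[j]) - sum(
                    oracle_mi(cols[j], cols[i]) for i in selected
                ) / len(selected)
            elif method == "jmi":
                s = sum(oracle_joint_mi(y, cols[j], cols[i]) for i in selected)
            elif method == "jmim":
                s = min(oracle_joint_mi(y, cols[j], cols[i]) for i in selected)
            elif method == "disr":
                s = sum(
                    oracle_joint_mi(y, cols[j], cols[i])
                    / oracle_entropy(y, cols[j], cols[i])
                    for i in selected
                )
            elif method == "njmim":
                s = min(
                    oracle_joint_mi(y, cols[j], cols[i])
                    / oracle_entropy(y, cols[j], cols[i])
                    for i in selected
                )
            elif method == "cmim":
                s = min(oracle_cmi(y, cols[j], cols[i]) for i in selected)
            if best is None or s > best_score + 1e-12:
                best, best_score = j, s
        selected.append(best)
    return selected


def random_codes(seed, n=60, p=6, q=4):
    rng = np.random.default_rng(seed)
    y = rng.integers(1, q + 1, n)
    X = rng.integers(1, q + 1, (n, p))
    X[:, 0] = np.where(rng.uniform(size=n) < 0.7, y, X[:, 0])  # one informative
    return y, X


# ---------------------------------------------------------------------------


def make_cdata(y, X):
    from survfilter.data import CategorizedVariable
    from survfilter.filters.mi import CategorizedDataset

    q = int(max(y.max(), X.max()))
    target = CategorizedVariable(y, q, np.arange(q + 1) + 0.5)
    return CategorizedDataset(target, X, tuple(f"f{j}" for j in range(X.shape[1])), q)


class TestInformationQuantities:
    def test_entropy_examples(self):
        assert sf.entropy([1, 1, 2, 2]) == pytest.approx(1.0)
        assert sf.entropy([3, 3, 3]) == 0.0
        assert sf.entropy([1, 2, 3, 4]) == pytest.approx(2.0)

    def test_conditional_entropy_limits(self):
        y = [1, 2, 1, 2, 1]
        assert sf.conditional_entropy(y, [7] * 5) == pytest.approx(sf.entropy(y))
        assert sf.conditional_entropy(y, y) == pytest.approx(0.0, abs=1e-12)

    def test_conditional_entropy_matches_table_oracle(self):
        rng = np.random.default_rng(1)
        y, x = rng.integers(0, 3, 50), rng.integers(0, 3, 50)
        expected = oracle_entropy(tuple(y), tuple(x)) - oracle_entropy(tuple(x))
        assert sf.conditional_entropy(y, x) == pytest.approx(expected, abs=1e-12)

    def test_mi_self_information(self):
        y = [1, 2, 2, 3, 1, 3]
        assert sf.mutual_information(y, y) == pytest.approx(sf.entropy(y))

    def test_mi_matches_table_oracle(self):
        rng = np.random.default_rng(2)
        y, x = rng.integers(0, 4, 80), rng.integers(0, 3, 80)
        assert sf.mutual_information(y, x) == pytest.approx(oracle_mi(tuple(y), tuple(x)), abs=1e-12)

    def test_joint_mi_dominates_marginals(self):
        for seed in range(5):
            rng = np.random.default_rng(seed)
            y, xk, xj = (rng.integers(0, 3, 40) for _ in range(3))
            joint = sf.joint_mutual_information(y, xk, xj)
            assert joint >= sf.mutual_information(y, xk) - 1e-12
            assert joint >= sf.mutual_information(y, xj) - 1e-12

    def test_cmi_examples_and_oracle(self):
        rng = np.random.default_rng(3)
        y, xk, xj = (rng.integers(0, 3, 50) for _ in range(3))
        assert sf.conditional_mutual_information(y, xk, xk) == pytest.approx(0.0, abs=1e-12)
        assert sf.conditional_mutual_information(y, xk, [1] * 50) == pytest.approx(
            sf.mutual_information(y, xk), abs=1e-12
        )
        assert sf.conditional_mutual_information(y, xk, xj) == pytest.approx(
            oracle_cmi(tuple(y), tuple(xk), tuple(xj)), abs=1e-12
        )

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            sf.mutual_information([1, 2], [1, 2, 3])

    @given(st.integers(0, 200))
    def test_information_inequalities(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 60))
        y = rng.integers(0, 4, n)
        x = rng.integers(0, 4, n)
        hy, hyx = sf.entropy(y), sf.conditional_entropy(y, x)
        mi = sf.mutual_information(y, x)
        assert hy >= -1e-12 and hyx <= hy + 1e-12 and mi >= -1e-12
        assert mi == pytest.approx(sf.mutual_information(x, y), abs=1e-12)

    def test_relabeling_invariance(self):
        rng = np.random.default_rng(4)
        y, x = rng.integers(1, 4, 40), rng.integers(1, 4, 40)
        assert sf.mutual_information(y, x) == pytest.approx(
            sf.mutual_information(10 - y, x * 7), abs=1e-12
        )


class TestMimFilter:
    def test_target_copy_scores_full_entropy(self):
        y, X = random_codes(0)
        X[:, 1] = y
        scores = mim_filter(make_cdata(y, X))
        assert scores.values[1] == pytest.approx(sf.entropy(y), abs=1e-12)

    def test_constant_feature_zero(self):
        y, X = random_codes(1)
        X[:, 2] = 1
        assert mim_filter(make_cdata(y, X)).values[2] == 0.0

    def test_all_scores_match_oracle(self):
        y, X = random_codes(2, n=20, p=4)
        scores = mim_filter(make_cdata(y, X))
        for j in range(4):
            assert scores.values[j] == pytest.approx(
                oracle_mi(tuple(y), tuple(X[:, j])), abs=1e-12
            )


class TestGreedySelection:
    def test_first_pick_shared_across_methods(self):
        y, X = random_codes(5)
        cdata = make_cdata(y, X)
        first = {greedy_mi_filter(cdata, m, 1).selected[0] for m in GREEDY_MI_METHODS}
        assert len(first) == 1

    @pytest.mark.parametrize("method", GREEDY_MI_METHODS)
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_selection_matches_bruteforce_oracle(self, method, seed):
        y, X = random_codes(seed)
        cdata = make_cdata(y, X)
        trace = greedy_mi_filter(cdata, method, 4)
        expected = oracle_greedy(y, X, method, 4)
        assert trace.selected == tuple(f"f{j}" for j in expected)

    def test_duplicate_feature_not_selected_early(self):
        # f1 duplicates f0 (maximal redundancy); f2 carries fresh signal
        rng = np.random.default_rng(6)
        y = rng.integers(1, 4, 90)
        f0 = np.where(rng.uniform(size=90) < 0.8, y, rng.integers(1, 4, 90))
        f2 = np.where(rng.uniform(size=90) < 0.4, y, rng.integers(1, 4, 90))
        X = np.column_stack([f0, f0, f2])
        trace = greedy_mi_filter(make_cdata(y, X), "mrmr", 2)
        assert trace.selected == ("f0", "f2")

    def test_prefix_consistency(self):
        y, X = random_codes(7)
        cdata = make_cdata(y, X)
        for method in GREEDY_MI_METHODS:
            long = greedy_mi_filter(cdata, method, 5).selected
            short = greedy_mi_filter(cdata, method, 3).selected
            assert long[:3] == short

    def test_no_duplicates_and_bounds(self):
        y, X = random_codes(8)
        cdata = make_cdata(y, X)
        trace = greedy_mi_filter(cdata, "jmi", 6)
        assert len(set(trace.selected)) == 6
        with pytest.raises(ValueError):
            greedy_mi_filter(cdata, "jmi", 7)


class TestDatasetPipeline:
    def test_categorize_dataset_uses_bin_rule(self, random_dataset):
        ds = random_dataset(9, n=40, p=3)
        cdata = categorize_dataset(ds)
        assert cdata.q == sf.n_bins(40)
        assert cdata.target.codes.min() >= 1

    def test_constant_feature_single_category(self, random_dataset):
        base = random_dataset(10, n=20, p=2)
        X = np.column_stack([base.features, np.ones(20)])
        ds = sf.SurvivalDataset(X, ("a", "b", "c"), base.time, base.event)
        cdata = categorize_dataset(ds)
        assert np.all(cdata.feature_codes[:, 2] == 1)

    def test_full_ranking_covers_all_features(self, random_dataset):
        ds = random_dataset(11, n=30, p=5)
        for method in ("mim", "mrmr", "cmim"):
            ranking = sf.mi_feature_ranking(ds, method)
            assert sorted(ranking.ordered_names) == sorted(ds.feature_names)

    def test_greedy_prefix_then_relevance_order(self, random_dataset):
        ds = random_dataset(12, n=30, p=6)
        full = sf.mi_feature_ranking(ds, "jmi")
        prefix = sf.mi_feature_ranking(ds, "jmi", k=3)
        assert full.ordered_names[:3] == prefix.ordered_names[:3]
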