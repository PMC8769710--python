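"""Ridge Cox regression, survival prediction and IPCW metrics."""

import numpy as np
import pytest
from scipy.optimize import minimize

import survfilter as sf
from survfilter.models import (
    SurvivalPrediction,
    cox_gradient,
    cox_partial_loglik,
    ibs_grid,
)


@pytest.fixture
def well_conditioned():
    rng = np.random.default_rng(10)
    n, p = 30, 2
    X = rng.standard_normal((n, p))
    t = rng.exponential(np.exp(-X @ np.array([0.8, -0.5]))) + 0.01
    e = (rng.uniform(size=n) < 0.8).astype(int)
    return X, t, e


class TestRidgeCox:
    def test_huge_penalty_shrinks_to_zero(self, well_conditioned):
        X, t, e = well_conditioned
        model = sf.fit_ridge_cox(X, t, e, 1e6)
        assert np.linalg.norm(model.coef) < 1e-3

    def test_unpenalized_matches_generic_optimizer(self, well_conditioned):
        X, t, e = well_conditioned
        model = sf.fit_ridge_cox(X, t, e, 0.0)
        res = minimize(
            lambda b: -cox_partial_loglik(X, t, e, b), np.zeros(2), method="BFGS"
        )
        np.testing.assert_allclose(model.coef, res.x, atol=1e-4)

    def test_stationarity_of_solution(self, well_conditioned):
        X, t, e = well_conditioned
        for lam in (0.0, 0.5, 10.0):
            model = sf.fit_ridge_cox(X, t, e, lam)
            g = cox_gradient(X, t, e, model.coef, penalty=lam)
            assert np.max(np.abs(g)) < 1e-6

    def test_coefficient_norm_nonincreasing_in_penalty(self, well_conditioned):
        X, t, e = well_conditioned
        norms = [
            np.linalg.norm(sf.fit_ridge_cox(X, t, e, lam).coef)
            for lam in np.logspace(-2, 3, 10)
        ]
        assert np.all(np.diff(norms) <= 1e-9)

    def test_baseline_nondecreasing(self, well_conditioned):
        X, t, e = well_conditioned
        model = sf.fit_ridge_cox(X, t, e, 1.0)
        assert np.all(np.diff(model.baseline_cumhaz.values) > 0)

    def test_no_events_rejected(self):
        with pytest.raises(ValueError):
            sf.fit_ridge_cox(np.zeros((3, 1)), [1.0, 2.0, 3.0], [0, 0, 0], 1.0)

    def test_serializable(self, well_conditioned):
        X, t, e = well_conditioned
        d = sf.fit_ridge_cox(X, t, e, 1.0).to_dict()
        assert set(d) >= {"coef", "penalty", "baseline_knots", "baseline_values"}


class TestLambdaSelection:
    def test_deterministic(self, well_conditioned):
        X, t, e = well_conditioned
        a = sf.select_lambda_cv(X, t, e, n_folds=3, seed=4, n_lambda=15)
        b = sf.select_lambda_cv(X, t, e, n_folds=3, seed=4, n_lambda=15)
        assert a == b

    def test_pure_noise_selects_heavy_penalty(self):
        upper = 0
        for seed in range(5):
            rng = np.random.default_rng(seed)
            X = rng.standard_normal((40, 5))
            t = rng.exponential(1.0, 40) + 0.05
            e = (rng.uniform(size=40) < 0.7).astype(int)
            lam = sf.select_lambda_cv(X, t, e, n_folds=3, seed=seed, n_lambda=20)
            grid = np.sort(
                1e2
                * np.max(np.abs(cox_gradient(X, t, e, np.zeros(5))))
                * np.logspace(0, -4, 20)
            )
            upper += lam >= np.median(grid)
        assert upper >= 4

    def test_reduces_folds_with_warning_when_events_scarce(self):
        rng = np.random.default_rng(1)
        X = rng.standard_normal((20, 2))
        t = rng.exponential(1.0, 20) + 0.05
        e = np.zeros(20, int)
        e[:3] = 1
        with pytest.warns(UserWarning, match="fewer events"):
            sf.select_lambda_cv(X, t, e, n_folds=10, seed=0, n_lambda=10)


class TestPrediction:
    def test_zero_coef_gives_baseline(self, well_conditioned):
        X, t, e = well_conditioned
        model = sf.fit_ridge_cox(X, t, e, 1e8)
        pred = sf.predict_survival(model, X[:3])
        base = np.exp(-model.baseline_cumhaz.values)
        for i in range(3):
            np.testing.assert_allclose(pred.surv[i], base, atol=1e-4)

    def test_monotone_in_linear_predictor(self, well_conditioned):
        X, t, e = well_conditioned
        model = sf.fit_ridge_cox(X, t, e, 0.5)
        x_low, x_high = -2 * model.coef, 2 * model.coef  # eta < 0 < eta
        pred = sf.predict_survival(model, np.vstack([x_low, x_high]))
        assert np.all(pred.surv[0] >= pred.surv[1])

    def test_survival_curve_validity(self, well_conditioned):
        X, t, e = well_conditioned
        pred = sf.predict_survival(sf.fit_ridge_cox(X, t, e, 1.0), X)
        assert np.all((pred.surv >= 0) & (pred.surv <= 1))
        assert np.all(np.diff(pred.surv, axis=1) <= 1e-15)
        np.testing.assert_allclose(pred.at(0.0), np.ones(30))

    def test_feature_name_mismatch_rejected(self, well_conditioned):
        X, t, e = well_conditioned
        model = sf.fit_ridge_cox(X, t, e, 1.0, feature_names=("a", "b"))
        with pytest.raises(ValueError):
            sf.predict_survival(model, X, feature_names=("b", "a"))


class TestKMPredictor:
    def test_identical_curves_equal_training_km(self):
        t = np.array([1.0, 2.0, 3.0, 4.0])
        e = np.array([1, 0, 1, 1])
        pred = sf.km_predictor(t, e, n_obs=3)
        km = sf.kaplan_meier(t, e)
        for i in range(3):
            np.testing.assert_allclose(pred.surv[i], km.values)

    def test_no_events_all_ones(self):
        pred = sf.km_predictor(np.array([1.0, 2.0]), np.array([0, 0]))
        assert np.all(pred.surv == 1.0)


class TestHarrellC:
    def test_perfect_and_reversed(self):
        t, e = [1.0, 2.0, 3.0], [1, 1, 1]
        assert sf.harrell_c(t, e, [3.0, 2.0, 1.0]) == 1.0
        assert sf.harrell_c(t, e, [1.0, 2.0, 3.0]) == 0.0

    def test_censored_case_matches_pair_enumeration(self):
        t = np.array([2.0, 3.0, 4.0, 5.0, 6.0])
        e = np.array([1, 0, 1, 0, 1])
        r = np.array([0.5, 1.0, 0.7, 0.2, 0.2])
        conc = comp = 0.0
        for i in range(5):
            for j in range(5):
                if t[i] < t[j] and e[i] == 1:
                    comp += 1
                    conc += 1.0 if r[i] > r[j] else (0.5 if r[i] == r[j] else 0.0)
        assert sf.harrell_c(t, e, r) == pytest.approx(conc / comp)

    def test_complement_identity_without_ties(self):
        rng = np.random.default_rng(3)
        t = rng.exponential(1, 15) + 0.1
        e = (rng.uniform(size=15) < 0.7).astype(int)
        e[0] = 1
        r = rng.standard_normal(15)
        assert sf.harrell_c(t, e, r) + sf.harrell_c(t, e, -r) == pytest.approx(1.0)

    def test_agrees_with_scikit_survival(self):
        from sksurv.metrics import concordance_index_censored

        rng = np.random.default_rng(6)
        t = rng.exponential(1, 25) + 0.1
        e = (rng.uniform(size=25) < 0.6).astype(int)
        e[0] = 1
        r = rng.standard_normal(25)
        expected = concordance_index_censored(e.astype(bool), t, r)[0]
        assert sf.harrell_c(t, e, r) == pytest.approx(expected, abs=1e-12)

    def test_no_comparable_pairs_rejected(self):
        with pytest.raises(ValueError):
            sf.harrell_c([1.0, 1.0], [1, 1], [0.5, 0.7])


def _const_prediction(value, times, n):
    return SurvivalPrediction(np.asarray(times, float), np.full((n, len(times)), value))


class TestBrierScore:
    def test_perfect_prediction_no_censoring_zero(self):
        t = np.array([1.0, 2.0, 3.0])
        e = np.array([1, 1, 1])
        G = sf.kaplan_meier(t, 1 - e)  # no censoring: G = 1 everywhere
        times = np.array([0.5, 1.5, 2.5, 3.5])
        surv = np.array([(t_i > times).astype(float) for t_i in t])
        pred = SurvivalPrediction(times, surv)
        for horizon in (1.5, 2.5):
            assert sf.brier_score(pred, t, e, horizon, G) == pytest.approx(0.0)

    def test_coin_flip_prediction_quarter(self):
        t = np.array([1.0, 2.0, 3.0, 4.0])
        e = np.ones(4, int)
        G = sf.kaplan_meier(t, 1 - e)
        pred = _const_prediction(0.5, [0.5], 4)
        for horizon in (0.7, 1.5, 3.5):
            assert sf.brier_score(pred, t, e, horizon, G) == pytest.approx(0.25)

    def test_hand_computed_censored_case(self):
        t = np.array([2.0, 5.0, 7.0])
        e = np.array([1, 1, 0])
        G = sf.kaplan_meier(t, 1 - e)  # censoring event at t=7 only
        pred = SurvivalPrediction(np.array([4.0]), np.array([[0.8], [0.5], [0.4]]))
        # at horizon 4: obs1 evented at 2 (G(2-)=1): 0.8^2; obs2, obs3 still
        # at risk (G(4)=1): 0.5^2 and 0.6^2
        expected = (0.64 + 0.25 + 0.36) / 3
        assert sf.brier_score(pred, t, e, 4.0, G) == pytest.approx(expected, abs=1e-12)

    def test_vanishing_censoring_survival_rejected(self):
        # G estimated on training data hits 0 at its last (censored) time;
        # a test observation beyond that point cannot be weighted
        G = sf.kaplan_meier(np.array([1.0, 3.0]), np.array([1, 1]))
        assert G(3.0) == 0.0
        t = np.array([2.0, 5.0])
        e = np.array([1, 0])
        pred = _const_prediction(0.5, [0.5], 2)
        with pytest.raises(ValueError):
            sf.brier_score(pred, t, e, 4.0, G)


class TestIntegratedBrier:
    def test_perfect_prediction_zero(self):
        t = np.array([1.0, 2.0, 3.0, 4.0])
        e = np.ones(4, int)
        G = sf.kaplan_meier(t, 1 - e)
        surv = np.array([(t_i > t).astype(float) for t_i in t])
        pred = SurvivalPrediction(t, surv)
        assert sf.integrated_brier_score(pred, t, e, G) == pytest.approx(0.0)

    def test_coin_flip_quarter(self):
        t = np.array([1.0, 2.0, 3.0, 4.0])
        e = np.ones(4, int)
        G = sf.kaplan_meier(t, 1 - e)
        pred = _const_prediction(0.5, [0.5], 4)
        assert sf.integrated_brier_score(pred, t, e, G) == pytest.approx(0.25)

    def test_bounded_on_random_fixtures(self, random_dataset):
        for seed in range(5):
            train = random_dataset(seed, n=40, p=3)
            test = random_dataset(seed + 100, n=25, p=3)
            model = sf.fit_ridge_cox(train.features, train.time, train.event, 1.0)
            pred = sf.predict_survival(model, test.features)
            G = sf.kaplan_meier(train.time, 1 - train.event)
            ibs = sf.integrated_brier_score(pred, test.time, test.event, G)
            assert 0.0 <= ibs <= 1.0

    def test_km_self_ibs_equals_time_average(self, random_dataset):
        ds = random_dataset(7, n=50, p=2)
        pred = sf.km_predictor(ds.time, ds.event)
        G = sf.kaplan_meier(ds.time, 1 - ds.event)
        grid = ibs_grid(ds.time, ds.event, G)
        bs = [sf.brier_score(pred, ds.time, ds.event, u, G) for u in grid]
        expected = np.trapezoid(bs, grid) / (grid[-1] - grid[0])
        assert sf.integrated_brier_score(pred, ds.time, ds.event, G) == pytest.approx(expected)

    def test_degenerate_grid_rejected(self):
        t = np.array([1.0, 2.0])
        e = np.array([1, 0])
        G = sf.kaplan_meier(t, 1 - e)
        pred = _const_prediction(0.5, [0.5], 2)
        with pytest.raises(ValueError):
            sf.integrated_brier_score(pred, t, e, G)
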