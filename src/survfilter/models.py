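"""Predictive survival models and IPCW evaluation metrics.

The downstream learner of the benchmark is a ridge (L2) penalized Cox
proportional hazards model h(t, x) = h0(t) exp(x'beta), fitted by Newton
iterations on the penalized partial log-likelihood (Breslow tie handling),
with the penalty weight chosen by cross-validated partial-likelihood
deviance.  The feature-free baseline is the Kaplan-Meier curve.

Prediction error is measured by the inverse-probability-of-censoring
weighted Brier score and its time-averaged integral (IBS, range [0, 1],
lower is better); discrimination by Harrell's concordance index.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .data import SurvivalDataset, kaplan_meier, stratified_folds
from .stepfun import StepFunction

__all__ = [
    "RidgeCoxModel",
    "SurvivalPrediction",
    "fit_ridge_cox",
    "select_lambda_cv",
    "predict_survival",
    "km_predictor",
    "harrell_c",
    "brier_score",
    "integrated_brier_score",
    "ibs_grid",
    "cox_partial_loglik",
    "cox_gradient",
]


# ---------------------------------------------------------------------------
# Cox partial likelihood machinery (Breslow ties)


def _sorted_views(time, event, X=None):
    order = np.argsort(-np.asarray(time, dtype=float), kind="stable")
    t, e = np.asarray(time, float)[order], np.asarray(event)[order]
    return (t, e, None if X is None else np.asarray(X, float)[order])


def cox_partial_loglik(X, time, event, beta) -> float:
    """Breslow partial log-likelihood at ``beta``."""
    t, e, Xs = _sorted_views(time, event, X)
    eta = Xs @ beta
    # guard against overflow in exp by centering
    c = eta.max() if eta.size else 0.0
    log_cum = np.log(np.cumsum(np.exp(eta - c))) + c
    ll = 0.0
    for tj in np.unique(t[e == 1]):
        rows = np.flatnonzero((t == tj) & (e == 1))
        j = np.flatnonzero(t >= tj)[-1]
        ll += eta[rows].sum() - len(rows) * log_cum[j]
    return float(ll)


def cox_gradient(X, time, event, beta, penalty: float = 0.0) -> np.ndarray:
    """Gradient of the (optionally L2-penalized) partial log-likelihood."""
    t, e, Xs = _sorted_views(time, event, X)
    eta = Xs @ beta
    w = np.exp(eta - eta.max())
    S0 = np.cumsum(w)
    S1 = np.cumsum(w[:, None] * Xs, axis=0)
    g = np.zeros_like(beta)
    for tj in np.unique(t[e == 1]):
        rows = np.flatnonzero((t == tj) & (e == 1))
        j = np.flatnonzero(t >= tj)[-1]
        g += Xs[rows].sum(axis=0) - len(rows) * S1[j] / S0[j]
    return g - penalty * beta


def _cox_grad_hess(Xs, t, e, beta, penalty):
    """Penalized gradient and Hessian of the negative partial log-likelihood
    at ``beta``, rows pre-sorted by descending time."""
    n, p = Xs.shape
    eta = Xs @ beta
    w = np.exp(eta - eta.max())
    S0 = np.cumsum(w)
    S1 = np.cumsum(w[:, None] * Xs, axis=0)
    etimes = np.unique(t[e == 1])
    boundary = {tj: int(np.flatnonzero(t >= tj)[-1]) for tj in etimes}
    # risk-set second moments at the prefix boundaries, built incrementally
    # from segment-wise X' diag(w) X products (BLAS) instead of per-row outers
    g = np.zeros(p)
    H = np.zeros((p, p))
    S2 = np.zeros((p, p))
    start = 0
    for tj in etimes[::-1]:  # largest event time first = smallest risk-set prefix
        j = boundary[tj]
        if j >= start:
            seg = Xs[start : j + 1]
            S2 += seg.T @ (w[start : j + 1, None] * seg)
            start = j + 1
        rows = np.flatnonzero((t == tj) & (e == 1))
        d = len(rows)
        mean = S1[j] / S0[j]
        g += Xs[rows].sum(axis=0) - d * mean
        H += d * (S2 / S0[j] - np.outer(mean, mean))
    g -= penalty * beta
    H += penalty * np.eye(p)
    return g, H


@dataclass(frozen=True)
class RidgeCoxModel:
    """Fitted L2-penalized Cox model with Breslow baseline cumulative hazard."""

    coef: np.ndarray
    penalty: float
    baseline_cumhaz: StepFunction
    feature_names: tuple

    def linear_predictor(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(X, float) @ self.coef

    def to_dict(self) -> dict:
        return {
            "coef": self.coef.tolist(),
            "penalty": self.penalty,
            "feature_names": list(self.feature_names),
            "baseline_knots": self.baseline_cumhaz.knots.tolist(),
            "baseline_values": self.baseline_cumhaz.values.tolist(),
        }


def _breslow_baseline(X, time, event, beta) -> StepFunction:
    t, e, Xs = _sorted_views(time, event, X)
    eta = Xs @ beta
    c = eta.max()
    S0 = np.cumsum(np.exp(eta - c))
    etimes = np.unique(t[e == 1])
    inc = []
    for tj in etimes:
        d = np.sum((t == tj) & (e == 1))
        j = np.flatnonzero(t >= tj)[-1]
        inc.append(d / S0[j] * np.exp(-c))
    return StepFunction(etimes, np.cumsum(inc), value_before=0.0)


def fit_ridge_cox(
    X,
    time,
    event,
    penalty: float,
    feature_names=None,
    beta0=None,
    tol: float = 1e-8,
    max_iter: int = 100,
) -> RidgeCoxModel:
    """Maximize the L2-penalized partial log-likelihood by damped Newton.

    Convergence when the penalized gradient's max component drops below
    ``tol``; raises on non-convergence, reporting the last gradient norm.
    """
    X = np.asarray(X, dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event)
    if event.sum() < 1:
        raise ValueError("cannot fit a Cox model without events")
    if penalty < 0:
        raise ValueError("penalty must be nonnegative")
    n, p = X.shape
    if feature_names is None:
        feature_names = tuple(f"x{j}" for j in range(p))
    t, e, Xs = _sorted_views(time, event, X)
    beta = np.zeros(p) if beta0 is None else np.array(beta0, dtype=float)

    def objective(b):
        return -cox_partial_loglik(X, time, event, b) + 0.5 * penalty * b @ b

    obj = objective(beta)
    for _ in range(max_iter):
        g, H = _cox_grad_hess(Xs, t, e, beta, penalty)
        if np.max(np.abs(g)) < tol:
            break
        try:
            step = np.linalg.solve(H, g)
        except np.linalg.LinAlgError:
            step = np.linalg.solve(H + 1e-8 * np.eye(p), g)
        # step halving on the penalized negative log-likelihood
        alpha = 1.0
        for _ in range(30):
            cand = beta + alpha * step
            cand_obj = objective(cand)
            if cand_obj <= obj + 1e-12:
                break
            alpha *= 0.5
        beta, obj = cand, cand_obj
    else:
        g, _ = _cox_grad_hess(Xs, t, e, beta, penalty)
        if np.max(np.abs(g)) >= tol:
            raise RuntimeError(
                f"ridge Cox did not converge: max|gradient| = {np.max(np.abs(g)):.3e}"
            )
    return RidgeCoxModel(beta, float(penalty), _breslow_baseline(X, time, event, beta), tuple(feature_names))


def select_lambda_cv(
    X,
    time,
    event,
    n_folds: int = 10,
    seed: int = 0,
    n_lambda: int = 100,
    lambda_min_ratio: float = 1e-4,
) -> float:
    """Penalty selection by cross-validated partial-likelihood deviance.

    A log-spaced grid of ``n_lambda`` values descends from lambda_max
    (scaled from the score vector at beta = 0 so that the fitted
    coefficients are essentially zero there) by ``lambda_min_ratio``.  The
    held-out deviance of a fold is the Verweij-van Houwelingen difference
    -2 [pl(all data; beta) - pl(training part; beta)].  Folds are
    event-stratified; ties in the deviance go to the larger penalty.
    """
    X = np.asarray(X, dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    if n_folds < 2:
        raise ValueError("n_folds must be at least 2")
    n_events = int(event.sum())
    if n_events < n_folds:
        warnings.warn(
            f"fewer events ({n_events}) than folds ({n_folds}); reducing folds",
            stacklevel=2,
        )
        n_folds = max(2, n_events)
    g0 = cox_gradient(X, time, event, np.zeros(X.shape[1]))
    lam_max = 1e2 * max(np.max(np.abs(g0)), 1e-8)
    grid = lam_max * np.logspace(0, np.log10(lambda_min_ratio), n_lambda)
    ds = SurvivalDataset(X, tuple(f"x{j}" for j in range(X.shape[1])), time, event)
    folds = stratified_folds(ds, n_folds, seed)
    dev = np.zeros(n_lambda)
    for train_idx, _test_idx in folds.splits():
        Xtr, ttr, etr = X[train_idx], time[train_idx], event[train_idx]
        beta = np.zeros(X.shape[1])
        for li, lam in enumerate(grid):  # warm-started path, large to small
            model = fit_ridge_cox(Xtr, ttr, etr, lam, beta0=beta)
            beta = model.coef
            dev[li] += -2.0 * (
                cox_partial_loglik(X, time, event, beta)
                - cox_partial_loglik(Xtr, ttr, etr, beta)
            )
    best = int(np.argmin(dev))  # argmin returns the first (largest-lambda) tie
    return float(grid[best])


@dataclass(frozen=True)
class SurvivalPrediction:
    """Per-observation survival curves S(t | x_i) on a shared time grid.

    ``surv[i, j]`` is the predicted survival of observation i at
    ``times[j]``; curves are 1 before the first grid time and
    right-continuous.
    """

    times: np.ndarray
    surv: np.ndarray

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        surv = np.asarray(self.surv, dtype=float)
        if surv.ndim != 2 or surv.shape[1] != times.size:
            raise ValueError("surv must be (n_obs, n_times)")
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "surv", surv)

    @property
    def n_obs(self) -> int:
        return self.surv.shape[0]

    def at(self, t: float) -> np.ndarray:
        """Survival probabilities of all observations at time t."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return self.surv[:, idx] if idx >= 0 else np.ones(self.n_obs)

    def curve(self, i: int) -> StepFunction:
        return StepFunction(self.times, self.surv[i], value_before=1.0)


def predict_survival(model: RidgeCoxModel, X_new, feature_names=None) -> SurvivalPrediction:
    """S(t | x) = exp(-H0(t) exp(x'beta)) for new observations."""
    if feature_names is not None and tuple(feature_names) != model.feature_names:
        raise ValueError("feature names do not match the training features")
    eta = model.linear_predictor(X_new)
    H0 = model.baseline_cumhaz.values
    return SurvivalPrediction(
        model.baseline_cumhaz.knots,
        np.exp(-np.outer(np.exp(eta), H0)),
    )


def km_predictor(time, event, n_obs: int | None = None) -> SurvivalPrediction:
    """Feature-free baseline: every observation receives the training
    Kaplan-Meier curve."""
    km = kaplan_meier(time, event)
    n_obs = len(np.asarray(time)) if n_obs is None else n_obs
    if km.knots.size == 0:
        return SurvivalPrediction(np.array([np.inf]), np.ones((n_obs, 1)))
    return SurvivalPrediction(km.knots, np.tile(km.values, (n_obs, 1)))


def harrell_c(time, event, risk) -> float:
    """Harrell's concordance index.

    A pair (i, j) is comparable when t_i < t_j and observation i had the
    event; it is concordant when the shorter survivor carries the higher
    risk, and risk ties count 1/2.
    """
    t = np.asarray(time, dtype=float)
    e = np.asarray(event, dtype=int)
    r = np.asarray(risk, dtype=float)
    ii, jj = np.meshgrid(np.arange(t.size), np.arange(t.size), indexing="ij")
    comparable = (t[ii] < t[jj]) & (e[ii] == 1)
    n_comp = comparable.sum()
    if n_comp == 0:
        raise ValueError("no comparable pairs")
    conc = (r[ii] > r[jj]) & comparable
    tied = (r[ii] == r[jj]) & comparable
    return float((conc.sum() + 0.5 * tied.sum()) / n_comp)


def brier_score(prediction: SurvivalPrediction, time, event, t: float, G_hat: StepFunction) -> float:
    """IPCW Brier score at horizon t.

    BS(t) = mean over observations of
    S(t|x_i)^2 1(t_i <= t, event) / G(t_i-) + (1 - S(t|x_i))^2 1(t_i > t) / G(t).
    """
    ti = np.asarray(time, dtype=float)
    ei = np.asarray(event, dtype=int)
    s = prediction.at(t)
    past_event = (ti <= t) & (ei == 1)
    future = ti > t
    out = np.zeros(ti.size)
    if past_event.any():
        g = np.asarray(G_hat.left_limit(ti[past_event]), dtype=float)
        if np.any(g <= 0):
            raise ValueError("censoring survival function vanishes before horizon")
        out[past_event] = s[past_event] ** 2 / g
    if future.any():
        gt = float(G_hat(t))
        if gt <= 0:
            raise ValueError("censoring survival function vanishes at horizon")
        out[future] = (1.0 - s[future]) ** 2 / gt
    return float(out.mean())


def ibs_grid(time, event, G_hat: StepFunction) -> np.ndarray:
    """Evaluation grid for the IBS: unique test event times within
    [first event time, tau], tau the largest test time with G(tau) > 0."""
    ti = np.asarray(time, dtype=float)
    ei = np.asarray(event, dtype=int)
    etimes = np.unique(ti[ei == 1])
    if etimes.size == 0:
        raise ValueError("no events in the evaluation data")
    ok = np.asarray(G_hat(ti), dtype=float) > 0
    if not ok.any():
        raise ValueError("censoring survival function vanishes on all test times")
    tau = float(ti[ok].max())
    return etimes[(etimes >= etimes[0]) & (etimes <= tau)]


def integrated_brier_score(
    prediction: SurvivalPrediction, time, event, G_hat: StepFunction, grid=None
) -> float:
    """Time-averaged IPCW Brier score over the evaluation grid (trapezoid
    rule divided by the grid span), guaranteeing the [0, 1] range."""
    grid = ibs_grid(time, event, G_hat) if grid is None else np.asarray(grid, float)
    if grid.size < 2:
        raise ValueError("IBS needs at least 2 grid points")
    bs = np.array([brier_score(prediction, time, event, t, G_hat) for t in grid])
    return float(np.trapezoid(bs, grid) / (grid[-1] - grid[0]))
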