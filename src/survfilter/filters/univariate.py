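"""Univariate filter scores: variance, correlation, Cox score test, CARSS.

* ``variance``: the sample variance of each feature, ignoring the outcome.
  Only meaningful when all features share a common, unscaled measurement
  scale (as raw gene-expression matrices do).
* ``correlation``: |Pearson correlation| between each feature and the
  martingale-residual surrogate outcome.
* ``cox.score``: the score-test statistic U(0)^2 / I(0) of the univariate
  Cox model containing only that feature.
* ``carss``: absolute correlation-adjusted regression survival scores --
  IPC-weighted marginal correlations with log(T), decorrelated by the
  inverse square root of the shrunken feature correlation matrix.

Constant features receive score 0 everywhere ("no evidence" rather than an
error), keeping full-matrix filtering total.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..data import SurvivalDataset, kaplan_meier, martingale_residuals
from .base import FilterScores

__all__ = [
    "variance_filter",
    "correlation_filter",
    "cox_score_filter",
    "carss_filter",
    "CarssIntermediate",
]


def variance_filter(dataset: SurvivalDataset) -> FilterScores:
    """Sample variance (denominator n-1) of each feature."""
    if dataset.n < 2:
        raise ValueError("variance filter needs at least 2 observations")
    return FilterScores(
        "variance", dataset.feature_names, np.var(dataset.features, axis=0, ddof=1)
    )


def _abs_corr_with(dataset: SurvivalDataset, y: np.ndarray) -> np.ndarray:
    X = dataset.features
    Xc = X - X.mean(axis=0)
    yc = y - y.mean()
    sx = np.sqrt(np.sum(Xc * Xc, axis=0))
    sy = np.sqrt(np.sum(yc * yc))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (Xc.T @ yc) / (sx * sy)
    r[sx == 0] = 0.0  # constant features carry no evidence
    return np.abs(r)


def correlation_filter(dataset: SurvivalDataset) -> FilterScores:
    """|Pearson correlation| of each feature with the martingale residuals."""
    if dataset.n < 3:
        raise ValueError("correlation filter needs at least 3 observations")
    resid = martingale_residuals(dataset)
    if np.ptp(resid) == 0:
        raise ValueError("martingale residuals are degenerate (all equal)")
    return FilterScores(
        "correlation", dataset.feature_names, _abs_corr_with(dataset, resid)
    )


def cox_score_filter(dataset: SurvivalDataset) -> FilterScores:
    """Cox score-test statistic U_k(0)^2 / I_k(0) per feature.

    With Breslow tie handling, U_k(0) sums (x_ik - risk-set mean of x_k)
    over events and I_k(0) sums the risk-set population variance of x_k
    over events.  Computed for all features at once via reverse cumulative
    sums over time-sorted rows.
    """
    time, event, X = dataset.time, dataset.event, dataset.features
    if event.sum() < 1:
        raise ValueError("cox score filter needs at least one event")
    order = np.argsort(-time, kind="stable")  # descending time
    ts, es, Xs = time[order], event[order], X[order]
    cs1 = np.cumsum(Xs, axis=0)  # risk-set sums of x
    cs2 = np.cumsum(Xs * Xs, axis=0)  # risk-set sums of x^2
    counts = np.arange(1, dataset.n + 1, dtype=float)

    # risk set of an event time t_j = all rows with time >= t_j; with ties in
    # time, the last occurrence (descending order) indexes the full risk set
    etimes = np.unique(ts[es == 1])
    U = np.zeros(dataset.p)
    I = np.zeros(dataset.p)
    for t in etimes:
        in_risk = np.flatnonzero(ts >= t)  # prefix of the descending order
        j = in_risk[-1]
        r = counts[j]
        mean = cs1[j] / r
        var = cs2[j] / r - mean**2
        ev_rows = np.flatnonzero((ts == t) & (es == 1))
        d = len(ev_rows)
        U += Xs[ev_rows].sum(axis=0) - d * mean
        I += d * var
    with np.errstate(invalid="ignore", divide="ignore"):
        stat = U * U / I
    stat[I <= 0] = 0.0  # constant feature: U = 0 and I = 0, score 0
    return FilterScores("cox.score", dataset.feature_names, stat)


@dataclass(frozen=True)
class CarssIntermediate:
    """Intermediate quantities of the CARSS computation (for inspection)."""

    ipc_weights: np.ndarray
    marginal_correlations: np.ndarray
    shrinkage_intensity: float


def ipc_weights(time, event) -> np.ndarray:
    """Normalized inverse-probability-of-censoring weights on the log-time scale.

    G is the Kaplan-Meier estimate of the censoring survival function on
    log(T); the raw weight of an uncensored observation is 1 / G(log t-),
    censored observations get weight 0, and weights are normalized to sum 1.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event)
    logt = np.log(time)
    # shift to positive times: KM only uses the ordering of the knots
    G = kaplan_meier(logt - logt.min() + 1.0, 1 - event)
    w = np.zeros(time.size)
    uncens = event == 1
    Gm = G.left_limit(logt[uncens] - logt.min() + 1.0)
    if np.any(Gm <= 0):
        raise ValueError("censoring survival function vanishes at an event time")
    w[uncens] = 1.0 / Gm
    total = w.sum()
    if total == 0:
        raise ValueError("carss needs at least one uncensored observation")
    return w / total


def _shrinkage_intensity(Z: np.ndarray) -> float:
    """Analytic (Ledoit-Wolf / Schaefer-Strimmer) shrinkage of the feature
    correlation matrix toward the identity.

    lambda* = sum_{k != l} Var-hat(r_kl) / sum_{k != l} r_kl^2, clamped to
    [0, 1].  ``Z`` holds standardized feature columns (mean 0, 1/(n-1)
    normalization so that Z'Z = R).  Both sums are computed with O(n^2 p)
    Gram-matrix identities, never forming the p x p matrix.
    """
    n, p = Z.shape
    if n < 3 or p < 2:
        return 0.0
    # sum of squared off-diagonal correlations: ||Z'Z||_F^2 - sum_k r_kk^2
    Zn = Z * np.sqrt(n - 1)  # rows z_i with sum_i z_ik^2 = n-1 per column
    G = Zn @ Zn.T  # n x n
    frob2 = np.sum((G / (n - 1)) ** 2)
    diag_r2 = np.sum((np.sum(Zn * Zn, axis=0) / (n - 1)) ** 2)
    off_r2 = frob2 - diag_r2
    if off_r2 <= 0:
        return 1.0
    # Var-hat(r_kl) = n / (n-1)^3 * [ sum_i (z_ik z_il)^2 - (sum_i z_ik z_il)^2 / n ]
    sq = Zn * Zn
    sum_sq_all = np.sum(np.sum(sq, axis=1) ** 2)  # sum_{k,l} sum_i z2_ik z2_il
    sum_sq_diag = np.sum(sq * sq)
    cross_all = np.sum(G * G)  # sum_{k,l} (sum_i z_ik z_il)^2
    cross_diag = np.sum(np.sum(sq, axis=0) ** 2)
    var_sum = n / (n - 1) ** 3 * (
        (sum_sq_all - sum_sq_diag) - (cross_all - cross_diag) / n
    )
    return float(np.clip(var_sum / off_r2, 0.0, 1.0))


def carss_filter(
    dataset: SurvivalDataset,
    shrinkage: float | None = None,
    return_intermediate: bool = False,
):
    """Correlation-adjusted regression survival scores.

    Steps: (i) IPC weights from the Kaplan-Meier estimate of the censoring
    distribution on the log-time scale; (ii) weighted marginal correlations
    of each feature with log(T) (weighted covariance and target variance,
    unweighted feature variance); (iii) analytic shrinkage intensity lambda
    of the feature correlation matrix toward identity; (iv) scores
    |R_shrink^{-1/2} R_{X,logT}|, evaluated in the n-dimensional sample
    space so no dense p x p matrix is ever formed.

    ``shrinkage`` overrides the estimated lambda (e.g. 1.0 yields the pure
    marginal correlations).
    """
    if dataset.event.sum() < 2:
        raise ValueError("carss needs at least 2 events")
    if dataset.n < 3:
        raise ValueError("carss needs at least 3 observations")
    X = dataset.features
    n = dataset.n
    w = ipc_weights(dataset.time, dataset.event)
    logt = np.log(dataset.time)

    # weighted marginal correlations R_{X, logT}
    mu_t = float(w @ logt)
    var_t = float(w @ (logt - mu_t) ** 2)
    xbar_w = w @ X
    cov_w = (w[:, None] * (X - xbar_w)).T @ (logt - mu_t)
    sd_x = X.std(axis=0)  # population form: equal weights reduce to Pearson
    with np.errstate(invalid="ignore", divide="ignore"):
        r_xy = cov_w / (sd_x * np.sqrt(var_t))
    constant = sd_x == 0
    r_xy[constant] = 0.0
    r_xy = np.clip(r_xy, -1.0, 1.0)

    # standardized feature matrix with Z'Z = R (constant columns zeroed)
    Z = (X - X.mean(axis=0)) / np.where(constant, 1.0, X.std(axis=0, ddof=1))
    Z[:, constant] = 0.0
    Z = Z / np.sqrt(n - 1)

    lam = _shrinkage_intensity(Z) if shrinkage is None else float(shrinkage)
    if not 0.0 <= lam <= 1.0:
        raise ValueError("shrinkage intensity must lie in [0, 1]")

    # R_shrink = lam I + (1-lam) Z'Z.  With Z = U S V', R_shrink^{-1/2} x =
    # x / sqrt(lam) + V [ (lam + (1-lam) s^2)^{-1/2} - lam^{-1/2} ] V' x.
    if lam == 1.0:
        scores = np.abs(r_xy)
    else:
        U, s, Vt = np.linalg.svd(Z, full_matrices=False)
        d = lam + (1.0 - lam) * s**2
        if lam == 0.0:
            keep = s**2 > 1e-12
            inv_sqrt = np.zeros_like(d)
            inv_sqrt[keep] = 1.0 / np.sqrt(d[keep])
            scores = np.abs(Vt.T @ (inv_sqrt * (Vt @ r_xy)))
        else:
            delta = 1.0 / np.sqrt(d) - 1.0 / np.sqrt(lam)
            scores = np.abs(r_xy / np.sqrt(lam) + Vt.T @ (delta * (Vt @ r_xy)))
    scores[constant] = 0.0
    result = FilterScores("carss", dataset.feature_names, scores)
    if return_intermediate:
        return result, CarssIntermediate(w, r_xy, lam)
    return result
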