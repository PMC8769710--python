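"""Survival data model, file I/O, resampling and target transformations.

A right-censored survival data set consists of a continuous feature matrix
``X`` (n observations x p features), observed times ``T = min(T_true, C)``
and event indicators ``Delta = 1(T_true <= C)``.  Several filter methods do
not operate on ``(T, Delta)`` directly but on transformed targets:

* martingale residuals ``M_i = Delta_i - H(T_i)`` of the null Cox model,
  whose baseline cumulative hazard ``H`` is the Nelson-Aalen estimator --
  an uncensored continuous surrogate outcome;
* an equal-width categorization of the residuals (and of each feature) into
  ``q = max(min(floor(n/3), 10), 2)`` bins, for the mutual-information
  filters.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .stepfun import StepFunction

__all__ = [
    "SurvivalDataset",
    "CategorizedVariable",
    "FoldAssignment",
    "load_dataset",
    "stratified_folds",
    "nelson_aalen_cumhaz",
    "martingale_residuals",
    "kaplan_meier",
    "event_fraction",
    "n_bins",
    "categorize_equal_width",
]


class ValidationError(ValueError):
    """Raised when input data violate the survival-data invariants."""


@dataclass(frozen=True)
class SurvivalDataset:
    """Feature matrix with right-censored survival outcome.

    Invariants: strictly positive times, event indicators in {0, 1}, no
    missing entries, unique feature names, consistent shapes.
    """

    features: np.ndarray
    feature_names: tuple
    time: np.ndarray
    event: np.ndarray

    def __post_init__(self) -> None:
        X = np.asarray(self.features, dtype=float)
        t = np.asarray(self.time, dtype=float)
        e = np.asarray(self.event, dtype=float)
        names = tuple(str(f) for f in self.feature_names)
        if X.ndim != 2:
            raise ValidationError("features must be a 2-d matrix")
        n, p = X.shape
        if len(names) != p:
            raise ValidationError("feature_names length must equal number of columns")
        if len(set(names)) != p:
            raise ValidationError("feature names must be unique")
        if t.shape != (n,) or e.shape != (n,):
            raise ValidationError("time and event must have one entry per row")
        if not np.all(np.isfinite(X)):
            bad = np.argwhere(~np.isfinite(X))[0]
            raise ValidationError(
                f"non-finite feature value in column '{names[bad[1]]}', row {bad[0]}"
            )
        if np.any(~np.isfinite(t)) or np.any(t <= 0):
            row = int(np.argmax(~np.isfinite(t) | (t <= 0)))
            raise ValidationError(f"times must be strictly positive (row {row})")
        if np.any(~np.isin(e, (0.0, 1.0))):
            row = int(np.argmax(~np.isin(e, (0.0, 1.0))))
            raise ValidationError(f"event values must be 0 or 1 (row {row})")
        object.__setattr__(self, "features", X)
        object.__setattr__(self, "feature_names", names)
        object.__setattr__(self, "time", t)
        object.__setattr__(self, "event", e.astype(int))

    @property
    def n(self) -> int:
        return self.features.shape[0]

    @property
    def p(self) -> int:
        return self.features.shape[1]

    def subset(self, rows) -> "SurvivalDataset":
        """Row subset (e.g. one CV fold), preserving feature order."""
        rows = np.asarray(rows)
        return SurvivalDataset(
            self.features[rows], self.feature_names, self.time[rows], self.event[rows]
        )

    def select_features(self, names) -> "SurvivalDataset":
        idx = [self.feature_names.index(str(f)) for f in names]
        return SurvivalDataset(
            self.features[:, idx],
            tuple(self.feature_names[i] for i in idx),
            self.time,
            self.event,
        )

    def to_frame(self, time_col: str = "time", event_col: str = "event") -> pd.DataFrame:
        df = pd.DataFrame(self.features, columns=list(self.feature_names))
        df.insert(0, event_col, self.event)
        df.insert(0, time_col, self.time)
        return df


@dataclass(frozen=True)
class CategorizedVariable:
    """Equal-width categorization of a continuous variable into q bins."""

    codes: np.ndarray
    q: int
    bin_edges: np.ndarray

    def __post_init__(self) -> None:
        codes = np.asarray(self.codes, dtype=int)
        edges = np.asarray(self.bin_edges, dtype=float)
        if self.q < 2:
            raise ValidationError("q must be at least 2")
        if edges.shape != (self.q + 1,) or np.any(np.diff(edges) <= 0):
            raise ValidationError("bin_edges must be q+1 strictly increasing values")
        if np.any(codes < 1) or np.any(codes > self.q):
            raise ValidationError("codes must lie in 1..q")
        object.__setattr__(self, "codes", codes)
        object.__setattr__(self, "bin_edges", edges)


@dataclass(frozen=True)
class FoldAssignment:
    """Disjoint, exhaustive test-index sets of a k-fold split."""

    k: int
    test_indices: tuple

    def __post_init__(self) -> None:
        sets = [np.asarray(ix, dtype=int) for ix in self.test_indices]
        if len(sets) != self.k:
            raise ValidationError("need exactly k test-index sets")
        flat = np.concatenate(sets) if sets else np.array([], dtype=int)
        if len(np.unique(flat)) != len(flat):
            raise ValidationError("folds must be disjoint")
        object.__setattr__(self, "test_indices", tuple(sets))

    def splits(self):
        """Yield (train_indices, test_indices) pairs."""
        all_idx = np.concatenate(self.test_indices)
        for test in self.test_indices:
            yield np.setdiff1d(all_idx, test), test


def load_dataset(
    path, time_col: str, event_col: str, delimiter: str = ","
) -> SurvivalDataset:
    """Read a delimited text file into a validated :class:`SurvivalDataset`.

    The file needs a header row; all columns other than ``time_col`` and
    ``event_col`` are treated as (numeric) features, in file order.
    """
    df = pd.read_csv(path, delimiter=delimiter)
    for col in (time_col, event_col):
        if col not in df.columns:
            raise ValidationError(f"column '{col}' not found in {path}")
    feat = df.drop(columns=[time_col, event_col])
    for col in feat.columns:
        if not pd.api.types.is_numeric_dtype(feat[col]):
            raise ValidationError(f"feature column '{col}' is not numeric")
    return SurvivalDataset(
        feat.to_numpy(dtype=float),
        tuple(feat.columns),
        df[time_col].to_numpy(dtype=float),
        df[event_col].to_numpy(dtype=float),
    )


def stratified_folds(dataset: SurvivalDataset, k: int, seed: int) -> FoldAssignment:
    """Event-stratified k-fold assignment.

    Each stratum (event = 0/1) is shuffled with the seed and dealt
    round-robin, so per-fold event counts deviate from perfect
    proportionality by at most one.
    """
    if k < 2:
        raise ValueError("k must be at least 2")
    rng = np.random.default_rng(seed)
    folds = [[] for _ in range(k)]
    offset = 0
    for value in (1, 0):
        members = np.flatnonzero(dataset.event == value)
        if members.size < k:
            warnings.warn(
                f"stratum event={value} has fewer members ({members.size}) than folds ({k})",
                stacklevel=2,
            )
        members = rng.permutation(members)
        for i, row in enumerate(members):
            folds[(i + offset) % k].append(row)
        # continue dealing where the previous stratum stopped, balancing sizes
        offset = (offset + members.size) % k
    return FoldAssignment(k, tuple(np.sort(f) for f in folds))


def _event_table(time, event):
    """Unique event times t_j with event counts d_j and at-risk counts r_j."""
    time = np.asarray(time, dtype=float)
    event = np.asarray(event)
    if time.size == 0:
        raise ValueError("empty input")
    etimes = np.unique(time[event == 1])
    d = np.array([np.sum((time == t) & (event == 1)) for t in etimes], dtype=float)
    r = np.array([np.sum(time >= t) for t in etimes], dtype=float)
    return etimes, d, r


def nelson_aalen_cumhaz(time, event) -> StepFunction:
    """Nelson-Aalen estimate of the cumulative hazard.

    H(t) = sum over event times t_j <= t of d_j / r_j.  This equals the
    Breslow baseline of a Cox model fitted without covariates.
    """
    etimes, d, r = _event_table(time, event)
    return StepFunction(etimes, np.cumsum(d / r), value_before=0.0)


def kaplan_meier(time, event) -> StepFunction:
    """Kaplan-Meier product-limit estimate of the survival function.

    S(t) = prod over event times t_j <= t of (1 - d_j / r_j).  Called with
    the flipped indicator ``1 - event`` it estimates the censoring survival
    function G.
    """
    etimes, d, r = _event_table(time, event)
    return StepFunction(etimes, np.cumprod(1.0 - d / r), value_before=1.0)


def martingale_residuals(dataset: SurvivalDataset) -> np.ndarray:
    """Null-model martingale residuals M_i = Delta_i - H(T_i).

    They sum to zero and are bounded above by 1; used as an uncensored
    continuous surrogate for the censored outcome.
    """
    H = nelson_aalen_cumhaz(dataset.time, dataset.event)
    return dataset.event - H(dataset.time)


def event_fraction(dataset: SurvivalDataset) -> float:
    """Relative number of events, n.e / n."""
    return float(np.mean(dataset.event))


def n_bins(n: int) -> int:
    """Bin count for equal-width categorization: q = max(min(floor(n/3), 10), 2)."""
    if n < 1:
        raise ValueError("n must be positive")
    return max(min(n // 3, 10), 2)


def categorize_equal_width(values, q: int) -> CategorizedVariable:
    """Cut the range of ``values`` into q equal-width bins.

    Intervals are left-open/right-closed except the first, which includes the
    minimum; codes run from 1 (lowest bin) to q.
    """
    values = np.asarray(values, dtype=float)
    if q < 2:
        raise ValueError("q must be at least 2")
    lo, hi = float(np.min(values)), float(np.max(values))
    if lo == hi:
        raise ValueError("cannot categorize a constant variable (degenerate range)")
    edges = np.linspace(lo, hi, q + 1)
    # code = 1 + number of interior edges strictly below the value
    codes = 1 + np.searchsorted(edges[1:-1], values, side="left")
    return CategorizedVariable(codes, q, edges)
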