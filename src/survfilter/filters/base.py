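"""Filter score containers and feature rankings.

Every filter method maps a survival data set to one finite score per
feature, with higher scores indicating features worth keeping; the induced
ordering (ties broken by original column index) is the feature ranking.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class FilterScores:
    """Per-feature filter scores, higher is better.

    ``names`` preserve the data set's column order, which also serves as the
    deterministic tie-break when ranking.
    """

    method: str
    names: tuple
    values: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        names = tuple(self.names)
        if values.shape != (len(names),):
            raise ValueError("one score per feature required")
        if not np.all(np.isfinite(values)):
            raise ValueError("filter scores must be finite")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "names", names)

    def __getitem__(self, name: str) -> float:
        return float(self.values[self.names.index(name)])

    def as_series(self) -> pd.Series:
        return pd.Series(self.values, index=list(self.names), name=self.method)


@dataclass(frozen=True)
class FeatureRanking:
    """Feature names ordered best-first, optionally with their scores."""

    method: str
    ordered_names: tuple
    scores: np.ndarray | None = None

    def top(self, k: int) -> tuple:
        return self.ordered_names[:k]

    def __len__(self) -> int:
        return len(self.ordered_names)


def rank_features(scores: FilterScores) -> FeatureRanking:
    """Order features by descending score; ties keep original column order."""
    order = np.argsort(-scores.values, kind="stable")
    return FeatureRanking(
        scores.method,
        tuple(scores.names[i] for i in order),
        scores.values[order],
    )
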