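"""Right-continuous step functions on the time axis.

Carrier type for the nonparametric estimators used throughout the package:
the Nelson-Aalen cumulative hazard H(t), the Kaplan-Meier survival function
S(t) and the censoring survival function G(t).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class StepFunction:
    """A right-continuous step function.

    ``f(t)`` equals ``values[j]`` for the largest knot ``knots[j] <= t`` and
    ``value_before`` for ``t`` below the first knot.
    """

    knots: np.ndarray
    values: np.ndarray
    value_before: float = 0.0

    def __post_init__(self) -> None:
        knots = np.asarray(self.knots, dtype=float)
        values = np.asarray(self.values, dtype=float)
        if knots.ndim != 1 or values.shape != knots.shape:
            raise ValueError("knots and values must be 1-d arrays of equal length")
        if knots.size and np.any(np.diff(knots) <= 0):
            raise ValueError("knots must be strictly increasing")
        object.__setattr__(self, "knots", knots)
        object.__setattr__(self, "values", values)

    def _eval(self, t, side: str):
        t = np.asarray(t, dtype=float)
        if self.knots.size == 0:
            out = np.full(t.shape, self.value_before)
            return out if out.ndim else float(out)
        idx = np.searchsorted(self.knots, t, side=side) - 1
        out = np.where(idx >= 0, self.values[np.clip(idx, 0, None)], self.value_before)
        return out if out.ndim else float(out)

    def __call__(self, t) -> np.ndarray | float:
        """Evaluate at ``t`` (scalar or array), right-continuously."""
        return self._eval(t, "right")

    def left_limit(self, t) -> np.ndarray | float:
        """Evaluate the left limit f(t-): the value just before ``t``."""
        return self._eval(t, "left")

    def to_table(self):
        """Two-column (knot, value) array, serializable as delimited text."""
        return np.column_stack([self.knots, self.values])
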