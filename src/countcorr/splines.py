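"""Natural cubic spline design basis.

Truncated-power natural cubic basis with the usual epidemiological knot
convention: boundary knots at the data range, interior knots at equally
spaced quantiles, and ``df`` columns excluding the intercept (so ``df - 1``
interior knots).  The basis is linear beyond the boundary knots.  Inputs are
affinely standardised to [0, 1] internally, which keeps the truncated cubes
well conditioned for arguments like day indices in the thousands.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["NaturalSpline"]


@dataclass
class NaturalSpline:
    """Natural cubic spline basis fitted on a sample, evaluable at new points."""

    knots: np.ndarray  # standardised, includes boundary
    lo: float
    hi: float

    @classmethod
    def fit(cls, x, df: int) -> "NaturalSpline":
        if df < 1:
            raise ValueError("df must be >= 1")
        x = np.asarray(x, float)
        lo, hi = float(np.min(x)), float(np.max(x))
        if hi <= lo:
            raise ValueError("x must contain at least two distinct values")
        z = (x - lo) / (hi - lo)
        if df == 1:
            knots = np.array([0.0, 1.0])
        else:
            probs = np.linspace(0, 1, df + 1)[1:-1]
            interior = np.quantile(z, probs)
            knots = np.concatenate([[0.0], interior, [1.0]])
        if len(np.unique(knots)) != len(knots):
            raise ValueError("duplicate knots; reduce df or deduplicate x")
        return cls(knots=knots, lo=lo, hi=hi)

    @property
    def df(self) -> int:
        return len(self.knots) - 1

    def in_range(self, x) -> np.ndarray:
        x = np.atleast_1d(np.asarray(x, float))
        return (x >= self.lo - 1e-9) & (x <= self.hi + 1e-9)

    def basis(self, x) -> np.ndarray:
        """Design columns (no intercept): shape (len(x), df)."""
        z = (np.atleast_1d(np.asarray(x, float)) - self.lo) / (self.hi - self.lo)
        k = self.knots
        K = len(k)
        out = np.empty((len(z), K - 1))
        out[:, 0] = z
        if K > 2:

            def d(j):
                return (np.maximum(z - k[j], 0) ** 3 - np.maximum(z - k[-1], 0) ** 3) / (k[-1] - k[j])

            dlast = d(K - 2)
            for j in range(K - 2):
                out[:, j + 1] = d(j) - dlast
        return out
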