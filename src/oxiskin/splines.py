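"""Restricted cubic spline (natural spline) bases, Harrell parameterisation.

A restricted cubic spline with k knots t_1 < ... < t_k is a cubic spline
constrained to be linear beyond the boundary knots.  The basis has k - 1
columns: x itself plus k - 2 nonlinear terms

    C_j(x) = [ (x - t_j)_+^3
               - (x - t_{k-1})_+^3 (t_k - t_j) / (t_k - t_{k-1})
               + (x - t_k)_+^3 (t_{k-1} - t_j) / (t_k - t_{k-1}) ]
             / (t_k - t_1)^2 ,   j = 1 .. k-2,

which are zero below t_1 and linear above t_k, with continuous first and
second derivatives everywhere.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["SplineBasis", "rcs_basis", "default_knots", "HARRELL_QUANTILES"]

#: Harrell's recommended knot quantiles by knot count.
HARRELL_QUANTILES: dict[int, tuple[float, ...]] = {
    3: (0.10, 0.50, 0.90),
    4: (0.05, 0.35, 0.65, 0.95),
    5: (0.05, 0.275, 0.50, 0.725, 0.95),
    6: (0.05, 0.23, 0.41, 0.59, 0.77, 0.95),
    7: (0.025, 0.1833, 0.3417, 0.50, 0.6583, 0.8167, 0.975),
}


def default_knots(x, n_knots: int = 4) -> np.ndarray:
    """Knot locations at Harrell's recommended sample quantiles."""
    if n_knots not in HARRELL_QUANTILES:
        raise ValueError(f"n_knots must be one of {sorted(HARRELL_QUANTILES)}")
    x = np.asarray(x, dtype=float)
    knots = np.quantile(x, HARRELL_QUANTILES[n_knots])
    if np.any(np.diff(knots) <= 0):
        raise ValueError(
            "tied quantiles collapse knots; supply knots explicitly or "
            "reduce n_knots")
    return knots


def rcs_basis(x, knots) -> np.ndarray:
    """Restricted cubic spline basis matrix, shape (n, len(knots) - 1).

    Column 0 is x; the remaining columns are the restricted cubic terms.
    """
    knots = np.asarray(knots, dtype=float)
    if knots.ndim != 1 or len(knots) < 3:
        raise ValueError("at least 3 strictly increasing knots are required")
    if np.any(np.diff(knots) <= 0):
        raise ValueError("knots must be strictly increasing")
    x = np.asarray(x, dtype=float)
    k = len(knots)
    t1, tkm1, tk = knots[0], knots[-2], knots[-1]
    scale = (tk - t1) ** 2

    def plus3(u):
        return np.clip(u, 0.0, None) ** 3

    cols = [x]
    for j in range(k - 2):
        tj = knots[j]
        c = (plus3(x - tj)
             - plus3(x - tkm1) * (tk - tj) / (tk - tkm1)
             + plus3(x - tk) * (tkm1 - tj) / (tk - tkm1)) / scale
        cols.append(c)
    return np.column_stack(cols)


@dataclass(frozen=True)
class SplineBasis:
    """A fitted restricted-cubic-spline transform for one covariate."""

    knots: np.ndarray = field()

    def __post_init__(self) -> None:
        knots = np.asarray(self.knots, dtype=float)
        if len(knots) < 3 or np.any(np.diff(knots) <= 0):
            raise ValueError("knots must be >=3 and strictly increasing")
        object.__setattr__(self, "knots", knots)

    @property
    def n_basis(self) -> int:
        return len(self.knots) - 1

    def transform(self, x) -> np.ndarray:
        return rcs_basis(x, self.knots)

    @classmethod
    def from_data(cls, x, n_knots: int = 4) -> "SplineBasis":
        return cls(default_knots(x, n_knots))
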