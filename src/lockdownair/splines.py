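"""Natural cubic spline basis for the stringency exposure-response term.

The non-linear effect of the Stringency Index (SI) is expanded in a natural
cubic spline with four degrees of freedom: three interior knots at the 25,
50 and 75% quantiles of the pooled SI distribution plus boundary knots at 0
and the maximum observed SI.  "Natural" means the basis is constrained to be
linear beyond the boundary knots (zero second derivative there).

The model carries no intercept: no pollution change is expected while no
policy response is in place.  That is operationalised by *anchoring* the
basis at SI = 0 — every basis column has its value at 0 subtracted — so any
fitted curve passes exactly through (0, 0).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import BSpline

DEGREES_OF_FREEDOM = 4
_N_INTERIOR = 3


def _full_knots(interior: np.ndarray, boundary: tuple[float, float]) -> np.ndarray:
    lo, hi = boundary
    return np.concatenate([[lo] * 4, interior, [hi] * 4])


def _bspline_columns(t: np.ndarray) -> list[BSpline]:
    n_basis = len(t) - 4
    cols = []
    for j in range(n_basis):
        c = np.zeros(n_basis)
        c[j] = 1.0
        cols.append(BSpline(t, c, 3, extrapolate=False))
    return cols


def _design(x: np.ndarray, cols: list[BSpline], boundary: tuple[float, float]) -> np.ndarray:
    """Evaluate the cubic B-spline columns with linear (natural) extrapolation."""
    lo, hi = boundary
    x = np.asarray(x, dtype=float)
    inside = np.clip(x, lo, hi)
    out = np.column_stack([np.nan_to_num(c(inside), nan=0.0) for c in cols])
    below, above = x < lo, x > hi
    for mask, edge in ((below, lo), (above, hi)):
        if mask.any():
            val = np.array([float(np.nan_to_num(c(edge), nan=0.0)) for c in cols])
            der = np.array([float(np.nan_to_num(c.derivative()(edge), nan=0.0)) for c in cols])
            out[mask] = val[None, :] + (x[mask] - edge)[:, None] * der[None, :]
    return out


@dataclass(frozen=True)
class SplineSpec:
    """Specification of the anchored natural spline basis for SI.

    Attributes
    ----------
    interior_knots : three strictly increasing SI values inside the boundary.
    boundary : (0, max observed SI) knot pair.
    anchored_at_zero : subtract the basis row at SI = 0 (removes the
        intercept direction; default True).
    """

    interior_knots: tuple[float, float, float]
    boundary: tuple[float, float]
    anchored_at_zero: bool = True
    degrees_of_freedom: int = field(default=DEGREES_OF_FREEDOM, init=False)

    def __post_init__(self) -> None:
        lo, hi = self.boundary
        k = np.asarray(self.interior_knots, dtype=float)
        if len(k) != _N_INTERIOR:
            raise ValueError("exactly three interior knots required")
        if not (np.all(np.diff(k) > 0) and k[0] > lo and k[-1] < hi):
            raise ValueError("interior knots must be strictly increasing inside the boundary")
        if not lo < hi:
            raise ValueError("boundary knots must be ordered")

    @classmethod
    def from_si_values(
        cls,
        si_values: np.ndarray,
        boundary: tuple[float, float] | None = None,
        anchored_at_zero: bool = True,
    ) -> "SplineSpec":
        """Knots from the pooled SI distribution across all city-days.

        Interior knots sit at the 25/50/75% quantiles; the boundary defaults
        to [0, max observed SI].  Step-like SI trajectories can produce tied
        quantiles; ties are repaired by falling back to evenly indexed
        distinct observed values strictly inside the boundary.
        """
        x = np.asarray(si_values, dtype=float).ravel()
        if np.unique(x).size < 5:
            raise ValueError("need at least 5 distinct SI values to place knots")
        lo, hi = boundary if boundary is not None else (0.0, float(np.max(x)))
        knots = np.quantile(x, [0.25, 0.5, 0.75])
        ok = np.all(np.diff(knots) > 0) and knots[0] > lo and knots[-1] < hi
        if not ok:
            interior = np.unique(x[(x > lo) & (x < hi)])
            if interior.size >= _N_INTERIOR:
                idx = np.round(np.linspace(0, interior.size - 1, _N_INTERIOR + 2)).astype(int)
                knots = interior[idx[1:-1]]
            if interior.size < _N_INTERIOR or not np.all(np.diff(knots) > 0):
                knots = lo + (hi - lo) * np.array([0.25, 0.5, 0.75])
        return cls(tuple(float(v) for v in knots), (float(lo), float(hi)), anchored_at_zero)

    def _natural_transform(self) -> tuple[list[BSpline], np.ndarray]:
        """B-spline columns (dropping the intercept-like first one) and the
        null-space projector of the boundary second-derivative constraints."""
        t = _full_knots(np.asarray(self.interior_knots, dtype=float), self.boundary)
        cols = _bspline_columns(t)[1:]  # drop first column: no-intercept basis
        lo, hi = self.boundary
        constraint = np.array(
            [[float(np.nan_to_num(c.derivative(2)(b), nan=0.0)) for c in cols] for b in (lo, hi)]
        )
        q, _ = np.linalg.qr(constraint.T, mode="complete")
        return cols, q[:, 2:]

    def basis(self, si_values: np.ndarray) -> np.ndarray:
        """Evaluate the (n, 4) anchored natural spline basis at SI values."""
        x = np.atleast_1d(np.asarray(si_values, dtype=float))
        cols, nullspace = self._natural_transform()
        b = _design(x, cols, self.boundary) @ nullspace
        if self.anchored_at_zero:
            b0 = _design(np.array([0.0]), cols, self.boundary) @ nullspace
            b = b - b0
        return b


def build_spline_basis(si_values: np.ndarray, spec: SplineSpec) -> np.ndarray:
    """Anchored natural-spline design matrix (n x 4) for given SI values."""
    return spec.basis(si_values)
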