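"""Covariate bases for test-day models.

Three families of covariates enter the random-regression test-day model:

* normalized Legendre polynomials of days in milk (DIM), used for the random
  genetic and permanent-environment regressions;
* natural cubic splines of DIM, used for the fixed lactation-stage curves
  (one curve per kidding-age class and per kidding-period class);
* a natural cubic spline of gestation stage, zero before day 31 of gestation
  and held constant after day 100.

The DIM range modeled is 7..270 inclusive (264 days).  DIM is mapped to the
standardized coordinate ``x(d) = 2 (d - 7) / (270 - 7) - 1`` in [-1, 1]
before evaluating Legendre polynomials.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.polynomial import legendre as npleg

DIM_FIRST = 7
DIM_LAST = 270

#: knots of the fixed lactation-stage spline curves
LACTATION_KNOTS = (7, 20, 50, 110, 190, 270)
#: knots of the gestation-stage spline
GESTATION_KNOTS = (31, 53, 76, 100)
GESTATION_FREE_MAX = 30  # no gestation effect at or below this many days
GESTATION_PLATEAU = 100  # effect constant beyond this many days


@dataclass(frozen=True)
class DimGrid:
    """Ordered integer DIM grid within [7, 270]."""

    days: np.ndarray = field(
        default_factory=lambda: np.arange(DIM_FIRST, DIM_LAST + 1)
    )

    def __post_init__(self):
        d = np.asarray(self.days, dtype=int)
        if d.size == 0:
            raise ValueError("empty DIM grid")
        if np.any(np.diff(d) <= 0):
            raise ValueError("DIM grid must be strictly increasing")
        if d[0] < DIM_FIRST or d[-1] > DIM_LAST:
            raise ValueError(f"DIM grid must lie within [{DIM_FIRST}, {DIM_LAST}]")
        object.__setattr__(self, "days", d)

    def __len__(self) -> int:
        return self.days.size

    @property
    def x(self) -> np.ndarray:
        """Standardized coordinate of each day, in [-1, 1]."""
        return dim_to_x(self.days)


def full_grid() -> DimGrid:
    """The full 264-day grid 7..270."""
    return DimGrid()


def dim_to_x(d) -> np.ndarray:
    d = np.asarray(d, dtype=float)
    return 2.0 * (d - DIM_FIRST) / (DIM_LAST - DIM_FIRST) - 1.0


@dataclass(frozen=True)
class LegendreBasis:
    """Normalized Legendre basis evaluated on a DIM grid.

    Column ``o`` holds phi_o(x(d)) = sqrt((2 o + 1) / 2) * P_o(x(d)), the
    normalization standard in covariance-function work (columns orthonormal
    under the continuous inner product on [-1, 1]).
    """

    order: int
    grid: DimGrid
    matrix: np.ndarray

    @property
    def n_coef(self) -> int:
        return self.order + 1


def legendre_matrix(order: int, d) -> np.ndarray:
    """Evaluate the normalized Legendre columns phi_0..phi_order at DIM ``d``."""
    if not float(order).is_integer() or order < 0:
        raise ValueError("order must be a non-negative integer")
    order = int(order)
    if order > 10:
        raise ValueError("order above 10 is not supported")
    x = dim_to_x(d)
    # columns P_0..P_order, then normalize
    V = npleg.legvander(x, order)
    norms = np.sqrt((2.0 * np.arange(order + 1) + 1.0) / 2.0)
    return V * norms


def legendre_basis(order: int, grid: DimGrid | None = None) -> LegendreBasis:
    """Build the normalized Legendre basis of a given order on a DIM grid."""
    if grid is None:
        grid = full_grid()
    return LegendreBasis(order=int(order), grid=grid,
                         matrix=legendre_matrix(order, grid.days))


@dataclass(frozen=True)
class SplineBasis:
    """Natural cubic spline basis: as many columns as knots.

    Parameterization: the reduced truncated-power ("natural") basis of
    Hastie-Tibshirani-Friedman, on inputs rescaled to [0, 1] over the knot
    span for conditioning.  Columns 0 and 1 are the constant and linear
    terms; beyond the boundary knots every column continues linearly, so the
    natural (zero second derivative) condition holds at and outside the
    boundaries.  Any natural cubic spline on these knots is an exact linear
    combination of the columns.
    """

    knots: np.ndarray
    matrix: np.ndarray

    @property
    def n_basis(self) -> int:
        return self.knots.size


def natural_spline_matrix(knots, eval_points) -> np.ndarray:
    knots = np.asarray(knots, dtype=float)
    if knots.size < 2:
        raise ValueError("need at least 2 knots")
    if np.unique(knots).size != knots.size:
        raise ValueError("duplicate knots")
    knots = np.sort(knots)
    x = np.asarray(eval_points, dtype=float)
    span = knots[-1] - knots[0]
    t = (x - knots[0]) / span
    k = (knots - knots[0]) / span
    K = k.size

    def dfun(j, tt):
        # (t - k_j)_+^3 - (t - k_{K-1})_+^3, divided by (k_{K-1} - k_j)
        return (np.clip(tt - k[j], 0.0, None) ** 3
                - np.clip(tt - k[-1], 0.0, None) ** 3) / (k[-1] - k[j])

    cols = [np.ones_like(t), t]
    dK2 = dfun(K - 2, t)
    for j in range(K - 2):
        cols.append(dfun(j, t) - dK2)
    return np.column_stack(cols)


def natural_spline_basis(knots, eval_points) -> SplineBasis:
    """Natural cubic spline basis with one column per knot."""
    knots = np.sort(np.asarray(knots, dtype=float))
    return SplineBasis(knots=knots,
                       matrix=natural_spline_matrix(knots, eval_points))


def gestation_covariates(g) -> np.ndarray:
    """Gestation-stage covariate rows for gestation day(s) ``g``.

    Returns a 4-column array (one row per element of ``g``): all zeros for
    g <= 30 (g = 0 means not pregnant, and early gestation is assumed to have
    no effect on production), the natural-spline row on knots {31, 53, 76,
    100} for 31 <= g <= 100, and the g = 100 row for any later day (the
    effect is held constant once records become scarce).  Note the basis row
    at g = 31 is nonzero, so the fitted effect may step at the 30 -> 31
    boundary; the model tolerates this discontinuity.
    """
    g = np.asarray(g, dtype=float)
    scalar = g.ndim == 0
    g = np.atleast_1d(g)
    if np.any(g < 0):
        raise ValueError("gestation days must be >= 0")
    g_eval = np.clip(g, None, GESTATION_PLATEAU)
    M = natural_spline_matrix(GESTATION_KNOTS, g_eval)
    M[g <= GESTATION_FREE_MAX] = 0.0
    return M[0] if scalar else M


def lactation_stage_covariates(d) -> np.ndarray:
    """Fixed-curve natural-spline rows on the printed six DIM knots."""
    return natural_spline_matrix(LACTATION_KNOTS, d)
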