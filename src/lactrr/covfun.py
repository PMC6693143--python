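"""Covariance functions over DIM and heritability/correlation summaries.

Fitted coefficient covariances are mapped onto the day scale by congruence
with the basis: ``G = Q K_g Q'`` on the full 264-day grid (7..270), and the
same for the permanent-environment surface ``W``.  The phenotypic surface
adds the residual variance of each day's residual DIM class on the
diagonal: ``P = G + W + diag(sigma2_e(class(d)))``.  Daily heritability is
``G[d,d] / P[d,d]``; whole-lactation variances contract the surfaces with a
summation vector of ones, ``g_wl = s' G s``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .basis import DimGrid, full_grid
from .prep import residual_class


@dataclass
class CovarianceFunction:
    """Genetic, permanent-environment and phenotypic surfaces over DIM."""

    grid: DimGrid
    G: np.ndarray
    W: np.ndarray
    P: np.ndarray
    residual_by_day: np.ndarray


def covariance_function(k_g, basis_matrix, residual, k_p=None,
                        grid: DimGrid | None = None) -> CovarianceFunction:
    """Build the day-scale covariance surfaces from coefficient covariances.

    ``basis_matrix`` holds the basis values on the grid (|grid| x k); for a
    reduced model pass the eigenfunction matrix.  ``residual`` is either the
    9-class vector (mapped to days through the DIM classes) or a full
    per-day vector.
    """
    if grid is None:
        grid = full_grid()
    Q = np.asarray(basis_matrix, dtype=float)
    if Q.shape[0] != len(grid):
        raise ValueError("basis rows must cover the grid")
    k_g = np.atleast_2d(k_g)
    if Q.shape[1] != k_g.shape[0]:
        raise ValueError("basis/covariance dimension mismatch")
    G = Q @ k_g @ Q.T
    W = np.zeros_like(G) if k_p is None else Q @ np.atleast_2d(k_p) @ Q.T
    residual = np.asarray(residual, dtype=float)
    if residual.size == len(grid):
        r_day = residual
    else:
        r_day = residual[residual_class(grid.days) - 1]
    P = G + W + np.diag(r_day)
    return CovarianceFunction(grid=grid, G=G, W=W, P=P, residual_by_day=r_day)


def daily_heritability(cf: CovarianceFunction) -> np.ndarray:
    """h2(d) = G[d,d] / P[d,d] for every day of the grid."""
    pd_ = np.diag(cf.P)
    if np.any(pd_ <= 0):
        raise ValueError("zero phenotypic variance")
    return np.diag(cf.G) / pd_


def genetic_correlation(cf: CovarianceFunction, d1: int, d2: int) -> float:
    """Genetic correlation between two DIM."""
    days = cf.grid.days
    i = int(np.flatnonzero(days == d1)[0]) if d1 in days else None
    j = int(np.flatnonzero(days == d2)[0]) if d2 in days else None
    if i is None or j is None:
        raise ValueError("day not on grid")
    den = cf.G[i, i] * cf.G[j, j]
    if den <= 0:
        raise ValueError("zero genetic variance")
    return float(cf.G[i, j] / np.sqrt(den))


def genetic_correlation_slice(cf: CovarianceFunction, d_ref: int) -> np.ndarray:
    """Correlations of a reference day with every day of the grid."""
    days = cf.grid.days
    i = int(np.flatnonzero(days == d_ref)[0])
    diag = np.diag(cf.G)
    if np.any(diag <= 0):
        raise ValueError("zero genetic variance on the grid")
    return cf.G[i] / np.sqrt(diag[i] * diag)


def whole_lactation_heritability(cf: CovarianceFunction):
    """(g_wl, w_wl, p_wl, h_wl): s'Gs etc. with s a vector of ones.

    Residual covariance between days is zero (diagonal R), so p_wl adds
    only the summed daily residual variances.
    """
    if len(cf.grid) != 264:
        raise ValueError("whole-lactation summary needs the full 7..270 grid")
    s = np.ones(len(cf.grid))
    g = float(s @ cf.G @ s)
    w = float(s @ cf.W @ s)
    p = float(s @ cf.P @ s)
    return g, w, p, g / p


def record_weighted_mse(residual, class_counts) -> float:
    """Record-count-weighted mean of the per-class residual variances."""
    residual = np.asarray(residual, float)
    n = np.asarray(class_counts, float)
    return float(np.dot(residual, n) / n.sum())


def coefficient_heritability(k_g, k_p, mse: float) -> np.ndarray:
    """Per-coefficient heritability h_b[o] = g_oo / (g_oo + p_oo + mse)."""
    if mse < 0:
        raise ValueError("mse must be >= 0")
    g = np.diag(np.atleast_2d(k_g)).astype(float)
    p = (np.zeros_like(g) if k_p is None
         else np.diag(np.atleast_2d(k_p)).astype(float))
    den = g + p + mse
    if np.any(den == 0):
        raise ValueError("zero denominator in coefficient heritability")
    return g / den
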