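"""Eigen decomposition of the genetic coefficient covariance and rank
reduction.

The coefficient covariance of the full model is eigendecomposed; the
leading eigenvectors, mapped through the Legendre basis, give
*eigenfunctions* over DIM.  The first eigenfunction is close to constant
(average production level), the second crosses zero once (persistency).  A
sign convention makes the second eigenfunction negative in early lactation
and positive at the end; the first is oriented positive on average.  A
rank-z reduced model regresses the genetic and permanent-environment
effects on the first z eigenfunctions with a diagonal coefficient
covariance, so the level and persistency coefficients are uncorrelated by
construction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .basis import LegendreBasis, full_grid, legendre_basis


@dataclass
class EigenDecomposition:
    """Eigenvalues (descending), eigenvectors (columns) and variance shares."""

    values: np.ndarray
    vectors: np.ndarray
    shares: np.ndarray     # percent of total genetic variance

    def reconstruct(self) -> np.ndarray:
        return (self.vectors * self.values) @ self.vectors.T


@dataclass
class ReducedSpec:
    """Rank-z reduced parameterization built from the eigen decomposition."""

    rank: int
    eigenfunctions: np.ndarray       # |grid| x z
    vectors: np.ndarray              # k x z coefficient-space directions
    coefficient_variances: np.ndarray  # diag initializer (lambda_1..lambda_z)
    diagonal: bool = True

    @property
    def genetic_covariance(self) -> np.ndarray:
        """Coefficient covariance under the diagonal constraint (off-diag 0)."""
        return np.diag(self.coefficient_variances)


def eigendecompose(k_g) -> EigenDecomposition:
    """Eigen decomposition with descending eigenvalues and % variance shares."""
    K = np.atleast_2d(np.asarray(k_g, dtype=float))
    if not np.allclose(K, K.T, atol=1e-8):
        raise ValueError("covariance matrix must be symmetric")
    w, V = np.linalg.eigh(0.5 * (K + K.T))
    order = np.argsort(w)[::-1]
    w, V = w[order], V[:, order]
    if w.min() < -1e-10 * max(abs(w).max(), 1e-12):
        raise ValueError("covariance matrix must be positive semi-definite")
    total = w.sum()
    shares = 100.0 * w / total if total > 0 else np.zeros_like(w)
    return EigenDecomposition(values=w, vectors=V, shares=shares)


def orient_eigenfunctions(decomp: EigenDecomposition,
                          basis: LegendreBasis | np.ndarray | None = None,
                          ) -> EigenDecomposition:
    """Apply the sign convention on the *eigenfunction* scale.

    The second eigenfunction is made negative at DIM 7 and positive at DIM
    270 (multiplying the eigenvector by -1 when needed); the first, and any
    further components, are oriented positive on average.  Deciding on
    eigenfunction values rather than raw eigenvector entries makes the
    convention invariant to the basis normalization.  Idempotent.
    """
    if basis is None:
        basis = legendre_basis(decomp.vectors.shape[0] - 1, full_grid())
    Q = basis.matrix if isinstance(basis, LegendreBasis) else np.asarray(basis)
    chi = Q @ decomp.vectors
    V = decomp.vectors.copy()
    for o in range(V.shape[1]):
        if o == 1:
            if chi[0, o] > 0:
                V[:, o] *= -1.0
                chi[:, o] *= -1.0
            if not (chi[0, o] < 0 < chi[-1, o]):
                warnings.warn(
                    "second eigenfunction has no early-negative/late-positive "
                    "sign pattern on the DIM range", stacklevel=2)
        elif chi[:, o].mean() < 0:
            V[:, o] *= -1.0
            chi[:, o] *= -1.0
    return EigenDecomposition(values=decomp.values.copy(), vectors=V,
                              shares=decomp.shares.copy())


def build_reduced_spec(decomp: EigenDecomposition,
                       basis: LegendreBasis | np.ndarray | None = None,
                       z: int = 2, diagonal: bool = True) -> ReducedSpec:
    """First z eigenfunctions and their (diagonal) coefficient covariance.

    The same eigenfunctions model both the genetic and the
    permanent-environment random regressions of the reduced model.
    """
    k = decomp.vectors.shape[0]
    if not 1 <= z <= k:
        raise ValueError(f"rank must be in [1, {k}]")
    if basis is None:
        basis = legendre_basis(k - 1, full_grid())
    Q = basis.matrix if isinstance(basis, LegendreBasis) else np.asarray(basis)
    oriented = orient_eigenfunctions(decomp, Q) if z >= 2 else decomp
    V = oriented.vectors[:, :z]
    return ReducedSpec(rank=z,
                       eigenfunctions=Q @ V,
                       vectors=V,
                       coefficient_variances=oriented.values[:z].copy(),
                       diagonal=diagonal)
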