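"""Pedigree container and additive-relationship machinery.

The animal model assumes ``Var(a) = A * sigma2_a`` with ``A`` the additive
(numerator) relationship matrix implied by the pedigree.  Mixed-model
equations need ``A^-1``, which is sparse and is assembled directly from the
pedigree by Henderson's rules, with exact inbreeding coefficients from the
Meuwissen-Luo recursion so that matings between relatives are handled
correctly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp

UNKNOWN = 0


@dataclass
class Pedigree:
    """Animal/sire/dam triples, topologically ordered (parents first).

    Ids are arbitrary hashable labels; ``0`` (or ``None``/NaN) marks an
    unknown parent.  Internally animals are indexed 0..n-1 in pedigree order.
    """

    animals: np.ndarray       # ids in order
    sire_idx: np.ndarray      # int index into animals, -1 if unknown
    dam_idx: np.ndarray

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "Pedigree":
        """Build from a DataFrame with columns animal, sire, dam ('0' = unknown)."""
        animals = frame["animal"].to_numpy()
        if len(np.unique(animals)) != len(animals):
            raise ValueError("duplicate animal ids in pedigree")
        pos = {a: i for i, a in enumerate(animals)}

        def idx(col):
            out = np.full(len(animals), -1, dtype=np.int64)
            for i, p in enumerate(frame[col].to_numpy()):
                if p is None or (isinstance(p, float) and np.isnan(p)) or p == UNKNOWN or p == "0":
                    continue
                if p not in pos:
                    raise ValueError(f"parent {p!r} not in pedigree")
                j = pos[p]
                if j >= i:
                    raise ValueError("pedigree not topologically ordered (parent after offspring)")
                out[i] = j
            return out

        return cls(animals=animals, sire_idx=idx("sire"), dam_idx=idx("dam"))

    @classmethod
    def from_records(cls, entries) -> "Pedigree":
        """From (animal, sire, dam) triples; 0/None = unknown parent."""
        frame = pd.DataFrame(entries, columns=["animal", "sire", "dam"])
        return cls.from_frame(frame)

    def __len__(self) -> int:
        return len(self.animals)

    def to_frame(self) -> pd.DataFrame:
        def label(ix):
            return np.where(ix >= 0, self.animals[np.clip(ix, 0, None)], UNKNOWN)
        return pd.DataFrame({
            "animal": self.animals,
            "sire": label(self.sire_idx),
            "dam": label(self.dam_idx),
        })

    def index_of(self, ids) -> np.ndarray:
        pos = {a: i for i, a in enumerate(self.animals)}
        return np.asarray([pos[a] for a in ids], dtype=np.int64)


def inbreeding(ped: Pedigree) -> np.ndarray:
    """Inbreeding coefficients by the Meuwissen-Luo (1992) recursion.

    For each animal the diagonal of A is accumulated as ``A_ii = sum_j
    L_ij^2 d_j`` by walking its ancestor set, where L is the Cholesky-like
    factor of A and d_j the Mendelian-sampling variances; no dense A is
    formed.  Returns F with ``F[i] = A[i, i] - 1``.
    """
    n = len(ped)
    s, d = ped.sire_idx, ped.dam_idx
    F = np.zeros(n)
    D = np.zeros(n)
    for i in range(n):
        si, di = s[i], d[i]
        if si < 0 and di < 0:
            D[i] = 1.0
            F[i] = 0.0
            continue
        if si < 0 or di < 0:
            known = si if si >= 0 else di
            D[i] = 0.75 - 0.25 * F[known]
        else:
            D[i] = 0.5 - 0.25 * (F[si] + F[di])
        # descend through ancestors accumulating L_ij
        L = {i: 1.0}
        aii = 0.0
        for j in range(i, -1, -1):
            lj = L.pop(j, 0.0)
            if lj == 0.0:
                continue
            aii += lj * lj * D[j]
            if s[j] >= 0:
                L[s[j]] = L.get(s[j], 0.0) + 0.5 * lj
            if d[j] >= 0:
                L[d[j]] = L.get(d[j], 0.0) + 0.5 * lj
        F[i] = aii - 1.0
    return F


def mendelian_variances(ped: Pedigree, F: np.ndarray | None = None) -> np.ndarray:
    """Within-family (Mendelian sampling) variance scalars d_i."""
    if F is None:
        F = inbreeding(ped)
    s, d = ped.sire_idx, ped.dam_idx
    D = np.ones(len(ped))
    both = (s >= 0) & (d >= 0)
    D[both] = 0.5 - 0.25 * (F[s[both]] + F[d[both]])
    one_s = (s >= 0) & (d < 0)
    D[one_s] = 0.75 - 0.25 * F[s[one_s]]
    one_d = (s < 0) & (d >= 0)
    D[one_d] = 0.75 - 0.25 * F[d[one_d]]
    return D


def relationship_matrix(ped: Pedigree) -> np.ndarray:
    """Dense additive relationship matrix A by the tabular method.

    Quadratic memory; intended for oracles and small pedigrees.
    """
    n = len(ped)
    A = np.zeros((n, n))
    s, d = ped.sire_idx, ped.dam_idx
    for i in range(n):
        asd = A[s[i], d[i]] if (s[i] >= 0 and d[i] >= 0) else 0.0
        A[i, i] = 1.0 + 0.5 * asd
        for j in range(i):
            aij = 0.0
            if s[i] >= 0:
                aij += 0.5 * A[j, s[i]]
            if d[i] >= 0:
                aij += 0.5 * A[j, d[i]]
            A[i, j] = A[j, i] = aij
    return A


def relationship_inverse(ped: Pedigree) -> tuple[sp.csr_matrix, float]:
    """Sparse A^-1 by Henderson's rules with exact inbreeding.

    Returns ``(A_inv, logdet_A)``; the log-determinant falls out of the
    Mendelian variances (``log|A| = sum log d_i``) and is needed by the REML
    log-likelihood.
    """
    n = len(ped)
    F = inbreeding(ped)
    D = mendelian_variances(ped, F)
    s, d = ped.sire_idx, ped.dam_idx
    rows, cols, vals = [], [], []

    def add(i, j, v):
        rows.append(i); cols.append(j); vals.append(v)

    for i in range(n):
        inv_d = 1.0 / D[i]
        parents = [p for p in (s[i], d[i]) if p >= 0]
        add(i, i, inv_d)
        for p in parents:
            add(i, p, -0.5 * inv_d)
            add(p, i, -0.5 * inv_d)
        for p in parents:
            for q in parents:
                add(p, q, 0.25 * inv_d)
    A_inv = sp.csr_matrix(
        sp.coo_matrix((vals, (rows, cols)), shape=(n, n))
    )
    return A_inv, float(np.sum(np.log(D)))
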