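"""Daily EBV curves and derived breeding-value summaries.

An animal's random-regression solution is a coefficient vector; its daily
genetic contribution is the corresponding linear combination of basis
columns.  Two scalar summaries are used for selection:

* ``SUM``: the whole-lactation level, the sum of daily EBVs over DIM
  7..270;
* ``PERS``: persistency, the cumulative deviation of the daily genetic
  contribution from DIM 40 to DIM 240 relative to an animal with the same
  contribution at DIM 40, i.e. ``sum_{d=40}^{240} (u(d) - u(40))`` (201
  daily terms).  A flat genetic curve has PERS = 0; positive PERS means a
  flatter-than-average (more persistent) lactation.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .basis import DIM_FIRST, DIM_LAST

PERS_FIRST = 40
PERS_LAST = 240


def daily_curve(coeffs, basis_matrix) -> np.ndarray:
    """Daily EBV curve u(d) = sum_o coeff_o * basis_o(d) on the grid."""
    coeffs = np.asarray(coeffs, dtype=float)
    Q = np.asarray(basis_matrix, dtype=float)
    if Q.shape[-1] != coeffs.shape[-1]:
        raise ValueError("coefficient/basis dimension mismatch")
    return Q @ coeffs if coeffs.ndim == 1 else coeffs @ Q.T


def sum_ebv(curve) -> float | np.ndarray:
    """Whole-lactation level: sum of daily EBVs over the full grid."""
    curve = np.asarray(curve, dtype=float)
    if curve.shape[-1] != DIM_LAST - DIM_FIRST + 1:
        raise ValueError("curve must cover the full DIM grid 7..270")
    return curve.sum(axis=-1)


def persistency_ebv(curve) -> float | np.ndarray:
    """PERS: cumulative deviation from the DIM-40 level over DIM 40..240."""
    curve = np.asarray(curve, dtype=float)
    if curve.shape[-1] < PERS_LAST - DIM_FIRST + 1:
        raise ValueError("curve must cover DIM 40..240")
    i0 = PERS_FIRST - DIM_FIRST
    i1 = PERS_LAST - DIM_FIRST
    seg = curve[..., i0:i1 + 1]
    return (seg - seg[..., :1]).sum(axis=-1)


def sd_contribution_curve(eigenvalue: float, eigenfunction) -> dict:
    """Daily contribution of a one-SD change in one reduced coefficient.

    Returns the curve ``sqrt(lambda_o) * chi_o(d)`` plus its summed positive
    and negative parts over DIM and the DIM of any sign changes.
    """
    if eigenvalue < 0:
        raise ValueError("eigenvalue must be >= 0")
    chi = np.asarray(eigenfunction, dtype=float)
    curve = np.sqrt(eigenvalue) * chi
    crossing_days = (DIM_FIRST + np.flatnonzero(np.diff(np.sign(curve)) != 0)
                     ).tolist()
    return {
        "curve": curve,
        "positive_sum": float(curve[curve > 0].sum()),
        "negative_sum": float(curve[curve < 0].sum()),
        "sign_change_days": crossing_days,
    }


def ebv_correlation_table(measures: dict, animals=None) -> pd.DataFrame:
    """Pearson correlations between named per-animal EBV measures.

    ``measures`` maps a name (e.g. "SUM_leg4", "a0_leg4", "PERS_leg4",
    "b1_leg4R2") to a pandas Series indexed by animal id; the table is
    computed on the intersection of the indices (optionally restricted to
    ``animals``, e.g. the sires).
    """
    frame = pd.DataFrame(measures)
    if animals is not None:
        frame = frame.loc[frame.index.intersection(pd.Index(animals))]
    frame = frame.dropna()
    if len(frame) < 2:
        raise ValueError("need at least two animals common to all measures")
    sd = frame.std()
    zero = sd[sd == 0].index.tolist()
    if zero:
        raise ValueError(f"zero-variance EBV measures: {zero}")
    return frame.corr()
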