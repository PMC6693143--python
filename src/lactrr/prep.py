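"""Record filtering, deterministic class assignments and lactation totals.

Filtering rules (applied jointly, iterated to a fixpoint so the result does
not depend on rule order):

* each retained goat has at least four test days (TD) between DIM 7 and 270;
* its lactation lasts between 180 and 350 days;
* its dam is known in the pedigree;
* its sire has at least 20 retained daughters;
* each retained herd x test-date group holds more than four animals (>= 5).

Residual variance is heterogeneous along lactation, constant within nine DIM
classes (7-36, 37-66, ..., 217-246, 247-270); the multiple-trait comparison
model splits the lactation into six periods ([7,45], [46,90], ..., [226,270]).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .basis import DIM_FIRST, DIM_LAST

MIN_TESTDAYS = 4
MIN_HTD_ANIMALS = 5          # "more than four animals" per herd x test date
MIN_SIRE_PROGENY = 20
LACTATION_RANGE = (180, 350)
LACT_HORIZON = 250           # days; whole-lactation totals
N_RESIDUAL_CLASSES = 9
MT_PERIOD_UPPER = (45, 90, 135, 180, 225, 270)


def residual_class(d) -> np.ndarray | int:
    """Residual DIM class 1..9 for DIM ``d`` (7-36 -> 1, ..., 247-270 -> 9)."""
    d_arr = np.asarray(d)
    if np.any(d_arr < DIM_FIRST) or np.any(d_arr > DIM_LAST):
        raise ValueError(f"DIM out of [{DIM_FIRST}, {DIM_LAST}]")
    cls = np.minimum((d_arr - DIM_FIRST) // 30, N_RESIDUAL_CLASSES - 1) + 1
    return int(cls) if np.isscalar(d) else cls.astype(int)


def mt_period(d) -> np.ndarray | int:
    """Multiple-trait period 1..6 for DIM ``d`` ([7,45] -> 1, ..., [226,270] -> 6)."""
    d_arr = np.asarray(d)
    if np.any(d_arr < DIM_FIRST) or np.any(d_arr > DIM_LAST):
        raise ValueError(f"DIM out of [{DIM_FIRST}, {DIM_LAST}]")
    per = np.searchsorted(np.asarray(MT_PERIOD_UPPER[:-1]), d_arr, side="left") + 1
    return int(per) if np.isscalar(d) else per.astype(int)


@dataclass
class FilterReport:
    """Per-rule removal counts and iteration count of the filter fixpoint."""

    input_records: int = 0
    retained_records: int = 0
    input_goats: int = 0
    retained_goats: int = 0
    iterations: int = 0
    removed: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "input_records": self.input_records,
            "retained_records": self.retained_records,
            "input_goats": self.input_goats,
            "retained_goats": self.retained_goats,
            "iterations": self.iterations,
            "removed_goats_by_rule": dict(self.removed),
        }


REQUIRED_COLUMNS = ("goat", "herd", "test_date", "dim", "y")


def apply_filters(records: pd.DataFrame, pedigree=None) -> tuple[pd.DataFrame, FilterReport]:
    """Apply the record-retention rules, iterating to a fixpoint.

    ``records`` needs columns goat, herd, test_date, dim, y and, to enforce
    the sire and dam rules, sire/dam columns (or a ``pedigree`` to look them
    up).  A ``lactation_length`` column is used for the 180-350 day rule when
    present; otherwise the last observed DIM serves as a proxy.
    """
    missing = [c for c in REQUIRED_COLUMNS if c not in records.columns]
    if missing:
        raise ValueError(f"records missing required columns: {missing}")
    rec = records.copy()
    report = FilterReport(input_records=len(rec),
                          input_goats=rec["goat"].nunique())
    removed = {"few_testdays": 0, "lactation_length": 0, "unknown_dam": 0,
               "small_sire_family": 0}
    removed_htd = 0

    if "sire" not in rec.columns or "dam" not in rec.columns:
        if pedigree is not None:
            pf = pedigree.to_frame().set_index("animal")
            rec["sire"] = pf["sire"].reindex(rec["goat"]).to_numpy()
            rec["dam"] = pf["dam"].reindex(rec["goat"]).to_numpy()
        else:
            rec["sire"] = 0
            rec["dam"] = 1  # no pedigree: rules on parents cannot be applied

    in_range = (rec["dim"] >= DIM_FIRST) & (rec["dim"] <= DIM_LAST)
    rec = rec[in_range]

    it = 0
    while True:
        it += 1
        n_before = rec["goat"].nunique()

        counts = rec.groupby("goat")["dim"].count()
        bad = set(counts[counts < MIN_TESTDAYS].index)
        removed["few_testdays"] += len(bad)
        rec = rec[~rec["goat"].isin(bad)]

        if "lactation_length" in rec.columns:
            lact = rec.groupby("goat")["lactation_length"].first()
        else:
            lact = rec.groupby("goat")["dim"].max()
        bad = set(lact[(lact < LACTATION_RANGE[0]) | (lact > LACTATION_RANGE[1])].index)
        removed["lactation_length"] += len(bad)
        rec = rec[~rec["goat"].isin(bad)]

        dam_unknown = rec["dam"].isin([0, "0"]) | rec["dam"].isna()
        bad = set(rec.loc[dam_unknown, "goat"])
        removed["unknown_dam"] += len(bad)
        rec = rec[~rec["goat"].isin(bad)]

        # herd x test-date groups must keep >= 5 animals; drop the records
        htd_sizes = rec.groupby(["herd", "test_date"])["goat"].nunique()
        bad_htd = htd_sizes[htd_sizes < MIN_HTD_ANIMALS].index
        removed_htd += len(bad_htd)
        if len(bad_htd):
            key = pd.MultiIndex.from_frame(rec[["herd", "test_date"]])
            rec = rec[~key.isin(bad_htd)]

        progeny = rec.groupby("sire")["goat"].nunique()
        known_sire = ~rec["sire"].isin([0, "0"]) & ~rec["sire"].isna()
        bad_sires = set(progeny[progeny < MIN_SIRE_PROGENY].index) - {0, "0"}
        bad = set(rec.loc[known_sire & rec["sire"].isin(bad_sires), "goat"])
        bad |= set(rec.loc[~known_sire, "goat"])  # sires must be known AI bucks
        removed["small_sire_family"] += len(bad)
        rec = rec[~rec["goat"].isin(bad)]

        if rec["goat"].nunique() == n_before:
            break

    report.iterations = it
    report.retained_records = len(rec)
    report.retained_goats = rec["goat"].nunique()
    removed["herd_testdate_groups"] = removed_htd
    report.removed = removed
    return rec.reset_index(drop=True), report


def fleischmann_total(dims, yields, horizon: int = LACT_HORIZON) -> float:
    """Whole-lactation total by the Fleischmann (interval) method.

    The daily-yield trajectory is taken constant at the first TD value from
    day 0 to the first TD (ICAR convention), linear between successive TDs,
    and constant at the last TD value afterwards; the total is the integral
    of that trajectory from day 0 to the horizon (default 250 days).  This
    equals ``P1 d1 + sum (Pi + Pi+1)/2 (di+1 - di) + Pn (horizon - dn)``
    with all terms truncated at the horizon.
    """
    d = np.asarray(dims, dtype=float)
    p = np.asarray(yields, dtype=float)
    if d.size == 0:
        raise ValueError("need at least one test day")
    if np.any(np.diff(d) <= 0):
        raise ValueError("DIM must be strictly ascending")
    if np.any(p < 0):
        raise ValueError("negative yields")
    # extend to a piecewise-linear curve on [0, horizon]
    xs = np.concatenate(([0.0], d, [max(horizon, d[-1])]))
    ys = np.concatenate(([p[0]], p, [p[-1]]))
    grid = np.clip(xs, 0.0, horizon)
    return float(np.trapezoid(np.interp(grid, xs, ys), grid))


def lactation_totals(records: pd.DataFrame, horizon: int = LACT_HORIZON) -> pd.DataFrame:
    """Per-goat Fleischmann totals of the trait in column ``y``."""
    rows = []
    for goat, grp in records.sort_values("dim").groupby("goat"):
        rows.append((goat, fleischmann_total(grp["dim"], grp["y"], horizon)))
    return pd.DataFrame(rows, columns=["goat", "total"])


def mt_phenotypes(records: pd.DataFrame) -> pd.DataFrame:
    """Per-goat, per-period phenotypes for the multiple-trait model.

    Two TDs falling in the same period are averaged.  Returns long format:
    goat, period (1..6), y.
    """
    rec = records.copy()
    rec["period"] = mt_period(rec["dim"].to_numpy())
    out = rec.groupby(["goat", "period"], as_index=False)["y"].mean()
    return out
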