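"""Synthetic pedigrees and test-day records with the RRM generative structure.

The generator emulates a first-lactation dairy-goat recording scheme:
daughters of artificial-insemination sires spread over many herds, roughly
monthly milk recording (intervals of 28-35 days), lactations of 180-350
days, spline-shaped fixed lactation curves per kidding-age and
kidding-period class, herd x test-date effects, a gestation-stage effect in
late lactation, random-regression genetic and permanent-environment curves
on a Legendre basis drawn with pedigree covariance, and residual variance
heterogeneous over the nine DIM classes.

Default magnitudes (kg/day of milk) give a diagonal-dominant genetic
coefficient covariance whose first principal component carries ~88% of the
genetic variance, daily heritabilities around 0.25-0.3, and a U-shaped
residual profile; see docs/methods.md for the rationale.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .basis import (
    gestation_covariates,
    lactation_stage_covariates,
    legendre_matrix,
)
from .pedigree import Pedigree, inbreeding, mendelian_variances
from .prep import residual_class

# month of kidding -> kidding period class (8 classes: Jan, Feb, Mar,
# Apr-Jun, Jul-Sep, Oct, Nov, Dec)
_MONTH_TO_PERIOD = {1: 1, 2: 2, 3: 3, 4: 4, 5: 4, 6: 4, 7: 5, 8: 5, 9: 5,
                    10: 6, 11: 7, 12: 8}
N_AGE_CLASSES = 7      # kidding age 9-11, 12, 13, 14, 15, 16, >=17 months
N_PERIOD_CLASSES = 8

DEFAULT_K_G = np.diag([0.40, 0.040, 0.012, 0.006, 0.003])
DEFAULT_K_P = np.diag([0.35, 0.050, 0.015, 0.008, 0.004])
DEFAULT_RESIDUAL = np.array(
    [0.45, 0.35, 0.30, 0.28, 0.28, 0.28, 0.30, 0.35, 0.50])


@dataclass
class SimulationConfig:
    """Study conditions for one simulated trait (milk yield scale)."""

    n_sires: int = 50
    daughters_per_sire: int = 20
    n_dams: int = 200
    n_herds: int = 40
    n_years: int = 2                   # kidding cohorts
    order: int = 4                     # Legendre order of the generating RRM
    k_g: np.ndarray = field(default_factory=lambda: DEFAULT_K_G.copy())
    k_p: np.ndarray = field(default_factory=lambda: DEFAULT_K_P.copy())
    residual: np.ndarray = field(default_factory=lambda: DEFAULT_RESIDUAL.copy())
    test_interval: tuple = (28, 35)    # days between herd recordings
    lactation_range: tuple = (180, 350)
    kidding_window: int = 90           # days over which a cohort kids
    htd_sd: float = 0.5                # herd x test-date effect spread
    year_age_sd: float = 0.10
    year_period_sd: float = 0.10
    class_curve_sd: float = 0.05       # per-class spline-curve deviations
    base_curve_knots: tuple = (2.6, 3.2, 3.5, 3.2, 2.8, 2.3)  # kg/day
    gestation_knots_effect: tuple = (0.0, -0.05, -0.15, -0.30)  # kg/day
    conception_range: tuple = (120, 200)  # kidding-to-conception days
    open_fraction: float = 0.10        # goats never pregnant in 1st lactation
    phenotyped_dams: bool = False      # dams recorded in an earlier cohort

    def __post_init__(self):
        self.k_g = np.atleast_2d(np.asarray(self.k_g, dtype=float))
        self.k_p = np.atleast_2d(np.asarray(self.k_p, dtype=float))
        self.residual = np.asarray(self.residual, dtype=float)
        k = self.order + 1
        if self.k_g.shape != (k, k) or self.k_p.shape != (k, k):
            raise ValueError("k_g/k_p dimension must equal order + 1")
        if self.residual.shape != (9,) or np.any(self.residual < 0):
            raise ValueError("residual must be a non-negative 9-vector")


@dataclass
class TrueEffects:
    """Generating effect values kept for recovery tests."""

    genetic: np.ndarray        # n_animals x (order+1), pedigree order
    pe: np.ndarray             # n_goats x (order+1), goat order
    goats: np.ndarray          # goat ids aligned with pe rows
    year_age: dict             # (year, age_class) -> value
    year_period: dict          # (year, period_class) -> value
    base_curve_coefs: np.ndarray
    age_curve_coefs: np.ndarray      # n_age_classes x 6 (row 0 = reference, zero)
    period_curve_coefs: np.ndarray   # n_period_classes x 6
    gestation_coefs: np.ndarray      # 4


def simulate_pedigree(n_sires: int, n_dams: int, daughters_per_sire: int,
                      seed: int) -> tuple[Pedigree, np.ndarray]:
    """Founder sires and dams plus phenotyped daughters.

    Every daughter has a known sire (exactly ``daughters_per_sire`` each)
    and a known dam drawn from the dam pool, so dams may have several
    daughters and maternal half-sib families occur.  Returns the pedigree
    (founders first) and the ids of the phenotyped goats.
    """
    if min(n_sires, n_dams, daughters_per_sire) < 1:
        raise ValueError("counts must be >= 1")
    rng = np.random.default_rng(seed)
    sires = np.arange(1, n_sires + 1)
    dams = np.arange(n_sires + 1, n_sires + n_dams + 1)
    n_goats = n_sires * daughters_per_sire
    goats = np.arange(n_sires + n_dams + 1, n_sires + n_dams + n_goats + 1)
    sire_of = np.repeat(sires, daughters_per_sire)
    dam_of = rng.choice(dams, size=n_goats, replace=True)
    entries = [(int(s), 0, 0) for s in sires]
    entries += [(int(d), 0, 0) for d in dams]
    entries += [(int(g), int(s), int(d))
                for g, s, d in zip(goats, sire_of, dam_of)]
    return Pedigree.from_records(entries), goats


def simulate_two_generation_pedigree(n_sires: int, n_dams: int,
                                     daughters_per_sire: int, seed: int,
                                     ) -> tuple[Pedigree, np.ndarray, np.ndarray]:
    """Pedigree in which the dams are themselves recorded goats.

    Dams are daughters of a small set of grand-sires (>= 25 daughters each,
    so they too pass the progeny filter) and of founder grand-dams; the
    study goats are daughters of (sire, dam) as usual.  Returns the
    pedigree, the phenotyped goat ids (dams first, then daughters) and a
    generation tag per phenotyped goat (0 = dam cohort, 1 = daughters).
    """
    if min(n_sires, n_dams, daughters_per_sire) < 1:
        raise ValueError("counts must be >= 1")
    rng = np.random.default_rng(seed)
    n_gs = max(1, n_dams // 25)
    n_gd = max(5, n_dams // 3)
    next_id = 1

    def take(n):
        nonlocal next_id
        ids = np.arange(next_id, next_id + n)
        next_id += n
        return ids

    gsires, gdams, sires = take(n_gs), take(n_gd), take(n_sires)
    dams = take(n_dams)
    goats = take(n_sires * daughters_per_sire)
    entries = [(int(i), 0, 0) for i in np.concatenate([gsires, gdams, sires])]
    gs_of = gsires[np.arange(n_dams) % n_gs]   # balanced grand-sire families
    gd_of = rng.choice(gdams, size=n_dams, replace=True)
    entries += [(int(d), int(s), int(m))
                for d, s, m in zip(dams, gs_of, gd_of)]
    sire_of = np.repeat(sires, daughters_per_sire)
    dam_of = rng.choice(dams, size=goats.size, replace=True)
    entries += [(int(g), int(s), int(m))
                for g, s, m in zip(goats, sire_of, dam_of)]
    phenotyped = np.concatenate([dams, goats])
    generation = np.concatenate([np.zeros(dams.size, dtype=int),
                                 np.ones(goats.size, dtype=int)])
    return Pedigree.from_records(entries), phenotyped, generation


def _psd_sqrt(K: np.ndarray) -> np.ndarray:
    w, V = np.linalg.eigh(K)
    if np.any(w < -1e-8 * max(w.max(), 1.0)):
        raise ValueError("covariance matrix is not positive semi-definite")
    return V * np.sqrt(np.clip(w, 0.0, None))


def simulate_genetic_values(ped: Pedigree, K_g: np.ndarray,
                            rng: np.random.Generator) -> np.ndarray:
    """Per-animal genetic coefficient vectors with pedigree covariance.

    Founders are N(0, K_g); an offspring is the parent average plus a
    Mendelian deviation with covariance ``d_i K_g`` where ``d_i`` accounts
    for unknown parents and parental inbreeding.
    """
    K_g = np.atleast_2d(K_g)
    n, k = len(ped), K_g.shape[0]
    root = _psd_sqrt(K_g)
    D = mendelian_variances(ped, inbreeding(ped))
    z = rng.standard_normal((n, k))
    a = np.zeros((n, k))
    s, d = ped.sire_idx, ped.dam_idx
    for i in range(n):
        mean = np.zeros(k)
        if s[i] >= 0:
            mean += 0.5 * a[s[i]]
        if d[i] >= 0:
            mean += 0.5 * a[d[i]]
        a[i] = mean + np.sqrt(D[i]) * (root @ z[i])
    return a


def simulate_true_effects(ped: Pedigree, K_g, K_p, goats,
                          config: SimulationConfig, seed: int) -> TrueEffects:
    """Draw all generating random and fixed effect values (HTD aside)."""
    rng = np.random.default_rng(seed)
    K_g = np.atleast_2d(np.asarray(K_g, dtype=float))
    K_p = np.atleast_2d(np.asarray(K_p, dtype=float))
    genetic = simulate_genetic_values(ped, K_g, rng)
    pe = rng.standard_normal((len(goats), K_p.shape[0])) @ _psd_sqrt(K_p).T

    # lactations started in the last cohort spill into the following
    # calendar year (one more when a dam generation precedes the cohorts),
    # so draw effects for the extra production years as well
    years = np.arange(config.n_years + 2)
    year_age = {(int(j), k): rng.normal(0.0, config.year_age_sd)
                for j in years for k in range(1, N_AGE_CLASSES + 1)}
    year_period = {(int(j), l): rng.normal(0.0, config.year_period_sd)
                   for j in years for l in range(1, N_PERIOD_CLASSES + 1)}

    # base lactation curve: natural spline interpolating the knot values
    knots_design = lactation_stage_covariates(np.asarray((7, 20, 50, 110, 190, 270)))
    base_coefs, *_ = np.linalg.lstsq(knots_design,
                                     np.asarray(config.base_curve_knots), rcond=None)
    age_curves = np.zeros((N_AGE_CLASSES, 6))
    age_curves[1:] = rng.normal(0.0, config.class_curve_sd, size=(N_AGE_CLASSES - 1, 6))
    period_curves = np.zeros((N_PERIOD_CLASSES, 6))
    period_curves[1:] = rng.normal(0.0, config.class_curve_sd,
                                   size=(N_PERIOD_CLASSES - 1, 6))

    gest_design = gestation_covariates(np.asarray((31, 53, 76, 100), dtype=float))
    gest_coefs, *_ = np.linalg.lstsq(gest_design,
                                     np.asarray(config.gestation_knots_effect),
                                     rcond=None)
    return TrueEffects(genetic=genetic, pe=pe, goats=np.asarray(goats),
                       year_age=year_age, year_period=year_period,
                       base_curve_coefs=base_coefs, age_curve_coefs=age_curves,
                       period_curve_coefs=period_curves,
                       gestation_coefs=gest_coefs)


@dataclass
class SimulatedData:
    records: pd.DataFrame
    pedigree: Pedigree
    effects: TrueEffects
    config: SimulationConfig
    htd_effects: dict          # (herd, day_offset) -> value

    def truth(self) -> dict:
        """JSON-serializable generating parameters for recovery tests."""
        return {
            "k_g": self.config.k_g.tolist(),
            "k_p": self.config.k_p.tolist(),
            "residual": self.config.residual.tolist(),
            "order": self.config.order,
        }


_EPOCH = pd.Timestamp("2000-09-01")


def simulate_testday_records(ped: Pedigree, effects: TrueEffects,
                             config: SimulationConfig, seed: int,
                             generation=None) -> tuple[pd.DataFrame, dict]:
    """Generate test-day records from the full RRM generative model.

    Returns the record table and the frozen herd x test-date effects.
    Columns: goat, sire, dam, herd, test_date (ISO), dim, age_class,
    period_class, year, gestation_days, lactation_length, y.
    """
    if len(ped) == 0:
        raise ValueError("empty pedigree")
    lo, hi = config.test_interval
    if not (0 < lo <= hi):
        raise ValueError("invalid test-interval schedule")
    rng = np.random.default_rng(seed)
    goats = effects.goats
    n_goats = goats.size
    g_index = ped.index_of(goats)
    sire_id = np.where(ped.sire_idx[g_index] >= 0,
                       ped.animals[ped.sire_idx[g_index]], 0)
    dam_id = np.where(ped.dam_idx[g_index] >= 0,
                      ped.animals[ped.dam_idx[g_index]], 0)

    herd_of = rng.integers(0, config.n_herds, size=n_goats)
    if generation is None:
        cohort = rng.integers(0, config.n_years, size=n_goats)
    else:
        # dams (generation 0) kid in year 0; their daughters from year 1 on
        cohort = np.where(np.asarray(generation) == 0, 0,
                          1 + rng.integers(0, config.n_years, size=n_goats))
    kid_day = cohort * 365 + rng.integers(0, config.kidding_window + 1, size=n_goats)
    age_class = rng.integers(1, N_AGE_CLASSES + 1, size=n_goats)
    lact_len = rng.integers(config.lactation_range[0],
                            config.lactation_range[1] + 1, size=n_goats)
    open_goat = rng.random(n_goats) < config.open_fraction
    conception = rng.integers(config.conception_range[0],
                              config.conception_range[1] + 1, size=n_goats)

    horizon = (int(cohort.max()) + 1) * 365 + config.kidding_window + 360
    schedules = {}
    for h in range(config.n_herds):
        t = int(rng.integers(0, hi))
        days = []
        while t < horizon:
            days.append(t)
            t += int(rng.integers(lo, hi + 1))
        schedules[h] = np.asarray(days)

    rows_goat, rows_day, rows_dim = [], [], []
    for i in range(n_goats):
        sched = schedules[herd_of[i]]
        dim = sched - kid_day[i]
        keep = (dim >= 7) & (dim <= min(270, lact_len[i]))
        for day, dd in zip(sched[keep], dim[keep]):
            rows_goat.append(i)
            rows_day.append(int(day))
            rows_dim.append(int(dd))
    gi = np.asarray(rows_goat)
    day = np.asarray(rows_day)
    dim = np.asarray(rows_dim)

    herd = herd_of[gi]
    # herd x test-date effects: drawn once in sorted-key order, then frozen
    htd_keys = sorted({(int(h_), int(t_)) for h_, t_ in zip(herd, day)})
    draws = rng.normal(0.0, config.htd_sd, size=len(htd_keys))
    htd_values = {key: float(v) for key, v in zip(htd_keys, draws)}

    kid_month = ((_EPOCH + pd.to_timedelta(kid_day, unit="D")).month)
    period_class = np.asarray([_MONTH_TO_PERIOD[m] for m in kid_month])
    test_year = (_EPOCH + pd.to_timedelta(day, unit="D")).year - _EPOCH.year

    gest = np.where(open_goat[gi], 0, np.clip(dim - conception[gi], 0, None))

    # assemble the phenotype
    y = np.fromiter((htd_values[(int(h), int(t))] for h, t in zip(herd, day)),
                    dtype=float, count=len(gi))
    y += np.asarray([effects.year_age[(int(j), int(k))]
                     for j, k in zip(test_year, age_class[gi])])
    y += np.asarray([effects.year_period[(int(j), int(l))]
                     for j, l in zip(test_year, period_class[gi])])
    N = lactation_stage_covariates(dim)
    y += N @ effects.base_curve_coefs
    y += np.einsum("ij,ij->i", N, effects.age_curve_coefs[age_class[gi] - 1])
    y += np.einsum("ij,ij->i", N, effects.period_curve_coefs[period_class[gi] - 1])
    y += gestation_covariates(gest.astype(float)) @ effects.gestation_coefs
    Phi = legendre_matrix(config.order, dim)
    y += np.einsum("ij,ij->i", Phi, effects.genetic[g_index[gi]])
    y += np.einsum("ij,ij->i", Phi, effects.pe[gi])
    sd = np.sqrt(config.residual[residual_class(dim) - 1])
    y += rng.standard_normal(len(gi)) * sd
    y = np.maximum(y, 0.0)   # measured daily yields cannot be negative

    records = pd.DataFrame({
        "goat": goats[gi],
        "sire": sire_id[gi],
        "dam": dam_id[gi],
        "herd": herd,
        "test_date": (_EPOCH + pd.to_timedelta(day, unit="D")).strftime("%Y-%m-%d"),
        "dim": dim,
        "age_class": age_class[gi],
        "period_class": period_class[gi],
        "year": test_year,
        "gestation_days": gest,
        "lactation_length": lact_len[gi],
        "y": y,
    })
    records = records.sort_values(["goat", "dim"], kind="stable").reset_index(drop=True)
    return records, htd_values


def simulate_dataset(config: SimulationConfig | None = None,
                     seed: int = 0) -> SimulatedData:
    """End-to-end simulation: pedigree, true effects, test-day records."""
    if config is None:
        config = SimulationConfig()
    if config.phenotyped_dams:
        ped, goats, generation = simulate_two_generation_pedigree(
            config.n_sires, config.n_dams, config.daughters_per_sire, seed)
    else:
        ped, goats = simulate_pedigree(config.n_sires, config.n_dams,
                                       config.daughters_per_sire, seed)
        generation = None
    effects = simulate_true_effects(ped, config.k_g, config.k_p, goats,
                                    config, seed + 1)
    records, htd = simulate_testday_records(ped, effects, config, seed + 2,
                                            generation=generation)
    return SimulatedData(records=records, pedigree=ped, effects=effects,
                         config=config, htd_effects=htd)


def leg2_config(**overrides) -> SimulationConfig:
    """A second-order generating truth used for recovery experiments."""
    base = dict(order=2,
                k_g=np.diag([0.40, 0.040, 0.012]),
                k_p=np.diag([0.35, 0.050, 0.015]))
    base.update(overrides)
    return SimulationConfig(**base)
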