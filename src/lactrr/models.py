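"""Estimators for test-day and whole-lactation genetic evaluation.

Four scikit-learn-style estimators share the mixed-model engine:

* :class:`RandomRegressionModel` — the test-day RRM: herd-test-date,
  year x age and year x period fixed effects, natural-spline fixed
  lactation curves per kidding-age and kidding-period class, a
  gestation-stage spline, and Legendre random regressions (order q) for the
  additive genetic and permanent-environment effects, with nine residual
  DIM classes.
* :class:`ReducedRankRandomRegression` — the same model with the random
  regressions on the first z eigenfunctions of a full model's genetic
  coefficient covariance, diagonal coefficient covariances by construction.
* :class:`LactationModel` — whole-lactation Fleischmann totals with a
  scalar animal effect (the routine-evaluation style model).
* :class:`MultiTraitModel` — test days grouped into six lactation periods
  treated as six correlated traits.

``fit(records, pedigree=...)`` takes a test-day record table (columns:
goat, herd, test_date, dim, age_class, period_class, year, gestation_days,
y) and a :class:`~lactrr.pedigree.Pedigree`; fitted attributes follow the
sklearn trailing-underscore convention.  ``score`` returns the Pearson
correlation between observed and fitted phenotypes, the model-comparison
statistic used alongside BIC.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import scipy.sparse as sp
from sklearn.base import BaseEstimator

from .basis import (
    full_grid,
    gestation_covariates,
    lactation_stage_covariates,
    legendre_basis,
    legendre_matrix,
)
from .covfun import CovarianceFunction, covariance_function
from .mme import (
    FitResult,
    MixedModelDesign,
    VarianceComponents,
    blup_solve,
    fit_correlation,
    random_regression_design,
    reduce_to_full_rank,
    reml_fit,
)
from .pedigree import Pedigree, relationship_inverse
from .prep import (
    N_RESIDUAL_CLASSES,
    lactation_totals,
    mt_phenotypes,
    residual_class,
)
from .reduction import ReducedSpec, build_reduced_spec, eigendecompose

RECORD_COLUMNS = ("goat", "herd", "test_date", "dim", "age_class",
                  "period_class", "year", "gestation_days", "y")

N_AGE_CLASSES = 7
N_PERIOD_CLASSES = 8


def _check_records(records: pd.DataFrame, columns=RECORD_COLUMNS):
    missing = [c for c in columns if c not in records.columns]
    if missing:
        raise ValueError(f"records missing columns: {missing}")


class _FactorBlock:
    """One-hot block for a categorical term, with stored level mapping."""

    def __init__(self, keys):
        self.levels = list(dict.fromkeys(keys))  # first-appearance order
        self.pos = {lev: i for i, lev in enumerate(self.levels)}

    @property
    def n(self) -> int:
        return len(self.levels)

    def transform(self, keys: pd.Series) -> sp.csr_matrix:
        rows, cols = [], []
        for r, k in enumerate(keys):
            j = self.pos.get(k)
            if j is not None:          # unseen levels contribute no effect
                rows.append(r)
                cols.append(j)
        data = np.ones(len(rows))
        return sp.csr_matrix((data, (rows, cols)), shape=(len(keys), self.n))


class _TestDayFixedDesign:
    """Fixed design of the RRM, reproducible on new records."""

    def fit(self, records: pd.DataFrame) -> "_TestDayFixedDesign":
        self.htd = _FactorBlock(list(zip(records["herd"], records["test_date"])))
        self.year_age = _FactorBlock(list(zip(records["year"], records["age_class"])))
        self.year_period = _FactorBlock(list(zip(records["year"], records["period_class"])))
        X = self._full(records)
        XtX_cols, self.rank = reduce_to_full_rank(np.asarray(X.todense()))
        self.keep = XtX_cols
        return self

    def _full(self, records: pd.DataFrame) -> sp.csr_matrix:
        dim = records["dim"].to_numpy()
        N = lactation_stage_covariates(dim)                  # n x 6
        n = len(records)
        blocks = [
            self.htd.transform(list(zip(records["herd"], records["test_date"]))),
            self.year_age.transform(list(zip(records["year"], records["age_class"]))),
            self.year_period.transform(list(zip(records["year"], records["period_class"]))),
            sp.csr_matrix(N),                                # common curve
        ]
        # per-class spline deviations; the reference class is absorbed into
        # the common curve
        age = records["age_class"].to_numpy()
        for k in range(2, N_AGE_CLASSES + 1):
            blocks.append(sp.csr_matrix(N * (age == k)[:, None]))
        per = records["period_class"].to_numpy()
        for l in range(2, N_PERIOD_CLASSES + 1):
            blocks.append(sp.csr_matrix(N * (per == l)[:, None]))
        blocks.append(sp.csr_matrix(
            gestation_covariates(records["gestation_days"].to_numpy(dtype=float))))
        return sp.hstack(blocks, format="csr")

    def transform(self, records: pd.DataFrame) -> sp.csr_matrix:
        return self._full(records)[:, self.keep]


def _default_init(y, k: int, n_classes: int,
                  include_pe: bool) -> VarianceComponents:
    """Heuristic starting components: split the phenotypic variance."""
    v = float(np.var(np.asarray(y, float)))
    v = max(v, 1e-6)
    # phi_0^2 = 1/2, so a coefficient variance 2*s maps to daily variance s
    lead = np.asarray([2.0 * 0.25 * v * 0.3 ** o for o in range(k)])
    k_g = np.diag(lead)
    k_p = np.diag(lead.copy()) if include_pe else None
    residual = np.full(n_classes, 0.5 * v)
    return VarianceComponents(k_g=k_g, residual=residual, k_p=k_p)


class _MixedModelMixin:
    """Shared post-fit surface: predictions, score, BIC."""

    def predict(self, records: pd.DataFrame) -> np.ndarray:
        """Fitted phenotype (fixed + genetic + PE parts) for each record."""
        design = self._design_rows(records)
        out = design @ self._solution_vector()
        return np.asarray(out).ravel()

    def score(self, records: pd.DataFrame, y=None) -> float:
        """Pearson correlation between observed and fitted phenotypes."""
        yy = records["y"].to_numpy(float) if y is None else np.asarray(y, float)
        return fit_correlation(yy, self.predict(records))

    def bic(self) -> float:
        """BIC = -2 logL + p ln(N - rank(X)), p = free covariance parameters."""
        return self.result_.bic()

    def _solution_vector(self) -> np.ndarray:
        r = self.result_
        parts = [r.fixed, r.ebv.ravel()]
        if r.pe is not None:
            parts.append(r.pe.ravel())
        return np.concatenate(parts)


class RandomRegressionModel(_MixedModelMixin, BaseEstimator):
    """Random-regression test-day model with Legendre random effects.

    Parameters
    ----------
    order : int
        Order q of the Legendre polynomials (the model is "leg<q>"); the
        genetic and permanent-environment regressions share the order.
    method : {"ai", "em"}
        REML algorithm: average-information with EM fallback, or pure EM.
    max_iter, tol : REML stopping rule (|change in logL| < tol).  With
        ``max_iter=0`` the model solves BLUP at ``init_components``.
    init_components : VarianceComponents, optional
        Starting values (also the fixed components when ``max_iter=0``).
    include_pe : bool
        Fit a permanent-environment regression per goat (on by default).
    """

    def __init__(self, order: int = 2, method: str = "ai",
                 max_iter: int = 100, tol: float = 1e-5,
                 init_components: VarianceComponents | None = None,
                 include_pe: bool = True):
        self.order = order
        self.method = method
        self.max_iter = max_iter
        self.tol = tol
        self.init_components = init_components
        self.include_pe = include_pe

    # -- design ----------------------------------------------------------

    def _random_basis(self, dim: np.ndarray) -> np.ndarray:
        return legendre_matrix(self.order, dim)

    def _build_design(self, records: pd.DataFrame,
                      pedigree: Pedigree) -> MixedModelDesign:
        self.fixed_design_ = _TestDayFixedDesign().fit(records)
        X = self.fixed_design_.transform(records)
        A_inv, logdet_A = relationship_inverse(pedigree)
        animal_code = pedigree.index_of(records["goat"])
        k = self.order + 1
        Zg = random_regression_design(records["dim"].to_numpy(), animal_code,
                                      len(pedigree), self._random_basis)
        goats = pd.unique(records["goat"])
        goat_pos = {g: i for i, g in enumerate(goats)}
        goat_code = np.asarray([goat_pos[g] for g in records["goat"]])
        Zp = None
        if self.include_pe:
            Zp = random_regression_design(records["dim"].to_numpy(), goat_code,
                                          len(goats), self._random_basis)
        return MixedModelDesign(
            X=X, Zg=Zg, A_inv=A_inv, logdet_A=logdet_A,
            resid_class=residual_class(records["dim"].to_numpy()) - 1,
            n_classes=N_RESIDUAL_CLASSES, k_g_dim=k,
            animal_ids=pedigree.animals,
            Zp=Zp, k_p_dim=k if self.include_pe else 0,
            goat_ids=goats if self.include_pe else None)

    def _design_rows(self, records: pd.DataFrame) -> sp.csr_matrix:
        X = self.fixed_design_.transform(records)
        d = self.design_
        animal_code = self._pedigree.index_of(records["goat"])
        Zg = random_regression_design(records["dim"].to_numpy(), animal_code,
                                      d.n_animals, self._random_basis)
        parts = [X, Zg]
        if d.Zp is not None:
            pos = {g: i for i, g in enumerate(d.goat_ids)}
            code = np.asarray([pos[g] for g in records["goat"]])
            parts.append(random_regression_design(
                records["dim"].to_numpy(), code, d.n_goats, self._random_basis))
        return sp.hstack(parts, format="csr")

    # -- estimation ------------------------------------------------------

    def fit(self, records: pd.DataFrame, y=None, *, pedigree: Pedigree):
        _check_records(records)
        self._pedigree = pedigree
        design = self._build_design(records, pedigree)
        self.design_ = design
        yv = records["y"].to_numpy(float)
        init = self.init_components or _default_init(
            yv, self.order + 1, N_RESIDUAL_CLASSES, self.include_pe)
        result = reml_fit(design, yv, init, method=self.method,
                          max_iter=self.max_iter, tol=self.tol)
        self._store(result)
        return self

    def _store(self, result: FitResult):
        self.result_ = result
        self.k_g_ = result.components.k_g
        self.k_p_ = result.components.k_p
        self.residual_ = result.components.residual
        self.loglik_ = result.loglik
        self.converged_ = result.converged
        self.n_iter_ = result.n_iter
        self.n_records_ = result.n_records
        self.ebv_ = pd.DataFrame(
            result.ebv, index=pd.Index(result.animal_ids, name="animal"),
            columns=[f"a{o}" for o in range(result.ebv.shape[1])])
        self.pe_ = None
        if result.pe is not None:
            self.pe_ = pd.DataFrame(
                result.pe, index=pd.Index(result.goat_ids, name="goat"),
                columns=[f"p{o}" for o in range(result.pe.shape[1])])

    # -- genetic-parameter surface ---------------------------------------

    def basis_matrix(self) -> np.ndarray:
        """Basis values on the full 264-day grid."""
        return legendre_basis(self.order, full_grid()).matrix

    def covariance_function(self) -> CovarianceFunction:
        """G, W and P surfaces on the full DIM grid from the fitted components."""
        return covariance_function(self.k_g_, self.basis_matrix(),
                                   self.residual_, k_p=self.k_p_)

    def ebv_curves(self) -> pd.DataFrame:
        """Daily EBV curves (animals x 264 days)."""
        Q = self.basis_matrix()
        return pd.DataFrame(self.ebv_.to_numpy() @ Q.T, index=self.ebv_.index,
                            columns=full_grid().days)

    def residual_profile(self) -> pd.DataFrame:
        """Fitted residual variance per DIM class, in DIM order."""
        return pd.DataFrame({
            "dim_class": np.arange(1, N_RESIDUAL_CLASSES + 1),
            "variance": self.residual_,
        })


class ReducedRankRandomRegression(_MixedModelMixin, BaseEstimator):
    """Rank-reduced RRM ("leg<q>R<z>") on genetic eigenfunctions.

    The genetic coefficient covariance of a full order-q model is
    eigendecomposed; the first ``rank`` eigenfunctions (sign-oriented so the
    second is negative early and positive late in lactation) replace the
    Legendre basis for both the genetic and the permanent-environment
    regressions, and the coefficient covariances are re-estimated by REML
    under a diagonal constraint, so the level (b1) and persistency (b2)
    coefficients have zero covariance by construction.

    ``base_model`` may be a fitted :class:`RandomRegressionModel`; otherwise
    a full model of the given order is fitted first.
    """

    def __init__(self, order: int = 4, rank: int = 2, method: str = "ai",
                 max_iter: int = 100, tol: float = 1e-5,
                 diagonal: bool = True, include_pe: bool = True,
                 base_model: RandomRegressionModel | None = None):
        self.order = order
        self.rank = rank
        self.method = method
        self.max_iter = max_iter
        self.tol = tol
        self.diagonal = diagonal
        self.include_pe = include_pe
        self.base_model = base_model

    def _random_basis(self, dim: np.ndarray) -> np.ndarray:
        return legendre_matrix(self.order, dim) @ self.spec_.vectors

    def fit(self, records: pd.DataFrame, y=None, *, pedigree: Pedigree):
        _check_records(records)
        self._pedigree = pedigree
        base = self.base_model
        if base is None or not hasattr(base, "k_g_"):
            base = RandomRegressionModel(
                order=self.order, method=self.method,
                max_iter=self.max_iter, tol=self.tol,
                include_pe=self.include_pe)
            base.fit(records, pedigree=pedigree)
        self.full_model_ = base
        self.eigen_ = eigendecompose(base.k_g_)
        Q = legendre_basis(self.order, full_grid()).matrix
        self.spec_: ReducedSpec = build_reduced_spec(
            self.eigen_, Q, z=self.rank, diagonal=self.diagonal)

        self.fixed_design_ = _TestDayFixedDesign().fit(records)
        X = self.fixed_design_.transform(records)
        A_inv, logdet_A = relationship_inverse(pedigree)
        animal_code = pedigree.index_of(records["goat"])
        Zg = random_regression_design(records["dim"].to_numpy(), animal_code,
                                      len(pedigree), self._random_basis)
        goats = pd.unique(records["goat"])
        goat_pos = {g: i for i, g in enumerate(goats)}
        goat_code = np.asarray([goat_pos[g] for g in records["goat"]])
        Zp = None
        if self.include_pe:
            Zp = random_regression_design(records["dim"].to_numpy(), goat_code,
                                          len(goats), self._random_basis)
        design = MixedModelDesign(
            X=X, Zg=Zg, A_inv=A_inv, logdet_A=logdet_A,
            resid_class=residual_class(records["dim"].to_numpy()) - 1,
            n_classes=N_RESIDUAL_CLASSES, k_g_dim=self.rank,
            animal_ids=pedigree.animals,
            Zp=Zp, k_p_dim=self.rank if self.include_pe else 0,
            goat_ids=goats if self.include_pe else None)
        self.design_ = design

        init = VarianceComponents(
            k_g=np.diag(np.clip(self.spec_.coefficient_variances, 1e-8, None)),
            residual=base.residual_.copy(),
            k_p=(np.diag(np.clip(
                np.abs(np.diag(self.spec_.vectors.T @ base.k_p_
                               @ self.spec_.vectors)), 1e-8, None))
                 if self.include_pe else None))
        yv = records["y"].to_numpy(float)
        result = reml_fit(design, yv, init, method=self.method,
                          max_iter=self.max_iter, tol=self.tol,
                          diag_g=self.diagonal, diag_p=self.diagonal)
        self._store(result)
        return self

    def _store(self, result: FitResult):
        self.result_ = result
        self.k_g_ = result.components.k_g
        self.k_p_ = result.components.k_p
        self.residual_ = result.components.residual
        self.loglik_ = result.loglik
        self.converged_ = result.converged
        self.n_iter_ = result.n_iter
        self.n_records_ = result.n_records
        self.ebv_ = pd.DataFrame(
            result.ebv, index=pd.Index(result.animal_ids, name="animal"),
            columns=[f"b{o + 1}" for o in range(result.ebv.shape[1])])
        self.pe_ = None
        if result.pe is not None:
            self.pe_ = pd.DataFrame(
                result.pe, index=pd.Index(result.goat_ids, name="goat"),
                columns=[f"c{o + 1}" for o in range(result.pe.shape[1])])

    def _design_rows(self, records: pd.DataFrame) -> sp.csr_matrix:
        X = self.fixed_design_.transform(records)
        d = self.design_
        animal_code = self._pedigree.index_of(records["goat"])
        Zg = random_regression_design(records["dim"].to_numpy(), animal_code,
                                      d.n_animals, self._random_basis)
        parts = [X, Zg]
        if d.Zp is not None:
            pos = {g: i for i, g in enumerate(d.goat_ids)}
            code = np.asarray([pos[g] for g in records["goat"]])
            parts.append(random_regression_design(
                records["dim"].to_numpy(), code, d.n_goats, self._random_basis))
        return sp.hstack(parts, format="csr")

    def basis_matrix(self) -> np.ndarray:
        """Eigenfunction values on the full grid (264 x rank)."""
        return self.spec_.eigenfunctions

    def covariance_function(self) -> CovarianceFunction:
        return covariance_function(self.k_g_, self.basis_matrix(),
                                   self.residual_, k_p=self.k_p_)

    def ebv_curves(self) -> pd.DataFrame:
        Q = self.basis_matrix()
        return pd.DataFrame(self.ebv_.to_numpy() @ Q.T, index=self.ebv_.index,
                            columns=full_grid().days)


def _gestation_at_270(records: pd.DataFrame) -> pd.Series:
    """Gestation stage (days) each goat would reach at DIM 270, binned.

    Uses the record-level gestation counter: if a goat shows g > 0 at DIM d,
    its stage at DIM 270 is g + (270 - d); goats never seen pregnant get
    class 0.  Stages are binned in 30-day classes.
    """
    last = records.sort_values("dim").groupby("goat").last()
    g270 = np.where(last["gestation_days"] > 0,
                    last["gestation_days"] + (270 - last["dim"]), 0)
    cls = np.where(g270 > 0, 1 + (g270 - 1) // 30, 0).astype(int)
    return pd.Series(cls, index=last.index)


def _goat_meta(records: pd.DataFrame) -> pd.DataFrame:
    """Per-goat fixed-effect classes for the LACT and MT models."""
    first = records.sort_values("dim").groupby("goat").first()
    kid_date = (pd.to_datetime(first["test_date"])
                - pd.to_timedelta(first["dim"], unit="D"))
    meta = pd.DataFrame({
        "age_class": first["age_class"],
        "period_class": first["period_class"],
        "herd_year": list(zip(first["herd"], kid_date.dt.year)),
        "gest_class": _gestation_at_270(records),
    })
    return meta


class LactationModel(_MixedModelMixin, BaseEstimator):
    """Whole-lactation animal model on Fleischmann totals.

    ``fit`` computes per-goat 250-day Fleischmann totals from the test-day
    records, then fits ``total = age + kidding-period + gestation-stage +
    herd-year + animal + e`` with a scalar genetic effect and a single
    residual variance.
    """

    def __init__(self, method: str = "ai", max_iter: int = 100,
                 tol: float = 1e-6, horizon: int = 250):
        self.method = method
        self.max_iter = max_iter
        self.tol = tol
        self.horizon = horizon

    def fit(self, records: pd.DataFrame, y=None, *, pedigree: Pedigree):
        _check_records(records)
        totals = lactation_totals(records, horizon=self.horizon)
        meta = _goat_meta(records)
        goats = totals["goat"].to_numpy()
        meta = meta.loc[goats]
        blocks = [
            _FactorBlock(meta["age_class"].tolist()),
            _FactorBlock(meta["period_class"].tolist()),
            _FactorBlock(meta["gest_class"].tolist()),
            _FactorBlock(meta["herd_year"].tolist()),
        ]
        self._blocks = blocks
        self._block_keys = ["age_class", "period_class", "gest_class",
                            "herd_year"]
        X_full = sp.hstack(
            [b.transform(meta[k].tolist())
             for b, k in zip(blocks, self._block_keys)],
            format="csr")
        keep, rank = reduce_to_full_rank(np.asarray(X_full.todense()))
        self._keep = keep
        X = X_full[:, keep]
        A_inv, logdet_A = relationship_inverse(pedigree)
        code = pedigree.index_of(goats)
        Zg = sp.csr_matrix((np.ones(len(goats)),
                            (np.arange(len(goats)), code)),
                           shape=(len(goats), len(pedigree)))
        design = MixedModelDesign(
            X=X, Zg=Zg, A_inv=A_inv, logdet_A=logdet_A,
            resid_class=np.zeros(len(goats), dtype=int), n_classes=1,
            k_g_dim=1, animal_ids=pedigree.animals)
        self.design_ = design
        yv = totals["total"].to_numpy(float)
        v = max(float(np.var(yv)), 1e-6)
        init = VarianceComponents(k_g=np.asarray([[0.3 * v]]),
                                  residual=np.asarray([0.7 * v]))
        result = reml_fit(design, yv, init, method=self.method,
                          max_iter=self.max_iter, tol=self.tol)
        self.result_ = result
        self.totals_ = totals.set_index("goat")
        self.k_g_ = result.components.k_g
        self.residual_ = result.components.residual
        self.loglik_ = result.loglik
        self.converged_ = result.converged
        self.n_iter_ = result.n_iter
        self.n_records_ = result.n_records
        self.ebv_ = pd.Series(result.ebv.ravel(),
                              index=pd.Index(result.animal_ids, name="animal"),
                              name="lact_ebv")
        return self

    def predict(self, records: pd.DataFrame) -> np.ndarray:
        meta = _goat_meta(records)
        goats = meta.index.to_numpy()
        X_full = sp.hstack(
            [b.transform(meta[k].tolist())
             for b, k in zip(self._blocks, self._block_keys)],
            format="csr")
        X = X_full[:, self._keep]
        fitted = X @ self.result_.fixed + self.ebv_.reindex(goats).to_numpy()
        return np.asarray(fitted).ravel()

    def score(self, records: pd.DataFrame, y=None) -> float:
        totals = lactation_totals(records, horizon=self.horizon)
        return fit_correlation(totals["total"].to_numpy(), self.predict(records))


class MultiTraitModel(_MixedModelMixin, BaseEstimator):
    """Six-period multiple-trait animal model.

    Test days are grouped into six DIM periods ([7,45], [46,90], [91,135],
    [136,180], [181,225], [226,270]); a goat's records within one period are
    averaged and the six period phenotypes are modeled as six traits with a
    full 6x6 genetic covariance, period-specific fixed effects (age, kidding
    period, gestation stage at DIM 270, herd-year) and one residual variance
    per period.  No permanent-environment effect: each trait has a single
    record per goat.
    """

    N_PERIODS = 6

    def __init__(self, method: str = "ai", max_iter: int = 100,
                 tol: float = 1e-5):
        self.method = method
        self.max_iter = max_iter
        self.tol = tol

    def fit(self, records: pd.DataFrame, y=None, *, pedigree: Pedigree):
        _check_records(records)
        pheno = mt_phenotypes(records)
        present = np.sort(pheno["period"].unique())
        if len(present) < self.N_PERIODS:
            import warnings
            missing = sorted(set(range(1, 7)) - set(present.tolist()))
            warnings.warn(f"periods with no records dropped: {missing}")
        self.periods_ = present
        per_code = pd.Series(np.arange(len(present)), index=present)
        meta = _goat_meta(records)
        meta = meta.loc[pheno["goat"]]
        per = pheno["period"].to_numpy()
        blocks = [
            _FactorBlock(list(zip(meta["age_class"], per))),
            _FactorBlock(list(zip(meta["period_class"], per))),
            _FactorBlock(list(zip(meta["gest_class"], per))),
            _FactorBlock(list(zip(meta["herd_year"], per))),
        ]
        key_lists = [
            list(zip(meta["age_class"], per)),
            list(zip(meta["period_class"], per)),
            list(zip(meta["gest_class"], per)),
            list(zip(meta["herd_year"], per)),
        ]
        X_full = sp.hstack([b.transform(k) for b, k in zip(blocks, key_lists)],
                           format="csr")
        keep, rank = reduce_to_full_rank(np.asarray(X_full.todense()))
        X = X_full[:, keep]
        A_inv, logdet_A = relationship_inverse(pedigree)
        code = pedigree.index_of(pheno["goat"])
        k = len(present)
        pc = per_code.loc[per].to_numpy()
        Zg = sp.csr_matrix((np.ones(len(pheno)),
                            (np.arange(len(pheno)), code * k + pc)),
                           shape=(len(pheno), len(pedigree) * k))
        design = MixedModelDesign(
            X=X, Zg=Zg, A_inv=A_inv, logdet_A=logdet_A,
            resid_class=pc, n_classes=k, k_g_dim=k,
            animal_ids=pedigree.animals)
        self.design_ = design
        yv = pheno["y"].to_numpy(float)
        v = max(float(np.var(yv)), 1e-6)
        init = VarianceComponents(
            k_g=0.3 * v * (0.5 * np.eye(k) + 0.5),
            residual=np.full(k, 0.7 * v))
        result = reml_fit(design, yv, init, method=self.method,
                          max_iter=self.max_iter, tol=self.tol)
        self.result_ = result
        self.pheno_ = pheno
        self.k_g_ = result.components.k_g
        self.residual_ = result.components.residual
        self.loglik_ = result.loglik
        self.converged_ = result.converged
        self.n_iter_ = result.n_iter
        self.n_records_ = result.n_records
        self.ebv_ = pd.DataFrame(
            result.ebv, index=pd.Index(result.animal_ids, name="animal"),
            columns=[f"period{p}" for p in present])
        return self

    def predict(self, records: pd.DataFrame) -> np.ndarray:
        """Fitted period phenotypes, aligned with ``mt_phenotypes(records)``."""
        pheno = mt_phenotypes(records)
        if not pheno[["goat", "period"]].equals(self.pheno_[["goat", "period"]]):
            raise NotImplementedError(
                "MultiTraitModel.predict supports the training records only")
        return self.result_.fitted

    def fit_phenotype_correlation(self) -> float:
        """Pearson correlation between observed and fitted period phenotypes."""
        return fit_correlation(self.pheno_["y"].to_numpy(), self.result_.fitted)

    def score(self, records: pd.DataFrame = None, y=None) -> float:
        return self.fit_phenotype_correlation()

    def genetic_correlations(self) -> np.ndarray:
        """6x6 genetic correlation matrix between periods."""
        sd = np.sqrt(np.diag(self.k_g_))
        return self.k_g_ / np.outer(sd, sd)

    def heritabilities(self) -> np.ndarray:
        """Per-period h2 = genetic / (genetic + residual)."""
        g = np.diag(self.k_g_)
        return g / (g + self.residual_)
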