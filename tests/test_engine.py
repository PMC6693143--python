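"""Mixed-model equations, BLUP and REML."""

import numpy as np
import pytest
import scipy.sparse as sp

from lactrr.mme import (
    MixedModelDesign,
    VarianceComponents,
    blup_solve,
    fit_correlation,
    reml_fit,
)
from lactrr.models import RandomRegressionModel
from lactrr.pedigree import Pedigree, relationship_inverse, relationship_matrix
from lactrr.simulate import SimulationConfig, simulate_dataset


def gls_solutions(model, records, pedigree, comp):
    """Dense GLS oracle: V built explicitly, solutions via V inversion."""
    d = model.design_
    A = relationship_matrix(pedigree)
    X = np.asarray(d.X.todense())
    Zg = np.asarray(d.Zg.todense())
    V = Zg @ np.kron(A, comp.k_g) @ Zg.T
    V = V + np.diag(comp.residual[d.resid_class])
    if d.Zp is not None:
        Zp = np.asarray(d.Zp.todense())
        V = V + Zp @ np.kron(np.eye(d.n_goats), comp.k_p) @ Zp.T
    y = records["y"].to_numpy()
    Vi = np.linalg.inv(V)
    b = np.linalg.solve(X.T @ Vi @ X, X.T @ Vi @ y)
    resid = Vi @ (y - X @ b)
    a = np.kron(A, comp.k_g) @ Zg.T @ resid
    fitted = X @ b + Zg @ a
    if d.Zp is not None:
        p = np.kron(np.eye(d.n_goats), comp.k_p) @ Zp.T @ resid
        fitted = fitted + Zp @ p
    else:
        p = None
    return a, p, fitted


class TestBlupOracle:
    def test_solutions_equal_dense_gls(self, tiny_leg1, tiny_components):
        m = RandomRegressionModel(order=1, max_iter=0,
                                  init_components=tiny_components)
        m.fit(tiny_leg1.records, pedigree=tiny_leg1.pedigree)
        a, p, fitted = gls_solutions(m, tiny_leg1.records, tiny_leg1.pedigree,
                                     tiny_components)
        assert np.abs(m.result_.ebv.ravel() - a).max() <= 1e-8
        assert np.abs(m.result_.pe.ravel() - p).max() <= 1e-8
        assert np.abs(m.predict(tiny_leg1.records) - fitted).max() <= 1e-8

    def test_ebv_shrink_to_zero_with_tiny_variances(self, tiny_leg1):
        comp = VarianceComponents(k_g=np.diag([1e-10, 1e-10]),
                                  residual=np.full(9, 0.3),
                                  k_p=np.diag([1e-10, 1e-10]))
        m = RandomRegressionModel(order=1, max_iter=0, init_components=comp)
        m.fit(tiny_leg1.records, pedigree=tiny_leg1.pedigree)
        assert np.abs(m.result_.ebv).max() < 1e-6

    def test_fitted_values_do_not_depend_on_aliased_column_choice(
            self, tiny_leg1, tiny_components):
        # choosing a different full-rank subset of an aliased fixed design
        # must not move the fitted values (estimable-function property)
        from lactrr.mme import reduce_to_full_rank
        m = RandomRegressionModel(order=1, max_iter=0,
                                  init_components=tiny_components)
        m.fit(tiny_leg1.records, pedigree=tiny_leg1.pedigree)
        fitted0 = m.predict(tiny_leg1.records)
        d = m.design_
        full = np.asarray(m.fixed_design_._full(tiny_leg1.records).todense())
        rev = full[:, ::-1]                      # different pivot order
        keep2, rank2 = reduce_to_full_rank(rev)
        assert rank2 == d.X.shape[1]
        d2 = MixedModelDesign(
            X=sp.csr_matrix(rev[:, keep2]), Zg=d.Zg, A_inv=d.A_inv,
            logdet_A=d.logdet_A, resid_class=d.resid_class,
            n_classes=d.n_classes, k_g_dim=d.k_g_dim,
            animal_ids=d.animal_ids, Zp=d.Zp, k_p_dim=d.k_p_dim,
            goat_ids=d.goat_ids)
        res2 = blup_solve(d2, tiny_leg1.records["y"].to_numpy(),
                          m.result_.components)
        assert np.abs(res2.fitted - fitted0).max() <= 1e-7


def one_way_design(q=30, n=12, s2u=2.0, s2e=5.0, seed=7):
    rng = np.random.default_rng(seed)
    u = rng.normal(0, np.sqrt(s2u), q)
    y = (u[:, None] + rng.normal(0, np.sqrt(s2e), (q, n))).ravel() + 10.0
    ped = Pedigree.from_records([(i + 1, 0, 0) for i in range(q)])
    A_inv, logdet_A = relationship_inverse(ped)
    N = q * n
    X = sp.csr_matrix(np.ones((N, 1)))
    Zg = sp.csr_matrix((np.ones(N), (np.arange(N), np.repeat(np.arange(q), n))),
                       shape=(N, q))
    design = MixedModelDesign(X=X, Zg=Zg, A_inv=A_inv, logdet_A=logdet_A,
                              resid_class=np.zeros(N, dtype=int), n_classes=1,
                              k_g_dim=1, animal_ids=ped.animals)
    return design, y, q, n


class TestReml:
    def test_balanced_one_way_matches_anova_closed_form(self):
        design, y, q, n = one_way_design()
        init = VarianceComponents(k_g=[[1.0]], residual=[1.0])
        res = reml_fit(design, y, init, method="ai", max_iter=100, tol=1e-10)
        Y = y.reshape(q, n)
        msb = n * Y.mean(1).var(ddof=1)
        msw = Y.var(1, ddof=1).mean()
        assert res.components.residual[0] == pytest.approx(msw, rel=1e-8)
        assert res.components.k_g[0, 0] == pytest.approx((msb - msw) / n,
                                                         rel=1e-8)

    def test_em_likelihood_never_decreases(self):
        design, y, *_ = one_way_design(seed=11)
        init = VarianceComponents(k_g=[[0.5]], residual=[3.0])
        res = reml_fit(design, y, init, method="em", max_iter=60, tol=1e-12)
        tr = np.asarray(res.loglik_trace)
        assert np.all(np.diff(tr) >= -1e-8)

    def test_scale_equivariance_of_variance_estimates(self):
        design, y, *_ = one_way_design(seed=13)
        init = VarianceComponents(k_g=[[1.0]], residual=[1.0])
        r1 = reml_fit(design, y, init, max_iter=100, tol=1e-10)
        c = 3.7
        r2 = reml_fit(design, c * y, init, max_iter=100, tol=1e-10)
        assert r2.components.k_g[0, 0] == pytest.approx(
            c ** 2 * r1.components.k_g[0, 0], rel=1e-5)
        assert r2.components.residual[0] == pytest.approx(
            c ** 2 * r1.components.residual[0], rel=1e-5)

    def test_reml_recovers_leg1_truth_roughly(self, filterable_data):
        from lactrr.prep import apply_filters
        rec, _ = apply_filters(filterable_data.records,
                               filterable_data.pedigree)
        m = RandomRegressionModel(order=1, max_iter=30, tol=1e-3)
        m.fit(rec, pedigree=filterable_data.pedigree)
        total_true = 0.4 + 0.3   # leading genetic + PE coefficient variance
        total_est = m.k_g_[0, 0] + m.k_p_[0, 0]
        assert total_est == pytest.approx(total_true, rel=0.5)
        assert m.loglik_ == pytest.approx(m.result_.loglik_trace[-1])


class TestCriteria:
    def test_bic_free_parameter_count(self, small_leg1, tiny_components):
        m = RandomRegressionModel(order=1, max_iter=0,
                                  init_components=tiny_components)
        m.fit(small_leg1.records, pedigree=small_leg1.pedigree)
        # order 1: 3 + 3 + 9 free parameters
        assert m.result_.p_free == 15
        comp5 = VarianceComponents(k_g=np.eye(5), residual=np.ones(9),
                                   k_p=np.eye(5))
        assert comp5.n_free() == 15 + 15 + 9  # the leg4 count
        n_eff = m.n_records_ - m.result_.rank_x
        assert m.bic() == pytest.approx(-2 * m.loglik_
                                        + 15 * np.log(n_eff))

    def test_fit_correlation_properties(self):
        rng = np.random.default_rng(3)
        y = rng.normal(size=50)
        f = y + 0.1 * rng.normal(size=50)
        rho = fit_correlation(y, f)
        assert rho == pytest.approx(fit_correlation(3.0 * y + 1.0, f))
        with pytest.raises(ValueError):
            fit_correlation(np.ones(5), f[:5])

    def test_noise_free_fit_correlation_is_one(self):
        cfg = SimulationConfig(n_sires=3, daughters_per_sire=4, n_dams=6,
                               n_herds=2, order=1,
                               k_g=np.diag([0.4, 0.04]),
                               k_p=np.zeros((2, 2)),
                               residual=np.full(9, 1e-6))
        data = simulate_dataset(cfg, seed=31)
        comp = VarianceComponents(k_g=np.diag([0.4, 0.04]),
                                  residual=np.full(9, 1e-6))
        m = RandomRegressionModel(order=1, max_iter=0, init_components=comp,
                                  include_pe=False)
        m.fit(data.records, pedigree=data.pedigree)
        assert m.score(data.records) >= 1 - 1e-6

    def test_residual_profile_shape(self, tiny_leg1, tiny_components):
        m = RandomRegressionModel(order=1, max_iter=0,
                                  init_components=tiny_components)
        m.fit(tiny_leg1.records, pedigree=tiny_leg1.pedigree)
        prof = m.residual_profile()
        assert list(prof["dim_class"]) == list(range(1, 10))
        assert np.all(prof["variance"].to_numpy() > 0)
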