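"""Henderson mixed-model equations and REML for test-day models.

A model instance is described by a :class:`MixedModelDesign`: a fixed-effect
design X (reduced to full column rank), a genetic random design Zg whose
columns are animal-major coefficient blocks with prior covariance
``A (x) K_g`` (Kronecker, animal-major ordering), an optional
permanent-environment design Zp with prior ``I (x) K_p``, and a residual
class label per record (diagonal R, heterogeneous by DIM class).

Variance components are estimated by REML.  The default algorithm takes
average-information (AI) Newton steps with expectation-maximization (EM)
fallback whenever an AI step leaves the parameter space or decreases the
restricted likelihood; a pure EM mode is available (its likelihood is
monotone, which the tests exercise).  Trace terms are taken from a dense
Cholesky inverse of the coefficient matrix, which is exact and affordable at
the system sizes this package targets (up to roughly 12,000 equations).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla
from scipy.linalg import cho_solve, solve
from scipy.linalg.lapack import dpotrf, dpotri, dpstrf


# --------------------------------------------------------------------------
# components


@dataclass
class VarianceComponents:
    """Genetic / permanent-environment coefficient covariances and residuals."""

    k_g: np.ndarray
    residual: np.ndarray
    k_p: np.ndarray | None = None

    def __post_init__(self):
        self.k_g = np.atleast_2d(np.asarray(self.k_g, dtype=float))
        self.residual = np.atleast_1d(np.asarray(self.residual, dtype=float))
        if self.k_p is not None:
            self.k_p = np.atleast_2d(np.asarray(self.k_p, dtype=float))

    def validate(self):
        for name, K in (("k_g", self.k_g), ("k_p", self.k_p)):
            if K is None:
                continue
            if not np.allclose(K, K.T, atol=1e-10):
                raise ValueError(f"{name} must be symmetric")
            w = np.linalg.eigvalsh(K)
            if w.min() < -1e-8 * max(w.max(), 1.0):
                raise ValueError(f"{name} must be positive semi-definite")
        if np.any(self.residual <= 0):
            raise ValueError("residual variances must be positive")

    def copy(self) -> "VarianceComponents":
        return VarianceComponents(self.k_g.copy(), self.residual.copy(),
                                  None if self.k_p is None else self.k_p.copy())

    def n_free(self, diag_g: bool = False, diag_p: bool = False) -> int:
        """Number of free (co)variance parameters (for BIC)."""
        kg = self.k_g.shape[0]
        n = kg if diag_g else kg * (kg + 1) // 2
        if self.k_p is not None:
            kp = self.k_p.shape[0]
            n += kp if diag_p else kp * (kp + 1) // 2
        return n + self.residual.size


def _bend(K: np.ndarray) -> np.ndarray:
    """Symmetric PSD inverse with eigenvalue bending for near-singular K."""
    K = 0.5 * (K + K.T)
    w, V = np.linalg.eigh(K)
    floor = max(w.max(), 1e-12) * 1e-10
    w = np.clip(w, floor, None)
    return (V / w) @ V.T


def _logdet_psd(K: np.ndarray) -> float:
    w = np.linalg.eigvalsh(0.5 * (K + K.T))
    floor = max(w.max(), 1e-12) * 1e-10
    return float(np.sum(np.log(np.clip(w, floor, None))))


# --------------------------------------------------------------------------
# design


def reduce_to_full_rank(X: np.ndarray, names=None, tol: float = 1e-8):
    """Drop linearly dependent columns (pivoted Cholesky of X'X).

    Returns (kept column indices, rank).  Fitted values are invariant to
    which columns of an aliased set survive.
    """
    XtX = X.T @ X
    scale = np.sqrt(np.clip(np.diag(XtX), 1e-300, None))
    C = XtX / scale[:, None] / scale[None, :]
    _, piv, rank, _ = dpstrf(C, tol=tol, lower=1)
    keep = np.sort(piv[:rank] - 1)
    return keep, int(rank)


@dataclass
class MixedModelDesign:
    """Assembled design for one model on one record set."""

    X: sp.csr_matrix
    Zg: sp.csr_matrix
    A_inv: sp.csr_matrix
    logdet_A: float
    resid_class: np.ndarray          # 0-based class per record
    n_classes: int
    k_g_dim: int
    animal_ids: np.ndarray
    Zp: sp.csr_matrix | None = None
    k_p_dim: int = 0
    goat_ids: np.ndarray | None = None
    fixed_names: list = field(default_factory=list)
    _A_lu: object = None

    @property
    def n_records(self) -> int:
        return self.X.shape[0]

    @property
    def n_fixed(self) -> int:
        return self.X.shape[1]

    @property
    def n_animals(self) -> int:
        return len(self.animal_ids)

    @property
    def n_goats(self) -> int:
        return 0 if self.goat_ids is None else len(self.goat_ids)

    @property
    def n_eq(self) -> int:
        n = self.n_fixed + self.k_g_dim * self.n_animals
        if self.Zp is not None:
            n += self.k_p_dim * self.n_goats
        return n

    def W(self) -> sp.csr_matrix:
        parts = [self.X, self.Zg]
        if self.Zp is not None:
            parts.append(self.Zp)
        return sp.hstack(parts, format="csr")

    def A_times(self, M: np.ndarray) -> np.ndarray:
        """A @ M via a factorization of the sparse A^-1."""
        if self._A_lu is None:
            self._A_lu = spla.splu(sp.csc_matrix(self.A_inv))
        return self._A_lu.solve(np.asarray(M))


def random_regression_design(dim, animal_codes, n_animals, basis_row) -> sp.csr_matrix:
    """Sparse design with one k-column basis block per animal (animal-major).

    ``basis_row`` maps a DIM vector to an (n, k) covariate matrix.
    """
    B = np.atleast_2d(basis_row(np.asarray(dim)))
    n, k = B.shape
    rows = np.repeat(np.arange(n), k)
    cols = (np.asarray(animal_codes)[:, None] * k + np.arange(k)[None, :]).ravel()
    return sp.csr_matrix((B.ravel(), (rows, cols)), shape=(n, n_animals * k))


# --------------------------------------------------------------------------
# fit result


@dataclass
class FitResult:
    components: VarianceComponents
    fixed: np.ndarray
    ebv: np.ndarray              # n_animals x k_g coefficient solutions
    pe: np.ndarray | None        # n_goats x k_p
    loglik: float
    n_records: int
    rank_x: int
    n_iter: int
    converged: bool
    p_free: int
    animal_ids: np.ndarray
    goat_ids: np.ndarray | None
    fitted: np.ndarray           # fitted fixed + genetic + PE per record
    loglik_trace: list = field(default_factory=list)

    def bic(self) -> float:
        """-2 logL + p ln(N - rank(X)) with p the free covariance count."""
        n_eff = self.n_records - self.rank_x
        if n_eff <= 0:
            raise ValueError("no residual degrees of freedom")
        return -2.0 * self.loglik + self.p_free * np.log(n_eff)


def fit_correlation(y, fitted) -> float:
    """Pearson correlation between observed and fitted phenotypes."""
    y = np.asarray(y, float)
    f = np.asarray(fitted, float)
    if np.std(y) == 0 or np.std(f) == 0:
        raise ValueError("zero variance in observed or fitted values")
    return float(np.corrcoef(y, f)[0, 1])


# --------------------------------------------------------------------------
# the engine


class _Engine:
    def __init__(self, design: MixedModelDesign, y,
                 diag_g: bool = False, diag_p: bool = False):
        self.d = design
        self.y = np.asarray(y, dtype=float)
        self.diag_g = diag_g
        self.diag_p = diag_p
        d = design
        self.W = d.W()
        self.n_eq = d.n_eq
        self.p = d.n_fixed
        self.ng_block = d.k_g_dim * d.n_animals
        # per-residual-class cross-products
        self.Mc, self.bc, self.yyc, self.nc = [], [], [], []
        for c in range(d.n_classes):
            mask = d.resid_class == c
            Wc = self.W[mask]
            yc = self.y[mask]
            self.Mc.append((Wc.T @ Wc).tocsr())
            self.bc.append(Wc.T @ yc)
            self.yyc.append(float(yc @ yc))
            self.nc.append(int(mask.sum()))
        self.nc = np.asarray(self.nc)
        self.empty_classes = np.flatnonzero(self.nc == 0)
        if self.empty_classes.size:
            warnings.warn(
                "residual classes with no records (variances kept at their "
                f"starting values): {(self.empty_classes + 1).tolist()}",
                stacklevel=3)
        self._C_buf = None
        # gather indices for the genetic trace term
        Acoo = sp.coo_matrix(d.A_inv)
        self._A_rows, self._A_cols, self._A_vals = Acoo.row, Acoo.col, Acoo.data

    # -- assembly ---------------------------------------------------------

    def _assemble(self, comp: VarianceComponents):
        d = self.d
        rinv = 1.0 / comp.residual
        Csp = sum(r * M for r, M in zip(rinv, self.Mc))
        rhs = sum(r * b for r, b in zip(rinv, self.bc))
        yRy = float(np.dot(rinv, self.yyc))
        Kg_inv = _bend(comp.k_g)
        pen = sp.kron(d.A_inv, Kg_inv, format="coo")
        blocks = [(pen, self.p)]
        if d.Zp is not None:
            Kp_inv = _bend(comp.k_p)
            pen_p = sp.kron(sp.identity(d.n_goats, format="coo"), Kp_inv,
                            format="coo")
            blocks.append((pen_p, self.p + self.ng_block))
        if self._C_buf is None:
            # Fortran order so LAPACK can factor and invert in place
            self._C_buf = np.zeros((self.n_eq, self.n_eq), order="F")
        C = self._C_buf
        C.fill(0.0)
        Ccoo = sp.coo_matrix(Csp)
        np.add.at(C, (Ccoo.row, Ccoo.col), Ccoo.data)
        for blk, off in blocks:
            np.add.at(C, (blk.row + off, blk.col + off), blk.data)
        return C, rhs, yRy

    def _factorize(self, comp: VarianceComponents):
        d = self.d
        C, rhs, yRy = self._assemble(comp)
        L, info = dpotrf(C, lower=1, overwrite_a=1)
        if info != 0:
            raise np.linalg.LinAlgError(
                "mixed-model equations not positive definite "
                "(confounded fixed effects or invalid components)")
        logdet_C = 2.0 * float(np.sum(np.log(np.diag(L))))
        theta = cho_solve((L, True), rhs)
        yPy = yRy - float(rhs @ theta)
        ll = -0.5 * (float(np.dot(self.nc, np.log(comp.residual)))
                     + d.k_g_dim * d.logdet_A
                     + d.n_animals * _logdet_psd(comp.k_g)
                     + (d.n_goats * _logdet_psd(comp.k_p)
                        if d.Zp is not None else 0.0)
                     + logdet_C + yPy)
        return L, theta, ll

    def _inverse(self, L):
        Ci, info = dpotri(L, lower=1, overwrite_c=1)
        if info != 0:
            raise np.linalg.LinAlgError("dpotri failed")
        # blocked in-place symmetrization (dpotri fills the lower triangle)
        n = Ci.shape[0]
        b = 2048
        for i0 in range(0, n, b):
            i1 = min(n, i0 + b)
            Ci[i0:i1, i1:] = Ci[i1:, i0:i1].T
            blk = Ci[i0:i1, i0:i1]
            iu = np.triu_indices(i1 - i0, 1)
            blk[iu] = blk.T[iu]
        return Ci

    # -- sufficient statistics -------------------------------------------

    def _suff_stats(self, comp, theta, Ci):
        d = self.d
        p, kg = self.p, d.k_g_dim
        U = theta[p:p + self.ng_block].reshape(d.n_animals, kg)
        T_g = U.T @ (d.A_inv @ U)
        base = p + self._A_rows * kg
        base_c = p + self._A_cols * kg
        blk = Ci[(base[:, None, None] + np.arange(kg)[None, :, None]),
                 (base_c[:, None, None] + np.arange(kg)[None, None, :])]
        T_g = T_g + np.einsum("x,xkl->kl", self._A_vals, blk)
        T_g = 0.5 * (T_g + T_g.T)

        T_p = None
        P = None
        if d.Zp is not None:
            kp = d.k_p_dim
            off = p + self.ng_block
            P = theta[off:].reshape(d.n_goats, kp)
            base = off + np.arange(d.n_goats) * kp
            idx = base[:, None] + np.arange(kp)[None, :]
            blocks = Ci[idx[:, :, None], idx[:, None, :]]
            T_p = P.T @ P + blocks.sum(axis=0)
            T_p = 0.5 * (T_p + T_p.T)

        ehat = self.y - self.W @ theta
        ess = np.zeros(d.n_classes)
        dc = np.zeros(d.n_classes)
        # diag(W Ci W') accumulated per class, chunked to bound memory
        chunk = max(1, int(2.0e8 / (8 * self.n_eq)))
        n = d.n_records
        diagq = np.empty(n)
        for s in range(0, n, chunk):
            Wc = self.W[s:s + chunk]
            diagq[s:s + chunk] = np.asarray(
                Wc.multiply(Wc @ Ci).sum(axis=1)).ravel()
        for c in range(d.n_classes):
            mask = d.resid_class == c
            ess[c] = float(ehat[mask] @ ehat[mask])
            dc[c] = float(diagq[mask].sum())
        return T_g, T_p, ess, dc, ehat, U, P

    # -- parameter packing -------------------------------------------------

    def _pairs(self, k, diag):
        if diag:
            return [(i, i) for i in range(k)]
        return [(i, j) for i in range(k) for j in range(i, k)]

    def _pack_info(self, comp):
        kg = comp.k_g.shape[0]
        info = [("g", i, j) for i, j in self._pairs(kg, self.diag_g)]
        if self.d.Zp is not None:
            kp = comp.k_p.shape[0]
            info += [("p", i, j) for i, j in self._pairs(kp, self.diag_p)]
        info += [("r", c, c) for c in range(self.d.n_classes)]
        return info

    def _pack_values(self, comp, info):
        out = []
        for kind, i, j in info:
            if kind == "g":
                out.append(comp.k_g[i, j])
            elif kind == "p":
                out.append(comp.k_p[i, j])
            else:
                out.append(comp.residual[i])
        return np.asarray(out)

    def _set_values(self, comp, info, values):
        new = comp.copy()
        for (kind, i, j), v in zip(info, values):
            if kind == "g":
                new.k_g[i, j] = new.k_g[j, i] = v
            elif kind == "p":
                new.k_p[i, j] = new.k_p[j, i] = v
            else:
                new.residual[i] = v
        return new

    def _apply_delta(self, comp, info, delta):
        new = comp.copy()
        for (kind, i, j), dv in zip(info, delta):
            if kind == "g":
                new.k_g[i, j] += dv
                if i != j:
                    new.k_g[j, i] += dv
            elif kind == "p":
                new.k_p[i, j] += dv
                if i != j:
                    new.k_p[j, i] += dv
            else:
                new.residual[i] += dv
        return new

    @staticmethod
    def _bend_components(comp: VarianceComponents) -> VarianceComponents:
        """Project a candidate onto the parameter space (PSD K, positive R)."""
        new = comp.copy()
        for name in ("k_g", "k_p"):
            K = getattr(new, name)
            if K is None:
                continue
            K = 0.5 * (K + K.T)
            w, V = np.linalg.eigh(K)
            floor = 1e-6 * max(w.max(), 1e-8)
            setattr(new, name, (V * np.clip(w, floor, None)) @ V.T)
        new.residual = np.clip(new.residual, 1e-8, None)
        return new

    @staticmethod
    def _valid(comp: VarianceComponents) -> bool:
        if np.any(comp.residual <= 0):
            return False
        for K in (comp.k_g, comp.k_p):
            if K is None:
                continue
            w = np.linalg.eigvalsh(0.5 * (K + K.T))
            if w.min() < -1e-10 * max(abs(w).max(), 1e-12):
                return False
        return True

    # -- EM / AI updates ---------------------------------------------------

    def _em_candidate(self, comp, T_g, T_p, ess, dc):
        d = self.d
        new = comp.copy()
        Kg = T_g / d.n_animals
        new.k_g = np.diag(np.diag(Kg)) if self.diag_g else Kg
        if d.Zp is not None:
            Kp = T_p / d.n_goats
            new.k_p = np.diag(np.diag(Kp)) if self.diag_p else Kp
        new.residual = np.where(self.nc > 0, (ess + dc) / np.maximum(self.nc, 1),
                                comp.residual)
        return new

    def _score(self, comp, info, T_g, T_p, ess, dc):
        Kg_inv = _bend(comp.k_g)
        Sg = -0.5 * (self.d.n_animals * Kg_inv - Kg_inv @ T_g @ Kg_inv)
        if self.d.Zp is not None:
            Kp_inv = _bend(comp.k_p)
            Sp = -0.5 * (self.d.n_goats * Kp_inv - Kp_inv @ T_p @ Kp_inv)
        sr = -0.5 * (self.nc / comp.residual
                     - (ess + dc) / comp.residual ** 2)
        sr[self.empty_classes] = 0.0
        out = []
        for kind, i, j in info:
            if kind == "g":
                out.append(Sg[i, j] * (1.0 if i == j else 2.0))
            elif kind == "p":
                out.append(Sp[i, j] * (1.0 if i == j else 2.0))
            else:
                out.append(sr[i])
        return np.asarray(out)

    def _ai_matrix(self, comp, info, Ci, ehat):
        d = self.d
        Py = ehat / comp.residual[d.resid_class]
        F = np.empty((d.n_records, len(info)))
        Tg = (d.Zg.T @ Py).reshape(d.n_animals, d.k_g_dim)
        if d.Zp is not None:
            Tp = (d.Zp.T @ Py).reshape(d.n_goats, d.k_p_dim)
        for m, (kind, i, j) in enumerate(info):
            if kind == "g":
                E = np.zeros((d.k_g_dim, d.k_g_dim))
                E[i, j] = E[j, i] = 1.0
                U = d.A_times(Tg @ E)
                F[:, m] = d.Zg @ U.ravel()
            elif kind == "p":
                E = np.zeros((d.k_p_dim, d.k_p_dim))
                E[i, j] = E[j, i] = 1.0
                F[:, m] = d.Zp @ (Tp @ E).ravel()
            else:
                F[:, m] = np.where(d.resid_class == i, Py, 0.0)
        Rinv = 1.0 / comp.residual[d.resid_class]
        RF = F * Rinv[:, None]
        WtRF = self.W.T @ RF
        PF = RF - Rinv[:, None] * (self.W @ (Ci @ WtRF))
        return 0.5 * (F.T @ PF)

    # -- main loop ---------------------------------------------------------

    def run(self, init: VarianceComponents, method: str = "ai",
            max_iter: int = 200, tol: float = 1e-6):
        comp = init.copy()
        comp.validate()
        trace = []
        prev_ll = -np.inf
        converged = False
        n_iter = 0
        pending_em = None      # EM candidate from the previous point
        best_ll, best_comp = -np.inf, None
        prev_vec = None
        dll = []               # accepted log-likelihood gains
        theta = None
        for it in range(max(max_iter, 1)):
            n_iter = it + 1
            L, theta, ll = self._factorize(comp)
            if ll < prev_ll - 10.0 * tol and pending_em is not None:
                # overshoot (AI or Aitken): retreat to the EM candidate of
                # the previous point, whose likelihood cannot decrease
                comp = pending_em
                pending_em = None
                dll.clear()
                L, theta, ll = self._factorize(comp)
            trace.append(ll)
            if ll > best_ll:
                best_ll, best_comp = ll, comp.copy()
            if max_iter == 0:
                break
            if it > 0 and abs(ll - prev_ll) < tol:
                converged = True
                break
            if np.isfinite(prev_ll):
                dll.append(ll - prev_ll)
            prev_ll = ll
            Ci = self._inverse(L)
            T_g, T_p, ess, dc, ehat, _, _ = self._suff_stats(comp, theta, Ci)
            em = self._em_candidate(comp, T_g, T_p, ess, dc)
            if method == "em":
                comp = em
                pending_em = None
                continue
            info = self._pack_info(comp)
            cur_vec = self._pack_values(comp, info)
            # Aitken extrapolation once the gains decay geometrically
            if len(dll) >= 3 and prev_vec is not None:
                d1, d2, d3 = dll[-3:]
                if 0 < d3 <= d2 <= d1 and d3 < 1.0 and d2 > 0 and d1 > 0:
                    r1, r2 = d2 / d1, d3 / d2
                    if abs(r1 - r2) < 0.05 and r2 < 0.999:
                        jump = r2 / (1.0 - r2)
                        cand = self._set_values(
                            comp, info, cur_vec + jump * (cur_vec - prev_vec))
                        cand = self._bend_components(cand)
                        if self._valid(cand):
                            prev_vec = cur_vec
                            pending_em = em
                            comp = cand
                            dll.clear()
                            continue
            prev_vec = cur_vec
            score = self._score(comp, info, T_g, T_p, ess, dc)
            AI = self._ai_matrix(comp, info, Ci, ehat)
            AI = AI + np.eye(len(info)) * (1e-8 * max(np.trace(AI), 1.0)
                                           / len(info))
            try:
                delta = solve(AI, score, assume_a="pos")
            except np.linalg.LinAlgError:
                delta = None
            new = None
            if delta is not None:
                step = 1.0
                for _ in range(4):
                    cand = self._apply_delta(comp, info, step * delta)
                    if self._valid(cand):
                        new = cand
                        break
                    step *= 0.5
            if new is None or not self._valid(new):
                new = em if self._valid(em) else comp
            comp = new
            pending_em = em
        if max_iter > 0:
            # report the best visited point (REML estimates) with its solutions
            if best_comp is not None and best_ll > trace[-1] + 1e-12:
                comp = best_comp
            L, theta, ll = self._factorize(comp)
            if not np.isclose(ll, trace[-1]):
                trace.append(ll)
        return comp, theta, trace, converged, n_iter

def reml_fit(design: MixedModelDesign, y, init: VarianceComponents,
             method: str = "ai", max_iter: int = 200, tol: float = 1e-6,
             diag_g: bool = False, diag_p: bool = False) -> FitResult:
    """Estimate variance components by REML and return solutions.

    ``max_iter=0`` skips estimation and returns BLUP at ``init`` (with the
    restricted log-likelihood evaluated there).
    """
    eng = _Engine(design, y, diag_g=diag_g, diag_p=diag_p)
    comp, theta, trace, converged, n_iter = eng.run(
        init, method=method, max_iter=max_iter, tol=tol)
    d = design
    p = d.n_fixed
    ng = d.k_g_dim * d.n_animals
    fitted = eng.W @ theta
    pe = None
    if d.Zp is not None:
        pe = theta[p + ng:].reshape(d.n_goats, d.k_p_dim)
    return FitResult(
        components=comp,
        fixed=theta[:p],
        ebv=theta[p:p + ng].reshape(d.n_animals, d.k_g_dim),
        pe=pe,
        loglik=trace[-1],
        n_records=d.n_records,
        rank_x=p,
        n_iter=n_iter,
        converged=converged or max_iter == 0,
        p_free=comp.n_free(diag_g=diag_g, diag_p=diag_p),
        animal_ids=d.animal_ids,
        goat_ids=d.goat_ids,
        fitted=np.asarray(fitted),
        loglik_trace=trace,
    )


def blup_solve(design: MixedModelDesign, y,
               components: VarianceComponents) -> FitResult:
    """Solve the MME at known components (no REML)."""
    return reml_fit(design, y, components, max_iter=0)
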