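# Methods

## The model

`lactrr` implements genetic evaluation of first-lactation dairy traits from
test-day (TD) records with random-regression animal models.  A TD record of
goat *n* on day in milk (DIM) *d* in herd-test-date class *i* is modeled as

```
y = HTD_i + A_jk + M_jl + sum_r theta_kr N(r,d) + sum_r tau_lr N(r,d)
    + sum_s gamma_s M(s,g) + sum_o a_no phi(o,d) + sum_o p_no phi(o,d) + e
```

with fixed effects for herd x test date (`HTD`), production-year x
kidding-age class (`A`, 7 age classes), production-year x kidding-period
class (`M`, 8 calendar classes), fixed lactation-stage curves per age and
period class on a natural cubic spline basis `N` with knots at DIM
{7, 20, 50, 110, 190, 270}, and a gestation-stage spline `M(s, g)` with
knots at gestation day {31, 53, 76, 100} (zero effect for g <= 30, constant
beyond g = 100).  The additive genetic (`a_n`) and permanent-environment
(`p_n`) effects of each animal are regression curves on normalized Legendre
polynomials `phi(o, d)` of order q in {0..4} ("leg0".."leg4"), evaluated on
the standardized DIM coordinate `x(d) = 2 (d - 7) / 263 - 1`.  Genetic
coefficient vectors have covariance `A (x) K_g` (A = pedigree relationship
matrix), PE vectors `I (x) K_p`, and the residual variance is constant
within nine 30-day DIM classes (7-36, ..., 247-270; the last class has 24
days) with no between-class correlation.

Two comparison models rephrase the same data: the lactation model (LACT)
fits a scalar animal effect to 250-day Fleischmann totals with age,
kidding-period, gestation-stage and herd-year fixed effects; the
multiple-trait model (MT) treats TD averages in six 45-day periods
([7,45] ... [226,270]) as six traits with a full 6x6 genetic covariance and
per-period residuals, and no PE effect (one record per trait).

### Covariance functions and summaries

With `Q` the 264 x (q+1) basis on the full DIM grid 7..270, the day-scale
genetic covariance is `G = Q K_g Q'`, the PE surface `W = Q K_p Q'`, and
`P = G + W + diag(residual by day class)`.  Daily heritability is
`G[d,d]/P[d,d]` (discontinuous exactly at the nine residual class
boundaries); whole-lactation variances contract the surfaces with a
vector of ones (`g_wl = s'Gs`, `h_wl = g_wl/p_wl`); per-coefficient
heritability is `k_g[oo] / (k_g[oo] + k_p[oo] + MSE)` where the MSE is the
record-count-weighted mean of the nine residual variances (a defensible
choice under heterogeneous residuals; any single-number summary is a
convention).

### Rank reduction

The eigen decomposition `K_g = V L V'` of a fitted full model yields
eigenfunctions `chi_o = Q v_o`.  The first is nearly constant (lactation
level), the second crosses zero once (persistency).  Sign convention:
the second eigenfunction is made negative at DIM 7 and positive at DIM 270,
the others positive on average; deciding signs on the eigenfunction scale
makes the convention invariant to basis normalization.  The rank-z reduced
model ("legqRz") regresses genetic and PE effects on the first z
eigenfunctions; coefficient covariances are re-estimated by REML under a
diagonal constraint (initialized at the leading eigenvalues), so the
level-persistency genetic covariance is zero by construction.  The PE
effect reuses the genetic eigenfunctions — an approximation inherited from
the modeling tradition, since the PE covariance has its own eigenstructure.

### EBV summaries

`SUM` is the sum of the daily EBV curve over DIM 7..270.  `PERS` is the
cumulative deviation from the DIM-40 level, `sum_{d=40}^{240} (u(d) -
u(40))` (201 daily terms — the natural discrete reading of a cumulative
deviation over that window).  Both are linear in the coefficient solutions.
One-SD contribution curves are `sqrt(lambda_o) * chi_o(d)`.

## REML

Variance components are estimated by REML on Henderson's mixed-model
equations, assembled sparse with `A^-1` built by Henderson's rules and
exact inbreeding (Meuwissen-Luo).  The default algorithm takes
average-information (AI) Newton steps on the free parameters (vech of K_g,
vech of K_p, nine residual variances), with three safeguards: step-halving,
fall-back to the EM update (which cannot decrease the likelihood) whenever
the AI step leaves the parameter space, and Aitken extrapolation of the
parameter vector once successive likelihood gains decay geometrically —
the regime these models enter when an eigenvalue of K_g approaches the
boundary.  If a step still decreases the restricted likelihood the
iteration retreats to the EM candidate of the previous point, and the
final report is the best visited point.  A pure EM mode (`method="em"`)
retains the monotonicity guarantee and is exercised by the tests.

Trace terms (EM updates, scores) are read off a dense Cholesky inverse of
the coefficient matrix, computed in place; this is exact and costs O(n_eq^3)
per iteration, which is the right trade-off for the system sizes this
package targets (10^3-10^4 equations).  The restricted log-likelihood is
`-1/2 [ log|R| + log|G| + log|C| + y'Py ]`; fixed effects are reduced to
full column rank beforehand by pivoted Cholesky of X'X, so estimable
functions (fitted values) are invariant to which aliased columns survive.

Model comparison uses `BIC = -2 logL + p ln(N - rank(X))` with p the number
of free covariance parameters (e.g. 15 + 15 + 9 = 39 for leg4), reported as
deviations from the best model, and the Pearson correlation between
observed and fitted (fixed + genetic + PE) phenotypes.  BIC deviations are
only formed between models sharing the same phenotypes; LACT and MT are
compared by fit correlation.

Numerical choices: REML stops on |change in logL| < tol (default 1e-5, 100
iterations); near-singular K matrices are inverted with eigenvalue bending
(floor 1e-10 of the largest eigenvalue); residual classes without records
keep their starting variance and are flagged with a warning; MME positive
definiteness failures raise rather than silently pseudo-solve.

## The synthetic-data generator

No real milk-recording data ship with the package, so `lactrr.simulate`
generates datasets with exactly the generative structure the model assumes:
herds with a recording visit every 28-35 days; goats kidding in seasonal
cohorts over 1-2 years with lactation lengths uniform on [180, 350] days;
TD records at herd visit dates with DIM in [7, 270]; fixed effects drawn
once and frozen (herd-test-date SD 0.5 kg/day, year-age and year-period SD
0.1, per-class spline-curve deviations SD 0.05 around a base curve through
(2.6, 3.2, 3.5, 3.2, 2.8, 2.3) kg/day at the six knots); a gestation effect
reaching -0.3 kg/day at gestation day 100, with conception 120-200 days
after kidding and 10% of goats open; genetic coefficient vectors drawn down
the pedigree (founders N(0, K_g), offspring = parent average + Mendelian
deviation scaled by parental inbreeding); independent PE vectors; and
Gaussian residuals with the 9-class variance profile.

Default components (milk-yield scale, kg/day): `K_g = diag(0.40, 0.040,
0.012, 0.006, 0.003)` — diagonal-dominant so the first principal component
carries ~88% of genetic variance, the structure the rank-2 reduction
presumes — `K_p = diag(0.35, 0.050, 0.015, 0.008, 0.004)`, residual profile
(0.45, 0.35, 0.30, 0.28, 0.28, 0.28, 0.30, 0.35, 0.50) (higher at both
ends of lactation).  These give daily heritabilities around 0.25-0.33,
realistic for dairy-goat milk yield.  The default population is 50 AI
sires x 20 daughters in 40 herds (the progeny filter requires >= 20
daughters per sire) with 200 shared dams; an optional two-generation mode
(`phenotyped_dams=True`) records the dams themselves in an earlier cohort,
emulating multi-year recording schemes, which strengthens the
genetic-vs-PE separation.

What the generator does **not** emulate: multiple parities, cross-trait
genetic correlations (each trait is simulated and modeled separately),
culling/selection over time, missing-at-random recording gaps, herd-size
heterogeneity, and real calendar irregularities.  Passing recovery tests
therefore demonstrates correctness of the estimation machinery under the
model's own assumptions, not robustness to violations of them.

## Problem sizes and tolerances in the test suite

The tests run the full analysis at deliberately moderate sizes chosen so
the whole suite completes in minutes on one CPU: oracle checks on tens of
records; REML recovery on 20 replicates of 16 sires x 20 daughters
(~2,300 records each, order-2 truth), asserting that the replicate-mean
estimate of K_g is within 30% relative Frobenius distance of truth and the
mean daily heritability at DIM 150 within +-0.05 — means across replicates
are the right target at this scale, where single-replicate REML estimates
of a 3x3 genetic covariance from 16 sire families are intrinsically noisy;
model comparison (leg0/leg2/leg4 + leg2R2) on one such dataset; and the
acceptance script's headline run at the default 50 x 20 population with a
leg4 fit capped at a few AI iterations, which is ample for EBV
correlations (the level measures correlate >= 0.99 long before the
variance components converge to full precision).

## Known limitations

* REML trace terms use a dense inverse; systems beyond ~15k equations need
  a sparse-inverse (Takahashi) or Monte-Carlo trace path that is not
  implemented.
* The AI/EM/Aitken iteration reports the best visited point; on nearly flat
  likelihood surfaces (tiny eigenvalues of K_g) different stopping points
  can differ slightly in the small coefficients.
* `predict` on records of unseen herd-test-date levels sets that effect
  contribution to zero rather than refusing.
* The gestation spline is allowed a step at g = 30 -> 31; its size depends
  on the fitted coefficients and is not constrained to zero.
* LACT fat/protein *content* traits (component total / milk total) require
  jointly simulated component yields, which the single-trait generator does
  not produce; the LACT machinery itself is trait-agnostic.
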