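# Methods

`krpower` computes approximate power for the Kenward–Roger (KR) scaled Wald
test of fixed effects in homoscedastic Gaussian linear mixed models with
*fixed, known* missing-data patterns, and validates the approximation by
Monte Carlo simulation of the actual REML + KR analysis.

## Model and assumptions

Each independent sampling unit (a participant, or a cluster of participants)
contributes `y_i = X_i beta + e_i`, `e_i ~ N(0, Sigma_d)`, independently
across units. Units are grouped by *observation pattern* `R_d`, a subset of
the `p` planned observation rows; `Sigma_d` is the principal submatrix of a
single maximal covariance `Sigma_max` at the observed rows. This
homoscedasticity is a strong assumption: it excludes random slopes, group
differences in variance, and time-varying covariates (covariates must be
constant within a unit). The hypothesis is `H0: C beta = theta0` with `C` of
full row rank `a`, tested at level `alpha`.

The patterns are part of the *design*: the method computes power for a
planned study whose dropout structure is specified in advance. Random
missingness is out of scope.

## The power approximation

The KR statistic is `F_R = lambda * w_R`, a scaled Wald statistic at REML
estimates with a small-sample adjusted covariance. Its distribution under
the alternative is approximated in four steps.

1. **Exact contrast moments.** The weighted-least-squares contrast estimate
   has `mu = C beta - theta0` and covariance
   `Sigma_x = C (X_s' Sigma_s^-1 X_s)^-1 C'`, accumulated pattern block by
   pattern block (no dense stacked matrix is formed).

2. **Single inverse-Wishart law for the information matrix.** Each pattern's
   covariance estimate behaves like a multivariate-model residual
   covariance, `Sigma_hat_d ~ W_{p_d}(N_d - q, Sigma_d/(N_d - q))`, where
   `q` is the rank of the between-unit design of the pattern's
   "multivariate recast" (the number of treatment conditions for parallel-arm
   designs). The estimated information matrix
   `X_s' Sigma_hat_s^-1 X_s = sum_d sum_i X_i' Sigma_hat_d^-1 X_i`
   is approximated by a single inverse Wishart matched to (i) the exact
   expectation of the sum and (ii) the variance of its trace **computed as
   if each unit's summand carried an independent inverse Wishart**. The
   independence treatment is deliberate and load-bearing: it is the
   assumption under which the underlying trace-variance additivity holds,
   and dropping it (i.e. accounting for the fact that units in a pattern
   share one covariance estimate) inflates the trace variance by roughly the
   pattern unit count, collapses the matched degrees of freedom, and makes
   the approximation visibly conservative for multi-row contrasts (we
   measured Wald-moment errors of ~25% under the dependence treatment versus
   <1% under independence, against a brute-force simulation of this very
   model). Both laws are available on the term objects; the pipeline uses
   independence.

   The matched degrees of freedom solve a one-dimensional trace-variance
   equation. With `M` the exact mean, `t1 = tr(M)^2`, `t2 = ||M||_F^2`, `v`
   the trace variance and `x = df - K`, the equation
   `[2 t1 + 2 (x - 1) t2] / [x (x - 3)] = v` is monotone on `x > 3` with a
   unique root; a bracketed root-finder is authoritative and the equivalent
   quadratic closed form is verified against it on every call. Degrees-of-
   freedom conventions for the inverse Wishart differ across texts; all
   internal moment formulas are parameterized by the Wishart degrees of
   freedom of the un-inverted matrix and are unit-tested against a sampling
   oracle, which removes the ambiguity.

3. **Scaled noncentral-F law for the unscaled Wald statistic.** With the
   contrast information approximately Wishart, `w` is a ratio of a Gaussian
   quadratic form to an independent Wishart form. The numerator
   `U = x' Sigma_W^-1 x` is collapsed to `lambda_u chi2_{n_u}(delta_u)` by a
   three-moment match (null mean, alternative mean, alternative variance) —
   solved directly from the matching equations in ratio form, with the
   `mu = 0` case handled by the explicit two-moment (Satterthwaite) branch
   because the general ratio degenerates to 0/0 there. This yields
   `w ~ tr(Q)/[a(n + a - 1)] * F(n_u, n + a - 1, delta_u)` with
   `Q = Sigma_W^-1 Sigma_x`. (The classical Hotelling-type result would put
   `n - a + 1` in the denominator; the method is defined, and was validated,
   with `n + a - 1`, and this package follows it. The two coincide for
   single-row contrasts.)

4. **Noncentral-F match for the scaled statistic.** From the null mean `E0`,
   alternative mean `EA` and alternative variance `VA` of `w`, set
   `rho = VA/(2 E0^2)`, `gamma = a (EA/E0 - 1)`,
   `nu = 4 + [2(a + 2 gamma) + (a + gamma)^2]/(rho a^2 - a - 2 gamma)`, and
   `lambda = nu / [(nu - 2) E0]`. At `gamma = 0` this reduces to the
   familiar KR null form `nu = 4 + (a + 2)/(a rho - 1)` — a permanent unit
   test, together with numerical verification that the matched F carries all
   three moments. Power is `1 - F(f_crit; a, nu, gamma)` at
   `f_crit = F^-1(1 - alpha; a, nu)`. The method refuses (with an actionable
   message) rather than clamps when the moments leave the matchable domain
   (`nu` would not exceed 4); silent clamping would mask approximation
   breakdown.

`nu` is real-valued, as in KR practice. Admissibility requires
`N_d > q + p_d + 1` for every pattern (first moments) and effectively
`N_d - q > p_d + 3` (trace variances); cluster-randomized designs satisfy
this through the **cluster-mean recast**: each cluster becomes a single
observation with variance `1' Sigma_d 1 / p_d^2`
(`sigma^2 [1 + (p_d - 1) rho]/p_d` under compound symmetry), one
1-dimensional pattern per distinct cluster size. The recast is what makes
large-cluster designs admissible, and it is the representation the analytic
pipeline consumes for cluster designs; the simulation arm always works at
the member level.

## The worked example

The packaged `oral_cancer` fixture encodes a worksite smoking-cessation
trial: 80 clusters in two arms (25 of size 30 and 15 of size 20 per arm),
outcome standard deviation 125 ng/ml, intraclass correlation 0.04, a
25 ng/ml program difference, `alpha = 0.05`. The published account of this
example prints its design matrices inconsistently (one cell shows a
rank-deficient single column, another mixes reference and cell-means
coding); the only coding consistent with the stated contrast `[1 -1]`,
coefficient vector `(25, 0)` and a 25 ng/ml arm difference is cell means,
which the fixture uses. This implementation computes power **0.8954**
(reported as 0.90 at two decimals), where the original report gives 0.87.
Our own simulation arm — REML plus the KR test, verified to reproduce an
independent reference implementation of the test to four decimals — puts
the Monte Carlo truth for this design at 0.9015 (se 0.0067, 2000
replicates), so the value computed here deviates from the simulation truth
by −0.007, inside the deviation range the approximation shows elsewhere. We
were unable to reproduce 0.87 from the published formulas under any
convention we tried; the discrepancy is documented rather than patched.

## Validation arm

The simulation machinery re-enacts the planned analysis:

* **Simulation** draws `y_i = X_i beta + e_i` per unit through the Cholesky
  root of each pattern covariance; all stochastic operations are pure
  functions of `(inputs, seed)`.
* **REML** maximizes the restricted likelihood of a parametric covariance
  family (`iid`, `cs` as variance components `v_e I + v_b J`, `ar1`,
  `unstructured`) over unconstrained transforms (log variances,
  `arctanh` correlation, Cholesky factors), Nelder–Mead with
  method-of-moments starts, a diagonal fallback start, tolerance `1e-8`,
  iteration cap 200 per parameter. Everything is computed from per-group
  sufficient statistics `(sum y y', sum y)`, so a likelihood evaluation
  costs `O(p^3)` regardless of the number of units. Non-converged
  replicates are excluded from rejection proportions, counted, and flagged
  when they exceed 1%.
* **KR test** at the fitted covariance: adjusted covariance
  `Phi_A = Phi + 2 Phi [sum_kl W_kl (Q_kl - P_k Phi P_l - R_kl/4)] Phi` with
  `W` twice the inverse expected REML information, and the standard
  moment-based denominator degrees of freedom and scale. Derivatives of
  `Sigma` with respect to the covariance parameters are analytic for every
  family; the second-derivative term vanishes for linear families and is
  included for AR(1). Parameterizations are chosen to match standard
  software (variance-component compound symmetry), because the adjustment is
  parameterization-dependent through the second-derivative term. The
  implementation reproduces, to four decimals, the denominator df, scale
  and statistic of `pbkrtest::KRmodcomp` on five frozen synthetic
  random-intercept datasets (`fixtures/kr_reference_synthetic.json`), and
  collapses exactly to the classical ANOVA F test (including `nu = N - t`)
  in complete balanced iid layouts.

### Design grids

`build_cluster_grid` crosses arms `t in {2,4}`, clusters per arm
`{10,40}`, complete cluster size `{5,50}` and incomplete-size ratio
`{0.6,0.8,1}` (half the clusters incomplete when the ratio is below 1),
keeps the member-level-admissible combinations (16 of 24 survive
`N_d > q + p_d + 1` with `q = t`), and expands over intraclass correlations
`{0.04,0.1,0.2,0.5}` and target powers `{0.2,0.5,0.8}`; the outcome variance
is 2 and coefficients are `b * e_1` in cell-means coding.
`build_longitudinal_grid` crosses `t in {2,4}`, monotone (`{1,2,3}`
observed) versus non-monotone (`{1,3,5}`) dropout and `{0,10,20}` incomplete
participants per 50-per-arm group, AR(1) errors with variance 1 and
correlation 0.4, hypothesis the time-by-treatment interaction — 12
structural designs, 36 with the three effect targets. Effect scales `b` are
calibrated by root finding so the *approximate* power hits the target —
calibration against the approximation itself, not against simulation.

Deviation = approximate − empirical power (positive means the approximation
is optimistic). Summaries are reported overall and stratified by design
type, arms, cluster size, incompleteness ratio, intraclass correlation,
dropout pattern, and number incomplete.

At desk scale (four designs, 1000 replicates) we observe deviations of
roughly −0.01 to +0.05, with the largest positive deviations on
small-cluster, higher-correlation cluster designs — the same regime where
the original study reports its largest deviations (up to +0.06). The full
grids at 10,000 replicates are an overnight job
(`make full-validation`, or `scripts/full_validation.py`), writing
per-design CSV, stratified JSON summaries, and deviation box plots; it is
not part of the test suite.

### What the generator does and does not emulate

The synthetic data are exactly the model the approximation assumes:
Gaussian, homoscedastic across units, with missingness fixed by design.
Passing validation therefore demonstrates the quality of the *distributional
approximations* (Wishart matching, moment matching), not robustness to
model violations — real studies with random dropout, non-Gaussian outcomes,
or unit-level heteroscedasticity are outside what these tests can certify.

## Numerical choices

* Pattern blocks everywhere; no `n x n` covariance is materialized (a dense
  construction exists only as a test oracle).
* Matched-df root finding: `brentq` on a bracket expanded geometrically,
  `xtol 1e-12`; closed-form quadratic cross-checked on every call.
* Positive-definiteness via Cholesky; symmetric matrices re-symmetrized
  after accumulation to suppress roundoff drift.
* Power values are reported at full precision; two-decimal rounding is
  applied only when quoting the worked example.
* Results are stable to relative `1e-6` under group reordering and
  `1e-12`-scale perturbations of `Sigma_max` (tested).

## Known limitations

* The `N_d > q + p_d + 1` rule can be restrictive for member-level
  multilevel designs with large clusters; use the cluster-mean recast.
* The approximation degrades for multi-row contrasts in small samples; the
  refusal guards surface this rather than extrapolate.
* Only `iid`, `cs`, `ar1` and `unstructured` covariance families are
  implemented in the validation arm; binary/Poisson outcomes and random
  missingness are out of scope.
* The worked-example discrepancy above (0.895 vs the published 0.87) is
  unresolved against the original report, but our value is closer to the
  Monte Carlo truth for that design.
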