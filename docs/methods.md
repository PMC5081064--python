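# Methods

## Model representation

A model is a list of observed/latent variables plus parameters of four kinds
— loadings, regressions, covariances, variances — each free, fixed, or tied
by an equality label. Everything is compiled into a reticular (RAM)
parameterization: one directed-coefficient matrix **B** over all variables
(loadings are simply factor→indicator coefficients) and one symmetric
residual matrix **Ψ**, giving the implied covariance
Σ(θ) = [(I−B)⁻¹Ψ(I−B)⁻ᵀ] restricted to observed rows/columns. Directed
cycles are rejected at validation; all models in the battery are acyclic.

Means are not modelled: the analysis is covariance-only, which matches the
convention of standardizing every variable before fitting. Degrees of
freedom are therefore p(p+1)/2 − q, with q the number of distinct free
parameters after equality-label merging.

Implicit parameters follow the conventions users of mainstream SEM software
expect: every variable gets a (residual) variance unless one is declared;
exogenous observed regression predictors intercovary freely (this is what
makes the MIMIC model's six speed measures and the watershed model's ten
tracts saturated within level); and a latent factor with no explicit scale
constraint has its first loading fixed to 1 with the factor (disturbance)
variance free. Fixed-loading identification was chosen over fixed-variance:
the two parameterizations have identical degrees of freedom and identical
fit, so the choice is cosmetic, and the fixed first loading makes generating
truths expressible directly in the fitted parameterization. Declaring both a
fixed loading and a fixed factor variance raises an identification-conflict
error (suppressible for fully-fixed generating tables).

## Estimation

The normal-theory discrepancy F = ln|Σ| + tr(SΣ⁻¹) − ln|S| − p is minimized
by L-BFGS-B with an analytic gradient assembled from
dF = tr((Σ⁻¹ − Σ⁻¹SΣ⁻¹)dΣ) in O(k³) per evaluation (k = number of
variables). The test statistic is T = (N−1)·F with S computed with
denominator N−1 (the Wishart convention). All fitted models here are
scale-invariant, so the alternative N·F convention differs only by the
factor N/(N−1); the Wishart pairing is used throughout and documented here
once.

Start values: 0.5 for loadings and paths, half the observed (co)variance for
the observed block of Ψ, 0.5 for latent variances. Because each observed
sub-block of the Ψ start is half a principal sub-block of S, the starting
implied covariance is positive definite whenever S is; if fixed nonzero
entries ever break this, covariance and path starts are halved until
feasible. Non-positive-definite trial points during optimization return a
large penalty so line searches back off. After L-BFGS-B, a Fisher-scoring
polish (Newton steps on the expected Hessian 2ΔᵀVΔ with Armijo backtracking)
runs until the gradient max-norm falls below the tolerance (1e-8 on F by
default); this cracks the ill-conditioned valleys produced by near-singular
covariance input or just-identified models. Fitting is fully deterministic —
no random restarts.

A non-positive-definite sample covariance is refused by default; with
`ridge=True` the diagonal is lifted just past singularity (1e-6 of the mean
diagonal beyond the most negative eigenvalue) with a loud warning.
Negative estimated residual variances (Heywood cases) are flagged, never
constrained away. Sample size must satisfy N ≥ p+1.

Standard errors come from the inverse expected information
I = (N−1)·ΔᵀVΔ, where Δ = ∂vech Σ/∂θ and V = ½Dᵀ(Σ⁻¹⊗Σ⁻¹)D. With raw data
available, the asymptotic covariance Γ of √N·vech(S) is estimated from
fourth-order sample moments and the fit is augmented with sandwich standard
errors (Δ-bread, Γ-meat) and the Satorra–Bentler scaled statistic
T/c, c = tr(UΓ)/df, U = V − VΔ(ΔᵀVΔ)⁻¹ΔᵀV. Under multivariate normality
c → 1 and the sandwich collapses onto the expected-information errors, which
the tests verify by simulation. Scaled fit indices use the scaled statistics
of both the target model and the independence baseline; a warning is issued
when N is small relative to the p(p+1)/2 fourth-moment count.

## Fit indices, comparison, diagnostics

* RMSEA = √(max(T−df,0)/(df(N−1))); its 90% interval inverts the noncentral
  χ² CDF at 0.95/0.05 by bracketed root-finding, with the interval pinned to
  0 when the central CDF already falls below the target. df = 0 reports
  RMSEA as not applicable.
* CFI = 1 − max(T−df,0)/max(T−df, T₀−df₀, 0) against the independence
  baseline (free variances, zero covariances), which has the closed form
  T₀ = (N−1)(Σᵢ ln sᵢᵢ − ln|S|), df₀ = p(p−1)/2 — no optimization.
* SRMR is computed on correlation-metric residuals over the p(p+1)/2 lower
  triangle; with standardized variables this is numerically almost identical
  to the covariance-metric version.
* AIC is reported on the discrepancy scale, T + 2q, so AIC differences
  between models fit to the same data equal full-likelihood AIC differences.
* Nested comparisons check structural nesting (the restricted model's free
  rows are a subset of the full model's, df ordered accordingly) and report
  the plain Δχ², and — when both fits carry scaling factors — the scaled
  difference with c_d = (df_r·c_r − df_f·c_f)/Δdf, falling back to the plain
  statistic if c_d ≤ 0.
* Modification indices are univariate score statistics
  MI = g²/(I_cc − I_cθI_θθ⁻¹I_θc) over all fixed-at-zero loadings,
  regressions and covariances that keep the graph acyclic, with expected
  parameter changes; candidates with numerically singular information are
  skipped. Ties in the descending sort are broken by enumeration order
  (table order, then variable order).
* R² per endogenous variable is 1 − ψᵥᵥ/implied total variance, clipped into
  [0, 1] with a message when a Heywood case pushes it outside.

## The battery

`run_battery` executes, in a fixed order: the four-indicator measurement
model; three PS dimensionality models (single factor; speed/consistency
factors; per-task factors); the ten-tract single-factor model; the MIMIC
model with zero-path, equal-path and strongest-path-only (choice-RT speed)
competitors; the full watershed model with zero-path,
strongest-tract-only (forceps minor), tract-specific and
measure-specific competitors; the covariate-adjusted model when binary
health covariates are configured (covariates predict every tract and
intercovary freely — the structure consistent with the battery's covariate
degrees of freedom); the inverted-hierarchy AIC contest; all C(10,6) = 210
tract-subset contests (watershed versus inverted on the same subset, upper
levels identical); and a modification-index scan. "Strongest" sources are
inputs, never auto-selected, so the battery is deterministic; identical
input and configuration produce byte-identical reports. Failed stages are
recorded with their error and the battery continues.

One deliberate reading: the tract-specificity competitor ties each tract's
effect to be equal across the six speed measures, which for a 10×6 path
block imposes 50 constraints (60 paths → 10 tied values). The builder
implements exactly this verbal constraint.

Verdict bands: RMSEA good < 0.05, acceptable 0.05–0.08; CFI good > 0.97,
acceptable 0.95–0.97; SRMR good < 0.05, acceptable 0.05–0.10.

## Synthetic data

The generator draws from the implied covariance of a fully-valued truth.
The paper-like profile encodes, by construction rather than by fitting:

* a two-community tract correlation structure (anterior vs posterior
  bundles, r = 0.55 within, 0.35 between) that a single factor cannot
  absorb;
* a sparse tract→speed path pattern in which the forceps minor predicts five
  of the six speed measures (strongest for choice-RT speed and consistency,
  ≈0.3) and the corticospinal tract contributes to speed measures (≈0.1–0.15),
  leaving per-measure upstream R² around 0.05–0.20;
* residual speed-measure correlations strongest within task (0.55; 0.45 for
  the uninstructed audio-visual task), 0.35 within measure type, 0.25
  otherwise;
* speed→FI paths with a zero simple-RT-speed path and a modestly negative
  audio-visual-speed path, scaled as one block so the population R² of
  latent FI is exactly 0.586 — the calibration anchor for the whole profile,
  chosen because it is the one headline magnitude the profile must
  reproduce; per-path magnitudes are the package's own design;
* standardized loadings (0.85, 0.80, 0.75, 0.70), expressed in the
  unit-first-loading parameterization, and unit implied variances for every
  observed variable.

The null-hierarchy profile adds direct forceps-minor→FI (0.28) and
corticospinal→FI (0.16) paths, sized so the misspecified watershed model's
population RMSEA clearly exceeds the 0.05 "good" bound — the property that
defines the profile. The single-factor profile generates all 20 variables
from one common factor (loadings 0.55/0.75/0.80 by level), collapsing the
hierarchy.

Non-normal data use the Vale–Maurelli construction: third-order (Fleishman)
polynomial marginals solved for the target skewness and excess kurtosis,
applied to correlated normals whose intermediate correlations are solved per
pair from the cubic moment relation. Achieved covariances are exact to that
cubic approximation; marginal moment targets are exact in expectation.
Infeasible skewness/kurtosis pairs (below the polynomial boundary) are
rejected. All randomness flows from explicit seeds through
`numpy.random.default_rng`; replicate streams are spawned from a
`SeedSequence`, so runs are reproducible at the level of the documented
generator algorithm. No hidden global state; the CLI requires explicit
seeds.

What the generator does *not* emulate: measurement non-invariance across
age, floor/ceiling effects in subtest scores, missingness, site or scanner
effects, and any genuinely nonlinear tract–behaviour coupling. Passing
recovery and discrimination tests on these data therefore demonstrates the
correctness and calibration of the estimation machinery under the stated
conditions, not robustness of the scientific conclusions to those
real-data complications.

## Monte-Carlo problem sizes

Parameter recovery and the hierarchy-discrimination contest use 200
replicates at N = 555; χ² calibration uses 1000 replicates at N = 500.
These sizes give binomial standard errors of ≈1.5% on per-parameter
coverage and ≈0.7% on a 5% rejection rate, adequate for the bands they are
checked against. One known property at this scale: with 150 free
parameters and 210 sample moments at N = 500, the plain ML χ² of the full
model over-rejects mildly (mean T ≈ 61 against df = 60; empirical type-I
rate ≈ 6.5–7.5% across seeds at α = 0.05). This is the familiar
finite-sample behaviour of the likelihood-ratio statistic in heavily
parameterized covariance models, not an optimizer artifact — the gradient
norm at the reported optimum is below 1e-8, and tightening tolerances does
not change T. Calibration at smaller model sizes (e.g. the four-indicator
measurement model) is nominal.

## Numerical conventions

Tolerances: optimizer gradient tolerance 1e-8 on F; convergence flag
requires a final gradient max-norm below max(1e-5, 100·gtol). Symmetry
tolerance on covariance input 1e-8 (symmetrized with a log message beyond
machine noise, refused beyond tolerance). RMSEA CI root-finding to 1e-12 in
the noncentrality parameter. Equality of reported numbers is always checked
with tolerances in tests, never by string comparison; serialized reports
round to 3 decimals for indices and 6 for estimates.

## Known limitations

No mean structures, multi-group models, ordinal indicators, missing-data
ML, bootstrap errors, or Bayesian estimation. Modification indices are
univariate (no multivariate joint scan). The Satorra–Bentler machinery
requires raw data; a covariance matrix alone yields plain ML statistics.
Published point statistics for the original cohort depend on its
restricted-access covariance matrix; with such a matrix supplied via
`read_covariance`, the same pipeline reproduces that analysis by variable
name, but the repository validates against its own calibrated synthetic
truths instead.
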