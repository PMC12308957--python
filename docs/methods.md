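# Methods

## Model

`dynacor` fits, per gene pair, a seven-parameter distributional regression
along pseudotime z with groups g ∈ {1..G} (group 1 is the reference /
wild-type):

* **Margins.** Positive expression follows a Gamma distribution
  parametrized by mean μ and coefficient of variation σ (shape 1/σ², scale
  μσ²), so E W = μ and Var W = σ²μ². This suits normalized continuous
  single-cell measurements and captures over-dispersion directly through σ.
* **Dependence.** The two positive components are joined by a Gaussian
  copula with correlation ρ. The copula density is evaluated on the
  Gamma-CDF-transformed values; the transformed values are clamped into
  [1e−12, 1 − 1e−12] before the normal quantile, and |ρ| is kept below
  1 − 1e−8, so the likelihood stays finite without visibly perturbing it.
* **Zeros.** Independent Bernoulli masks D_j ~ Bern(p_j) produce exact
  zeros (detected by equality with 0.0 — zeros are structural, not a
  threshold). The joint CDF of the zero-inflated pair combines the four
  zero/non-zero cases so the four masses sum to one; the bivariate normal
  CDF needed by the both-positive case is computed by a fixed 48-node
  Gauss–Legendre rule on the correlation-integral identity (deterministic,
  ~1e−14 accurate).
* **Likelihood.** Cells contribute 0 (both zero), a marginal log-density
  (one zero), or the full copula term (both positive). The additive
  constant that depends only on (p₁, p₂) is dropped: the zero rate equals
  the marginal zero probability, so (p₁, p₂) are estimated independently by
  penalized logistic regression on the zero indicators, and the copula-side
  parameters never see them. A consequence tested explicitly: relocating
  both-zero cells in pseudotime changes the zero-inflation fits but not the
  copula-side curves.

## Additive predictors and smooths

Each parameter is linked to an additive predictor (log for μ and σ, tanh⁻¹
for ρ, logit for p) built from an intercept, optional group dummies
(reference group 1 has none), optional unpenalized linear terms, and
penalized smooths. By-group smooths occupy disjoint column blocks with
zero rows outside their group, each with its own smoothing parameter, which
is what makes simultaneous multi-group trajectory comparison possible. A
shared-smooth option for σ (one s(z) across groups, no group intercept) is
available for datasets where relative dispersion is believed common.

Smooths are low-rank thin plate regression splines for one covariate: the
full thin plate problem on the knots (all unique pseudotimes, quantile
down-sampled above 2000 — the eigen-decomposition is cubic in the knot
count) is truncated to the leading J eigenvectors of the radial kernel
|r|³/12, the two null-space constraints are absorbed, and the penalty is
the integrated squared second derivative expressed in the truncated
coordinates. The constant is removed by column-centering (the sum-to-zero
identifiability constraint), leaving J − 1 columns per smooth: J − 2
penalized "wiggly" directions plus an unpenalized linear trend. Columns are
rescaled to unit standard deviation (penalty congruence-transformed) for
conditioning. Default J = 10; the truncation error of J = 10 against a
full-rank thin plate spline is ~2e−3 RMS for a one-period sinusoid over the
usual pseudotime span and vanishes as J grows (the suite checks 1e−6
agreement at J = 40).

## Estimation

The copula-side coefficient vector δ (stacked μ₁, σ₁, μ₂, σ₂, ρ blocks)
maximizes ℓ_p(δ) = Σℓᵢ − ½δᵀSδ with S block-diagonal, λ_b D_b per smooth
block and exact zeros at fixed-effect positions. The outer loop alternates:

1. **Trust-region Newton step.** The quadratic model of −ℓ_p (gradient and
   Hessian at the current δ, negative Hessian eigenvalue-floored at 1e−7)
   is minimized within the radius; the boundary subproblem is solved
   exactly in the eigenbasis by root-finding on the shift. Steps are
   accepted when the ratio of actual to predicted improvement exceeds 1e−4;
   the radius shrinks ×0.25 below ratio 0.25, doubles above 0.75 when the
   step hits the boundary, and 30 consecutive rejections abort the fit
   (reported as non-converged, never an exception at the screen level).
2. **Smoothing-parameter update.** With R'R the floored negative
   unpenalized Hessian B₀ and working data ẑ = Rδ + R⁻ᵀg₀, each λ_b
   minimizes the prediction-error criterion
   V(λ) = ‖ẑ − Rδ_λ‖²/n − 1 + 2γ·edf(λ)/n, where
   δ_λ = (B₀ + S_λ)⁻¹(B₀δ + g₀) and edf = tr((B₀ + S_λ)⁻¹B₀), by bounded
   scalar search on log λ per block (coordinate descent, λ ∈ [1e−6, 1e10]).
   Rank-r Woodbury identities around one factorization per sweep make each
   candidate O(r³), so selection is never the bottleneck. The inflation
   factor γ (config `smoothness_inflation`) defaults to 1.4, the customary
   protection of prediction-error criteria against occasional severe
   undersmoothing; γ = 1 recovers the plain criterion, and `lambda_fixed`
   bypasses selection entirely.

Iteration stops when |Δℓ_p| < 1e−7 and the gradient max-norm is below
1e−5 (or after 200 outer iterations / three stagnant iterations; the
convergence flag then reflects the gradient check). Start values are
method-of-moments: log of the non-zero means and CVs, ρ from Spearman's
correlation of the double-positive cells through the sine transform,
smooth coefficients zero, smoothing parameters one.

**Derivatives.** Per-cell first and second derivatives with respect to the
five predictors are obtained by central differencing (step 1e−4) of the
exactly vectorized per-cell likelihood in predictor space; the chain rule
through the linear designs is exact. This is accurate to ~1e−7 (gradient)
and ~1e−5 (Hessian) — the suite enforces agreement with direct finite
differences of ℓ_p at 1e−4 / 1e−3 — and keeps one code path for any
marginal family. The logistic fits use their closed-form derivatives.

## Inference and screening

* **ρ(z) ≡ 0.** All coefficients of the ρ predictor (intercept included)
  enter a Wald quadratic form with the penalized covariance
  (B₀ + S)⁻¹, rank-truncated at the rounded effective degrees of freedom,
  against a χ²(edf) reference. Under the null the intercept and linear
  trend are unpenalized, so the statistic is essentially an exact
  two-degree Wald test plus a small shrunken remainder; empirical type-I
  error sits at the nominal 5% (the acceptance study recomputes this).
* **Group-identity nulls.** "Both groups share one curve" (for ρ, or for a
  gene's zero-inflation curve) is tested by a likelihood ratio between the
  by-group model and a shared-single-smooth null, with a χ² reference on
  the difference of the predictors' effective degrees of freedom. This
  edf-calibrated reference is approximate: null simulations show mild
  anticonservatism (roughly 10–13% rejection at nominal 5% in small runs)
  while the p-value distribution remains close to uniform. Screens should
  treat borderline adjusted p-values accordingly; a permutation reference
  would be the rigorous (and much costlier) alternative and is out of
  scope.
* **Metrics.** Fitted ρ curves for the two groups are compared on an
  evenly spaced grid (default 100 points over the overlap of the groups'
  pseudotime ranges, so neither curve extrapolates; full-union span
  optional): Δ|ρ̂| is the mean absolute difference, |Δρ̂|max the maximum
  (bounded by 2), and AUD the Riemann integral of the absolute difference —
  identically span × Δ|ρ̂| on uniform grids. Benjamini–Hochberg adjustment
  runs across all attempted pairs; failed pairs propagate NaN and do not
  count toward the number of tests.
* **Confidence bands** for any fitted curve use the penalized coefficient
  covariance on the predictor scale mapped through the inverse link, so
  interval endpoints always respect parameter domains.

## Diagnostics

Quantile residuals for non-zero observations are r̂ = (1 − p̂)Φ⁻¹(F_GA(y)),
with zeros assigned uniform draws from (0, p̂] (seeded, reproducible).
These down-weighted residuals are the primary reporting convention; a
`variant="randomized"` option implements the fully randomized construction
Φ⁻¹(p̂u + (1 − p̂)F_GA(y)) for non-zero values and Φ⁻¹(p̂u) for zeros,
which is exactly standard normal under a correctly specified model — note
the *pooled* residual set is normal; the non-zero subset alone is truncated
normal. Q–Q summaries plot sorted residuals against normal order-statistic
medians (zero-cell residuals excluded by default, since in the primary
convention they live on the probability scale).

## Synthetic data

The generator draws a latent bivariate standard normal with the cell's ρ,
maps it through the normal CDF and Gamma quantiles, and applies the
Bernoulli masks. Four built-in scenarios define the study conditions used
by the tests and the acceptance script; pseudotime is uniform on (0, 27)
except scenario IV:

* **I (linear):** η_μ1 = 0.02z − 0.4, η_μ2 = −0.03z + 0.3, η_ρ = −0.02z;
  σ = (0.2, 0.27), p = (0.45, 0.30).
* **II (non-linear, one group):** μ₁ = e^{0.02z−0.3},
  μ₂ = 0.5cos(0.2z − 0.1) + 1, ρ = tanh(0.5 − e^{−0.2z}); σ = (0.2, 0.27),
  p = (0.40, 0.35). Emulates a developing-tissue pattern: one mean rising,
  one U-shaped with its minimum near pseudotime 16, correlation climbing
  from ≈ −0.46 through zero to a stable ≈ +0.46.
* **III (two groups, 55% wild-type / 45% mutant):** group-specific means
  (quadratic vs double-exponential for gene 1; sinusoid-exponential vs
  decaying exponential for gene 2), dispersions σ₁ = (0.2, 0.3) and
  σ₂ = (0.3, 0.4) by group, correlations tanh(0.4(0.2z − 1)) (wild-type,
  crossing zero at z = 5) vs tanh(−0.01z + 0.2) (mutant, weak), and four
  distinct sigmoid zero-inflation trajectories.
* **IV (power sweep):** constant margins μ = (5, 3), σ = (1/3, 1/2),
  p = (0.3, 0.4), and ρ = tanh(C(0.5sin(2πz) − 0.8 + 1.6z)) with
  z ~ U(0, 1) — one sine period with a symmetric linear ramp, so C = 0 is
  the exact zero-correlation null and growing C departs from it smoothly.
  The z-law is a package choice (configurable); the (0, 1) domain is the
  natural period of the sine term.

What the generator does **not** emulate: UMI/count-level noise, library-size
normalization artifacts, pseudotime-inference error (pseudotime is treated
as known), multiple lineages/branching, and dependence between the zero
masks and the latent positive values. Passing tests therefore demonstrate
correct recovery of the model's own data-generating process, not robustness
to real-data violations of it.

## Replicated studies (sizes and fit structure)

The parameter-recovery harness fixes one pseudotime draw across replicates
(so each cell has a well-defined truth), re-samples expression per
replicate, refits, and evaluates cell-averaged
bias = (1/N)Σᵢ|mean_l θ̂_il − θᵢ| and RMSE = (1/N)Σᵢ√(mean_l(θ̂_il − θᵢ)²).
The fit formulas mirror the generating structure: parameters constant (per
group) in truth are modelled as intercepts (plus group effects), trending
parameters get smooths, and the linear scenario is fitted with unpenalized
linear predictors — matching how the reference evaluation's printed
constant-parameter errors scale (they equal intercept-only sampling error).
Desk-scale replicate counts are 100 (scenario II at n = 1000; scenario I
coefficient coverage at n = 500 and 1000), 50 (scenario II at n = 3000;
scenario III at n = 2000), and 60 for the type-I error of the ρ-zero test,
keeping the whole suite near six minutes on one CPU at Monte-Carlo
tolerances of roughly ±15% (RMSE), ±30% (bias), and ±0.03 (rejection
rate).

## Numerical choices and edge cases

* Non-finite likelihood at a proposed trust-region step is treated as a
  rejection (radius shrinks), never an exception mid-fit.
* Hessian indefiniteness is handled by eigenvalue flooring at 1e−7 before
  the subproblem and before forming covariances.
* Eigenvector signs in the spline truncation are fixed (largest-magnitude
  component positive), and the Lanczos start vector is constant, so bases —
  and therefore entire fits and screens — are bit-reproducible and
  independent of pair-processing order.
* Genes with no zeros (or only zeros) yield a flagged, non-informative
  zero-inflation fit and NaN group-difference tests; screens record NaN and
  continue.
* The `min_cells` guard (default 50 double-positive cells) refuses pairs
  with too little dependence information for a copula fit.

## Known limitations

* The χ²(Δedf) reference of the likelihood-ratio curve tests is
  approximate (see above); the ρ-zero Wald test is the calibrated one.
* K = 1 continuous covariate (pseudotime) per smooth; no tensor-product
  smooths, no branching trajectories, single spline family (thin plate).
* Gamma margins only; count-data margins (negative binomial, Tweedie) are
  out of scope for this version, as is any pseudotime inference or
  uncertainty propagation from it.
* The basis dimension default (J = 10) is a convention, not a fitted
  quantity; strongly oscillatory trajectories need a larger J.
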