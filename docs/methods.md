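# Methods

## The problem and the model

An observed questionnaire score decomposes, under classical test theory, as
X = τ + ε with error uncorrelated with the true score, so
σ²_X = σ²_τ + σ²_ε and reliability rel = σ²_τ/σ²_X. A standardized mean
difference computed on observed scores therefore shrinks by √rel relative
to the true-score effect; `ctt_attenuation` expresses this closed form
(error variance, observed variance, attenuated d, percent bias), and all
downstream machinery exists to measure the same phenomenon in item-level
data rather than by formula.

The item-level model is a unidimensional congeneric ordinal factor model
for two groups. Respondent latent trait η ~ N(0, 1) in group 1 and
N(α₂, ψ₂) in group 2; latent item response y*ᵢ = λᵢη + εᵢ with unique
variance θᵢ; observed category = number of thresholds below y*ᵢ. Loadings
and thresholds are identical across groups — the scalar-invariance
assumption that raw-score comparisons make implicitly, imposed here so the
latent and observed comparisons answer the same question. Invariance
violations and multidimensional structure are out of scope by design.

## Estimation

Two-stage summary-statistics least squares, the standard route for ordinal
SEM:

1. **Thresholds** per group and item: Φ⁻¹ of cumulative category
   proportions. Cut-points not separating observed categories (empty
   extreme or interior categories) are dropped from that group's statistics
   but retain their index so the two groups align.
2. **Polychoric correlations** per group and item pair: two-step maximum
   likelihood over ρ ∈ [−0.999, 0.999] (bounded Brent, xatol 10⁻⁷) with
   thresholds fixed at stage-1 estimates. The bivariate normal CDF uses
   Owen's T function (accurate to ~10⁻¹⁵, fully vectorized). Empty cells
   contribute zero to the log-likelihood; estimates on the bound are
   clamped and flagged (near-perfect association). Full joint ML would
   differ negligibly at the sample sizes the pipeline targets.
3. **Model fit**: minimize Σ_g (s_g − σ_g(params))ᵀ W_g⁻¹ (s_g − σ_g(params))
   where s_g stacks the group's thresholds and polychorics. Delta
   parameterization: latent responses standardized in group 1 (θᵢ = 1 − λᵢ²);
   group 2 rescales by sᵢ = √(1 + λᵢ²(ψ₂ − 1)), giving implied group-2
   thresholds (tᵢₖ − λᵢα₂)/sᵢ and correlations λᵢλⱼψ₂/(sᵢsⱼ). Item
   intercepts are fixed at zero in both groups; for ordinal items the
   thresholds carry all location information, so intercept equality holds
   trivially.

**Weights.** `estimator="DWLS"` (default) uses diagonal weights equal to
inverse jackknife variances of each summary statistic (delete-a-block over
20 contiguous respondent blocks — cheap, deterministic, and adequate for
diagonal weights). `estimator="ULS"` uses identity weights. Point
estimates, which are all the pipeline consumes, are consistent under both;
large recovery loops in the tests and the acceptance study use ULS for
speed. Robust (mean-and-variance-adjusted) test statistics and fit indices
are not implemented — the pipeline reports no χ²/CFI/RMSEA.

**Optimizer.** L-BFGS-B on transformed parameters: loadings through a
scaled tanh bounded at ±0.999, thresholds as first value plus log-spaced
increments (ordering enforced by construction), ψ₂ through log. ftol 10⁻¹²,
gtol 10⁻⁷, max 500 iterations. Starting values are deterministic: loadings
from the first principal axis of the n-weighted pooled polychoric matrix,
thresholds from n-weighted averages of the group estimates, α₂ from the
standardized sum-score mean difference, ψ₂ = 1. The factor sign is fixed by
Σλ ≥ 0.

**Heywood handling.** In the delta parameterization a residual variance
reaches zero exactly when |λ| reaches 1, so a loading landing within 10⁻³
of the bound is reported as a `HeywoodError` naming the offending items.
The pipeline excludes such scales from the study table and records the
reason; the run continues.

## Derived quantities and conventions

- **d_τ** = (α₁ − α₂)/SD_pool with α₁ = 0 and the classical (n−1)-weighted
  pooled latent SD. Sign convention everywhere: group 1 minus group 2,
  group 1 being the alphabetically first group label (override by
  relabeling). The pooling weights are a convention choice; the classical
  Cohen's-d weighting keeps d_τ and d_Y directly comparable.
- **McDonald's ω** = (Σλ)²ψ̄/((Σλ)²ψ̄ + Σθ) on the latent-response metric of
  the constrained model, with ψ̄ the sample-size-weighted pooled latent
  variance. Computing ω on the latent-response scale of the constrained
  model (rather than a per-group or categorical variant) is a documented
  package convention.
- **Discrepancies**: signed Δd = |d_τ| − |d_Y| (positive when removing error
  enlarges the effect); Δd = |signed Δd|; percent change uses the symmetric
  denominator (|d_τ| + |d_Y|)/2 and is undefined (reported missing) when
  both effects are zero. z = signed Δd / √(Var d_τ + Var d_Y) treats the two
  estimates as independent although they share a sample; the dependence is
  positive, so the difference variance is overstated and the one-tailed
  test (H₁: |d_τ| > |d_Y|) is conservative. The 95% CI is
  signed Δd ± 1.96·SE, centered on the estimate.
- **Meta-analysis**: REML tau² by bounded one-dimensional profile
  maximization (truncated at 0), or DerSimonian–Laird; Q with fixed-effect
  weights (Cochran's convention); I² = 100·τ²/(τ² + v_typ) with
  v_typ = (k−1)Σw/((Σw)² − Σw²). Verified against the `metafor` R package
  on a frozen fixture. Per-scale variances for the meta stage are the sums
  of the two Eq.-style d variances, matching the z test. Exceedance
  percentages are upper tails of N(pooled, τ²). The Spearman variant of the
  reliability–discrepancy correlation applies the Fisher-z interval to the
  rank correlation — an approximation, noted here because the sampling
  distribution of rank correlations is only asymptotically matched by it.

## The synthetic-data generator

The generator defines the study conditions for every test. Defaults: five
response categories with thresholds at the normal quintiles (a symmetric
Likert emulation), homogeneous loadings with θ = 1 − λ² (standardized latent
responses), and two groups of equal size. `latent_d` is the generating
(group 1 − group 2) standardized latent difference on the pooled-latent-SD
scale (equal to the group-1 SD scale when ψ₂ = 1), so the fitted d_τ
estimates `latent_d` directly and α₂ = −latent_d·SD_pool. One integer seed
drives two deterministically derived per-group streams; identical seeds
give byte-identical data.

What it emulates: ordinal Likert items with a single common factor, exact
scalar invariance, complete cases. What it does not: multidimensionality,
cross-loadings, correlated residuals, acquiescence or social-desirability
contamination, missing data, invariance violations, non-normal traits.
Passing recovery tests therefore demonstrate correctness of the estimation
machinery under the model's own assumptions, not robustness of the method
on messy real questionnaire data.

One quantitative caveat is intrinsic: coarsening latent responses into five
categories discards a little information, so the ordinal sum score's
reliability sits slightly below the latent-response ω and the observed
attenuation of d_Y slightly exceeds the (1 − √ω) prediction — at the
default quintile thresholds by roughly 0.01 in Δd terms at d = 0.5. The
end-to-end checks compare means at a tolerance that covers sampling noise
plus this categorization gap.

## Problem sizes

Recovery checks run at the sizes a careful desk validation affords: 20
replicates of n = 2000/group for latent-mean recovery, n = 5000 for a
single polychoric, an 8-scale study at n = 2500/group for the end-to-end
attenuation comparison, and n between 2·10⁴ and 2·10⁵ for moment and
attenuation laws that need tight Monte-Carlo error. Threshold and
correlation grids for the brute-force oracles use steps of 5·10⁻³
(three-parameter grid) and 10⁻⁴ (one-dimensional ρ grid).

## Known limitations

- Only two groups; only unidimensional scales (each subscale treated as its
  own scale).
- No model-fit assessment: a badly misspecified scale will still return
  parameters if the optimizer converges.
- DWLS weights are jackknife approximations to the asymptotic variances,
  not the full WLSMV weight matrix; standard errors of the CFA parameters
  are not produced (the d variances come from the closed-form formula, not
  the fit).
- The CI of the discrepancy is centered on the estimate by construction;
  other centering conventions exist and published tables do not always use
  this one.
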