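# Methods

## Model and identification

The engine represents one group of a second-order latent curve model by
seven dense matrices — Λ_y (first-order loadings), τ_y (indicator
intercepts), Θ_ε (indicator residual covariance), Γ (growth basis), κ
(curve-factor means), Φ (curve-factor covariance), Ψ (first-order
disturbance covariance) — together with per-entry free/fixed masks and
equality labels.  Every distinct label is one free parameter; equality
constraints (within or across groups) are imposed exactly by sharing a
label in a flat parameter vector, never by penalty terms, so degrees of
freedom count correctly by construction.  Matrices are dense because the
models are tiny (four observed variables per group).

With two occasions and a single indicator, a latent change model needs 7
parameters against the 5 identified moments — under-identified, which the
package reports rather than hides (`degrees_of_freedom` returns the
negative df with a flag).  Identification with two waves is achieved by
**parallel indicators**: two parcels per occasion with λ = 1, τ = 0, equal
residual variances within an occasion, and ζ = 0 in the change form.  The
residual structure additionally frees one cross-occasion residual
covariance per parcel (the same parcel measured twice shares unique
variance).  This constraint table is pinned by the published
parameter-count bookkeeping: the no-change group form has 8 free parameters
(κ₁, φ₁, two occasion residual variances, two lag residual covariances, ζ₁,
ζ₂) and the latent change form 9 (ζ fixed to zero; κ₂, φ₂, φ₁₂ freed),
giving 16/17/18/15 free parameters and 12/11/10/13 df for the four sequence
models.  The source publication never prints its Θ_ε structure explicitly;
this is the unique structure consistent with all eight printed counts, and
the builders self-check against them in the test suite.

Per-group χ² contributions are reported with a per-group df attribution:
labels used by one group are charged to it, labels shared across groups are
split evenly.  This reproduces the published per-group df splits, including
the (6)/(7) split of the intercept-equated model.

## Estimation

*Summary-statistic ML.*  For group moments (m, S, n) and implied moments
(μ, Σ), the discrepancy is F = ln|Σ| + tr(SΣ⁻¹) − ln|S| − p +
(m−μ)'Σ⁻¹(m−μ); the fit minimizes Σₖ nₖFₖ and reports χ² = Σₖ nₖF̂ₖ with
per-group contributions nₖF̂ₖ.  The default sample-size convention is the
biased-ML n (χ² = n·F̂); n−1 is available because software conventions
differ and the source publication does not state its choice.

*FIML.*  For raw data with missing values, the casewise log-likelihood sums
the multivariate-normal log-density over each case's observed coordinates,
grouped by missingness pattern for speed.  Cases with no observed values
are excluded and counted.  The saturated reference model (unstructured
per-group mean and covariance under the same missingness) is fitted by EM
(tolerance 10⁻¹⁰ on the relative log-likelihood change), and
χ² = 2(ℓ_sat − ℓ_model).  On complete data this route equals the
summary-statistic route to ~10⁻⁴, which the tests verify.

*Optimization.*  L-BFGS-B on the free parameter vector with numeric
gradients; starting values come from observed-moment heuristics (intercept
mean ← grand pretest mean, change mean ← observed mean change, variances ←
fractions of the average observed variance, covariances ← 0).  Outside the
positive-definite region the objective returns a graded penalty
(10⁶·(1 + |min eigenvalue|)) so line searches stay informative.
Convergence requires the optimizer's success flag or a numerically flat
projected gradient; on failure, up to five seeded jittered restarts are
attempted (default seed 20170302).  Variances are *not* constrained:
negative estimates (Heywood cases) are reported as warnings, with an
optional bounded refit (`variance_floor=0`).

*Standard errors* are square roots of the diagonal of the inverse
observed information, computed by central-difference numerical
differentiation of −log L (relative step 10⁻⁴).  A non-invertible
information matrix yields "SEs unavailable" with a warning, never silent
zeros.

## Fit statistics

RMSEA uses the multi-group convention √(max((χ²−df)/(df·N),0))·√G with N
the total sample size and G the number of groups; this is the convention
that reproduces the published two-group RMSEA values exactly from the
printed χ²/df, and it can be switched off.  The 90% interval inverts the
noncentral-χ² CDF in the noncentrality parameter (Brent root-finding, zero
when no positive root exists).  CFI/TLI use a per-group independence
baseline (free means and variances, zero covariances, no cross-group
constraints) — the dominant software convention, stated here because the
source publication does not define its baseline.  TLI is clamped to [0, 1]
for reporting with the raw value retained.  SRMR averages squared
standardized residuals over the nonredundant covariance and mean elements,
pooling groups by element count.  AIC is −2lnL + 2q from the actual
(FIML/ML) log-likelihood, so AIC differences equal χ² differences plus
2·ΔNFP across nested fits.  ΔAIC support labels follow the published bins
(Δ < 2 strong; 4 ≤ Δ ≤ 7 considerably less; Δ > 10 essentially none); the
guidance leaves gaps at 2–4 and 7–10, and values there are labelled
"intermediate (guidance gap)" instead of being silently binned.

The χ² difference test validates nesting structurally (free coordinates
and label-partition coarsening).  One documented equivalence is accepted
besides the strict check: a no-change group (ζ free, change machinery
fixed) is an exact reparameterization of a restriction of the latent change
group (φ₁′ = φ₁+ζ₁, φ₁₂′ = −ζ₁, φ₂′ = ζ₁+ζ₂, κ₂ = 0), so no-change vs
latent-change comparisons are valid likelihood-ratio tests even though the
label sets do not nest.  Keeping the no-change form in its natural
parameterization (rather than slope coordinates) matters for the
intercept-equated model: the cross-group constraint applies to the
second-order intercept variance φ₁, excluding ζ, as in the source model.

## Model sequence and selection

`run_sequence` fits M1–M3, selects the best by lowest AIC with ΔAIC < 2
treated as a tie resolved toward fewer parameters (operationalizing the
published narrative use of ΔAIC plus parsimony), then fits M4 as the best
model with intercept mean and variance equated across groups (either
constraint can be relaxed for field studies with failed randomization), and
finally, when the best model carries a change factor in the intervention
group, fits the sensitivity model.  The sensitivity model rewrites Φ in
that group as slope = γ·intercept + disturbance, a one-to-one
reparameterization with identical likelihood (verified to 10⁻⁶);
β = γ·√(φ₁/φ₂) with φ₂ = γ²φ₁ + var(disturbance), and R² = β².

## The synthetic-data generator

`simulate` draws second-order factors from N(κ, Φ), builds η by the growth
basis (plus ζ disturbances in no-change groups), and adds indicator
residuals with within-occasion variance θ_t and per-parcel lag covariance
θ_c.  Posttest attrition is case-level MCAR (both posttest indicators
deleted jointly), matching the retention pattern of the school study the
defaults emulate; cell-level MCAR and a contaminated-normal residual
mixture (for stressing normality screens) are options.  The default
configuration (`study_config`) uses the empirical Model 2 fit rounded
to two decimals — intervention group: κ = (3.46, 0.19), φ₁ = 0.44,
φ₂ = 0.28, φ₁₂ = −0.22; control group: κ₁ = 3.47, φ₁ = 0.38,
ζ = (0.10, 0.03) — with n = 137/113 and 18% posttest MCAR.

What the generator does *not* emulate: Likert discreteness and ceiling
effects (draws are continuous normals), classroom clustering (the study
randomized classes, not students), non-MCAR attrition, and measurement
non-invariance over time.  Passing recovery tests therefore demonstrate
correctness of the estimator under the model's own assumptions, not
robustness to these real-data features.

## Problem sizes used in validation

Monte-Carlo oracles use 4·10⁵ draws for moment matching; parameter-recovery
and test-calibration studies use 200 replications at n = 2000/group
(complete data, summary-ML route — equivalent to FIML on complete data,
which is verified separately); model-selection rates use 100 replications
at n = 250/group; FIML unbiasedness under 30% MCAR is checked at reduced
replication counts.  These sizes give Monte-Carlo error comfortably below
the asserted tolerances.

## Known limitations

* Two occasions, two parallel indicators, one construct: the matrix engine
  accepts other dimensions, but the step builders and the identification
  constraints target the two-wave parallel-indicator design.
* Fitting printed summary tables (pairwise-complete correlations with the
  posttest n) approximates the original raw-data FIML fit; parameter
  estimates agree to ±0.02 on this study's headline quantities, but χ²
  values shift by about one point, so exact fit-statistic reproduction
  requires the undeposited raw data.
* No robust (sandwich) standard errors or robust/categorical estimators;
  no multilevel extension for classroom clustering; no MNAR mechanisms.
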