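# Methods

## The model

`combatpredict` implements location-scale harmonization of multi-site
feature matrices (the ComBat family). For subject *j* at site *i* and
feature *g* (e.g. one of 62 regional cortical-thickness measures, in mm):

    Y_ijg = α_g + X_ij β_g + γ_ig + δ_ig ε_ijg,     ε_ijg ~ N(0, σ_g²)

where `X` holds biological covariates (age, sex, diagnosis indicators),
`γ_ig` is the additive and `δ_ig` the multiplicative site effect. The
additive effects obey the identifiability constraint Σᵢ nᵢ γ̂_ig = 0, so
that α_g is the sample-size-weighted grand mean.

Fitting proceeds in three steps:

1. **Standardization.** Least squares of Y on site indicators and
   covariates gives α̂_g (the nᵢ-weighted average of the per-site
   intercepts), β̂_g, and the pooled residual scale σ̂_g. The residual
   variance uses divisor **N** (the total subject count), matching the
   constraint-based least-squares formulation; with divisor N the
   no-shrinkage adjustment is exactly mean-0/variance-1 per site after
   re-standardization, which the tests pin down. Standardized residuals
   are Z = (Y − α̂ − Xβ̂)/σ̂.

2. **Empirical Bayes.** Within each site the raw effects are the
   within-site mean γ̂_ig and sample variance δ̂²_ig (divisor nᵢ − 1) of Z.
   Conjugate priors γ ~ N(γ̄ᵢ, τᵢ²) and δ² ~ InvGamma(λᵢ, θᵢ) have their
   hyperparameters estimated **across features within the site** by the
   method of moments; for the inverse gamma, matching mean m and sample
   variance s² of the δ̂² gives the closed forms λ̂ = (m² + 2s²)/s²,
   θ̂ = (m³ + m s²)/s². Posterior estimates are the fixed point of the
   conditional posterior-mean updates

       γ*  ← (n τ̂² γ̂ + δ*² γ̄) / (n τ̂² + δ*²)
       δ*² ← (θ̂ + ½ Σⱼ (Z − γ*)²) / (n/2 + λ̂ − 1)

   initialized at the raw estimates and iterated jointly over the site's
   features until the maximum absolute relative change of both vectors
   falls below `tol` (default 1e-6, `max_iter` 500; non-convergence logs a
   warning and returns the last iterate — in practice convergence takes a
   few dozen iterations).

3. **Adjustment.** Y* = (σ̂/δ*)(Z − γ*) + α̂ + Xβ̂.

### Out-of-sample prediction (the package's reason to exist)

`CombatResults.predict_new_site` harmonizes a site never seen by the fit,
using only the stored (α̂, β̂, σ̂): standardize the new data with the stored
constants, compute the new site's raw effects, estimate its hyperpriors
from **its own across-feature estimates**, shrink, adjust. Because the
pooled fit treats each site the same way given (α̂, β̂, σ̂), predicting one
of the fit's own training sites reproduces the pooled harmonization
*exactly* — a test pins this round trip at 1e-8, EB on and off. No
training-site data is needed at prediction time, so a fit serialized to
JSON is sufficient to harmonize new cohorts against a reference space.

### Numerical choices and edge cases

- Site terms are obtained as site means of the standardized full-model
  residuals; since least-squares residuals are orthogonal to the site
  indicators, the nᵢ-weighted zero-sum constraint holds automatically
  (~1e-12 relative), with no explicit Lagrange machinery.
- A feature fit exactly by the design (zero residual variance, detected at
  a roundoff-scaled threshold) is an error naming the feature; a covariate
  confounded with the site indicators is an error naming the column.
- Sites are processed in sorted label order; subject and feature order are
  preserved; every random draw sits behind an explicit seed.
- Degenerate across-feature moments (s² = 0, hyperprior unidentified) are
  an error by default; `allow_flat_prior=True` falls back to the raw
  estimates for that site with a logged warning.
- γ update with τ̂² = 0 returns γ̄ exactly (total shrinkage); the
  inverse-gamma posterior requires n/2 + λ̂ − 1 > 0 and errors otherwise.
- Reference-site mode (`reference_site=...`): α̂ is the reference site's
  intercept and σ̂ its own residual scale, the reference site's effects are
  fixed at (γ* = 0, δ* = 1) so its data pass through unchanged, and all
  other sites (including predicted new ones) are mapped onto its
  location/scale. Off by default.
- The standardization carries a `mean_model_kind` tag as the hook for a
  smooth (spline/GAM) mean backend; only the linear backend is
  implemented.
- Only parametric empirical Bayes (the stated conjugates) is provided.

### A note on the EB estimator vs the exact posterior mean

The fixed point of the conditional-mean updates is the classical
estimator, not the joint posterior mean: the δ*² update evaluates the
conditional mean at γ = γ* instead of integrating over γ, omitting a term
of order n·Var(γ | Z)/2/(n/2 + λ − 1). The suite verifies both facts
separately: (a) the δ² update equals the exact InvGamma conditional
posterior mean to 1e-8 (1-D quadrature); (b) on an instance with a tight
γ prior (τ² = 0.002, λ = 5, n = 4, 2 features) — where the omitted term is
negligible — the fixed point matches a brute-force 2-D quadrature of the
joint posterior means of (γ, δ²) to 3 decimals. At moderate τ² the
discrepancy in δ*² is a real ~1–3% property of the estimator.

## The synthetic cohorts

`generate_combat_data` draws directly from the generative model above:
K sites with sizes uniform in [3, 20] by default (64 sites and 62 features
mirror a typical multi-scanner clinical cohort), age ~ U(55, 90),
sex ~ Bernoulli(½), a three-level diagnosis (CN/LMCI/AD) with per-site
Dirichlet-mixed proportions, γ_ig ~ N(γ̄ᵢ, τ²), δ²_ig ~ InvGamma(λ, θ) and
standard-normal residuals scaled by σ_g (the factorization δ·σ_g·ε keeps
σ_g inspectable; it is equivalent to folding σ_g² into the error
variance). Default magnitudes — feature means ≈ 2.5, residual scales
0.08–0.16, age slope −0.01/yr, sex effect +0.05, LMCI/AD shifts
−0.05/−0.10, additive site effects with SD ≈ 0.1 (γ̄ spread 0.08,
τ = 0.05), δ² prior mean 1 (λ = 6, θ = 5) — make site-effect variability
comparable to covariate-effect variability, so harmonization visibly
matters. `lam=inf` switches the multiplicative effect off (δ ≡ 1); setting
`gamma_bar_sd = tau2 = 0` switches the additive effect off. Every draw is
stored in a `GroundTruth` that reconstructs Y exactly.

`generate_reference_and_test` pairs a large, diagnosis-free reference
cohort with a clinical test cohort sharing α, σ and the age/sex slopes but
carrying its own (disjointly labelled) sites and its own diagnosis
effects — the reference-consortium / clinical-study design the normative
workflow expects.

What the generator does **not** emulate: longitudinal correlation,
missingness, non-linear age trends, covariate-dependent residual variance,
heavy-tailed measurement error, or scanner effects that act differently
across the feature covariance structure (as opposed to per-feature
location/scale). Passing tests therefore demonstrate correctness of the
estimator under its own model assumptions and sane behavior under the
emulated cohort structure — not robustness to everything real
neuroimaging data can do.

## The evaluation harnesses

- **Leave-one-site-out equivalence** (`loso_rmse`): for each site, fit on
  the rest, predict the held-out site, and compare with the harmonization
  the site receives from a pooled fit of all sites; report per-site RMSE
  over all (subject, feature) cells (per-subject RMSEs available for
  plotting). The pooled comparator includes all sites. On the 64-site
  cohort the per-site RMSE stays below ~6% of the raw site-effect SD and
  shows no rank correlation with the site's AD proportion.
- **Predictive generalization** (`predictive_generalization`): per-feature
  linear models of harmonized features on age+sex+diagnosis are trained on
  the retained sites and evaluated on the held-out site against raw vs
  out-of-sample-harmonized observations. Folds that lose a diagnosis level
  entirely are marked failed (confounded design) and the run continues.
- **Normative workflow** (`normative`): per-feature linear age+sex
  reference with constant residual SD (divisor n − 3) on the harmonized
  reference cohort; centiles are Φ((y − μ̂)/σ̂) clipped to the open unit
  interval. Test sites are harmonized out-of-sample with site effects
  estimated from ≥3 **controls only** and the adjustment applied to every
  subject of the site (sites with fewer controls are skipped with a logged
  reason). Heterogeneity between reference and test controls is
  quantified per feature by a two-sided Wilcoxon rank-sum test (normal
  approximation with tie correction) and the rank-biserial correlation
  RBC = (wins − losses)/(n₁n₂), positive when the test group tends
  higher; p-values are reported unadjusted, with the count of features
  below nominal α as the summary. All-tied features are flagged
  degenerate (RBC 0, p 1).

## Problem sizes in the shipped tests and acceptance script

Single-fit properties (constraint, exactness, round trip, LOSO RMSE
bound) run on the full 64-site × 62-feature cohort. Multi-seed
experiments use 20 seeds at reduced size (trend check: 20 sites × 20
features; generalization: 30 sites × 20 features; recovery: 8 sites × 30
features at site sizes 10/50/200); `scripts/acceptance.py` uses 10
repetitions per experiment. These sizes keep every experiment at seconds
on one CPU while leaving the measured effects far from their thresholds.
The Fig-style normative condition uses a 30-site × 10-subject test cohort
(Dirichlet(5, 2.5, 2.5) diagnosis mixing, so most sites keep ≥3 controls)
with injected site effects combining a systematic cohort offset (−0.10)
with per-site spread (SD 0.12, about one residual SD) — the "marked,
systematic displacement" regime that makes the unharmonized comparison
visibly heterogeneous.

## Known limitations

- Covariate effects β̂ are applied as stored at prediction time; a new
  site whose covariate-outcome relationship differs from the training
  population will not have that difference corrected (by design — nothing
  is re-estimated from the new site except its location/scale).
- New-site hyperpriors come from the new site's own across-feature
  moments; with very few features they are noisy, and with fewer than two
  features undefined.
- The normative reference is linear in age with constant residual SD;
  distributional regression (age-varying variance) is out of scope.
- Harmonization of a site estimated from controls only assumes controls
  are exchangeable with the reference population given age and sex.
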