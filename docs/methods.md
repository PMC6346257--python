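# Methods

This note records the statistical model, the numerical choices, the
synthetic-data design and the known limitations of `cgfmap`, at the level of
detail a maintainer or reviewer needs to re-derive the behaviour.

## 1. Data model

The estimation unit is a cluster observation: `N` children measured, `C`
below the threshold, at a point location (or a polygon reference) in a given
year, with a likelihood weight `w ∈ (0, 1]`. Anthropometry microdata reach
this form through three steps.

**LMS z-scores.** `z = ((x/M)^L − 1)/(L·S)` per (indicator, sex, index)
stratum, with the limit form `log(x/M)/S` used when `|L| < 1e-8` so the
function is continuous in `L`. HAZ/WAZ strata are indexed by completed age
in months (0–59); WHZ strata by height rounded to the nearest 1-cm table
band. Growth failure is the *strict* inequality `z < −2`; ties count as not
afflicted. Biologically-implausible-z flagging exists behind a parameter
(`flag_abs_z`) but defaults off. The shipped LMS tables are synthetic —
smooth, monotone growth curves with realistic magnitudes — adequate for
exercising the machinery and for round-trip simulation; real reference
tables can be loaded from CSV in `(indicator, sex, index, L, M, S)` layout.

**Exclusions.** Records missing sex, missing age, age outside 0–59 months,
or non-positive measurements are dropped and counted per rule; polygon
clusters containing a single child are dropped; records without interview
dates are dropped only where the seasonal adjustment requires them. The
operation is idempotent and returns a per-rule log.

**Collapse.** Per cluster: `N` = scoreable children, `C` = children with
`z < −2`, month = modal interview month; clusters with no scoreable
children are omitted.

## 2. Seasonality adjustment (wasting)

WHZ is modelled per region as
`WHZ ≈ intercept + f_per(month) + f_trend(time) + α_country` with

* `f_per`: periodic cubic B-splines, period 12, 6 basis functions built by
  folding an extended uniform knot sequence; centered after fitting so the
  component integrates to zero over the cycle (adjustment therefore leaves
  annual means unchanged when months are uniformly represented);
* `f_trend`: a plain cubic B-spline over the study duration (4 basis
  functions);
* `α_country`: country offsets under a ridge penalty (default weight 1.0 —
  a random-effect-like shrinkage; the penalty can be set to 0 for fixed
  effects; the field's conventions differ and both readings appear in
  practice, so the shrunk version is the default and the choice is exposed).

Adjusted WHZ = WHZ − `f_per(month)`; only the periodic term is used. Records
lacking an interview month cannot be placed in the cycle and are dropped.
Fitting requires ≥ 2 distinct months per region.

## 3. Polygon observations

Areal clusters are resampled to `n_samples = 10,000` locations inside the
referenced admin unit, sampled with probability ∝ pixel population
(year-matched) and uniform within a pixel, then reduced by k-means to `k`
centroids with weights = cluster shares (`Σ w_j = 1` exactly). `k` defaults
to `min(10, populated pixels in the unit)` — small enough to bound the
likelihood size, large enough to represent within-polygon heterogeneity.
Each pseudo-point multiplies the binomial log-likelihood of the parent's
`(C, N)` by `w_j`, so one polygon contributes one observation's worth of
information. The sampler is seeded per parent cluster and reproducible.

## 4. Stacked ensemble covariates

Three child learners are fitted to the cluster data with raw covariates as
predictors, each supporting case weights:

* **smoother** — additive logistic regression on per-covariate cubic
  B-spline bases (5 functions each), ridge penalty 1.0, fitted by IRLS;
* **boosted_trees** — xgboost, `binary:logistic`, ≤ 200 trees, depth 3,
  learning rate 0.1, labels `C/N` with weight `N·w`;
* **lasso** — L1 logistic regression (saga) on the two-row success/failure
  expansion; the penalty is chosen by a hand-rolled 3-fold CV over 7
  log-spaced strengths scored by *weighted* binomial log-loss (library CV
  wrappers score unweighted, which is degenerate for the two-row encoding);
  case weights are normalised to mean 1 for solver stability.

Out-of-sample features come from 5 plain random observation-level folds
(seeded); the prediction for an observation never saw its own fold, verified
by a fold-corruption test. Full-data refits provide the in-sample feature
maps used on the pixel grid. Features live on the logit scale, are never
centre-scaled, and are clipped to ±12. Degenerate regional responses (all
zeros / all ones) fall back to a clipped constant with a warning. Learners
are fitted per region with shared hyperparameters.

## 5. The geostatistical model and its engine

`logit(p_i) = X_i·β + Z_i + ε_i` with `β` on the simplex, `Z` a zero-mean
Gaussian process with Kronecker Matérn(ν = 1) ⊗ AR1 covariance, and nugget
`ε`. The Matérn uses the `κ = √(8ν)/range` convention (correlation ≈ 0.139
at `d = range`). The latent residual is represented at observation level
with covariance `σ²·Matérn(d_ij)·ρ^|t_i−t_j| + τ²·I`: observations snapped
to the same pixel centre and year share the field value exactly but keep
independent nuggets. Observation coordinates are snapped to the nearest
pixel centre.

**Priors** (weakly informative; stated because no external defaults exist):
log-normal(0, 1.5²) on range, field s.d. σ and nugget s.d. τ;
`logit((ρ+1)/2) ~ N(0, 1)`. The simplex is parameterised by softmax with a
symmetric Dirichlet(1) prior, implemented through the additive-logistic
transform density (`log p(b) = Σ_k log π_k`), whose gradient and Hessian are
analytic. Unconstrained ("linear") coefficient mode uses N(0, 5²) priors and
an automatic intercept; an intercept-only variant gives the GP-only model.

**Inference** (empirical Bayes, Laplace):

1. For each hyperparameter vector θ = (log range, log σ, logit((ρ+1)/2),
   log τ), the joint mode of (coefficients b, residual e) is found by
   damped Newton with backtracking line search (Gauss–Newton curvature for
   the softmax block); the Laplace marginal likelihood is
   `ℓ(û) + log p(û|θ) − ½ log det H + log p(θ)` plus constants.
2. θ is optimised by Nelder–Mead (default budget 150–200 evaluations,
   `xatol = fatol = 0.01`), warm-starting each mode from the previous one.
   A kernel cache evaluates the Matérn only on unique distances — snapped
   coordinates make these few — which dominates the per-evaluation cost
   otherwise.
3. Hyperparameter uncertainty: a central finite-difference Hessian of the
   marginal at the mode (step 0.1, eigenvalues floored at 1e-2 against FD
   noise) defines a Gaussian from which up to 25 θ samples are drawn; field
   and coefficient draws come from each θ's conditional Laplace Gaussian.

**Prediction** is conditioning-by-kriging: per draw, an unconditional field
on the full grid is simulated through the exact Kronecker factorisation
(`chol(Matérn) ⊗ chol(AR1)`), then corrected by
`K_*o K_oo^{-1} (e_draw − e_unconditional)`, which yields an exact draw from
the conditional Gaussian at all pixel-years. The nugget is *excluded* from
predicted surfaces by default (it is observation-level noise; a flag
includes it). Prevalence = inverse-logit, so candidate maps live in [0, 1]
by construction.

**Scale.** The engine is dense: it refuses more than 3,000 observations
(and `st_covariance` more than 20,000 pixel-years without an override). The
study-scale problem would require sparse approximations, which are out of
scope here; per-region fitting is the supported route to larger runs.

## 6. Post-estimation

Aggregation is the population-weighted mean over unmasked pixels with
year-matched population, per draw. Raking factors are per-draw ratios
target/estimate at anchor years (2000, 2005, 2010, 2016 by default; an
anchor beyond the modelled span enters through linear interpolation of the
*target* onto the final span year, mirroring the 2010→2016 interpolation
convention for 2015), then linearly interpolated across all years and
applied multiplicatively per country-year. Raked prevalence is clipped at 1
and clip events are counted — multiplicative raking can exceed the support
and the clamp is this package's choice. Exactness: absent clipping,
re-aggregated national values equal the series at anchor years to 1e-10 per
draw. Masking sets low-population (and optionally barren) pixels to NaN in
all products and is idempotent. Population-weighted map classes sort pixels
by value (ties by pixel index) and take maximal prefix/suffix sets whose
cumulative population does not exceed the tail fraction.

## 7. Projections and targets

AROC is the adjacent-year difference of logit posterior-mean prevalence
(computed from *raked* means — raking with non-constant factors changes
AROC, and the calibrated series is the one to project), with boundary
prevalences epsilon-clipped at 1e-6. The weighted mean uses
`w_t ∝ (t − 2000)^γ`, γ = 1 by default. Projection:
`p_2025 = expit(logit(p_2015) + 10 · AROC̄)`. Relative targets resolve to
`(1 − reduction) ×` the population-weighted 2010 aggregate (stunting 40 %;
underweight is shipped at 30 % as a configurable default — the canonical
GNT set does not state one); wasting is the fixed 5 % level. Pace and
acceleration are both defined on the logit scale for internal consistency:
`achieved = −AROC̄`, `required = max(0, (logit(p_2015) − logit(target))/10)`,
pace ratio = 100·achieved/required, acceleration capped into the “>400 %”
class; pixels at/below target are "met", non-declining pixels are
"non-decreasing" (no ratio is reported for either). Admin-level attainment
probabilities use the units' aggregate draws; a population-weighted mean of
pixel probabilities is available behind a flag.

## 8. Validation harness

Spatial folds are unions of whole admin units grouped by seeded
breadth-first growth over rook adjacency of the unit raster, sizes balanced
within ±1 (contiguity is best-effort where the adjacency graph disconnects).
Metrics on held-out observations: mean error, RMSE, sample-size-weighted
Pearson correlation, and 95 % *data-level* coverage — for each posterior
draw a binomial `C` is simulated given `N`, and the observed `C/N` is
checked against the 2.5–97.5 % band of the predictive `C/N` sample. The
data-level definition is primary because observed proportions are noisy
realisations; latent-level coverage would under-cover at small `N` for a
perfectly calibrated model. Five formulations are compared on identical
folds: stacked ± GP, raw covariates ± GP, GP only.

## 9. Synthetic worlds: what they emulate and what they do not

`make_world` builds a rectangular pixel grid (abstract planar coordinates,
Euclidean distances — no map projection, since projection handling is
cartographic rather than statistical) with nested rectangular admin
partitions, smoothed-noise covariate fields (static layers constant over
years; dynamic layers AR1(0.9) in time), a log-normal spatially smooth
under-5 population with 1 %/year growth, and a low-population mask.
`simulate_truth` draws the latent surface exactly from the model
(covariate linear term + Kronecker Matérn⊗AR1 field). Surveys place
clusters at population-weighted pixels, split point/polygon 60:40 by
default, draw `N ~ 1 + Poisson(23)` children and `C ~ Binomial(N, p)`;
microdata invert the LMS tables so re-scoring recovers the intended
z-scores, and wasting microdata carry a 12-month sinusoid (amplitude 0.4
z-units) on WHZ. The national series is the population-weighted national
truth at the anchor years with optional logit-scale noise; worlds default
to 2000–2016 so the 2016 anchor is an honest truth aggregate while the
analysis window is 2000–2015.

Not emulated: realistic geography or admin shapes, survey design effects
and sampling weights, measurement error and digit preference, covariate
measurement at 5×5-km fidelity, within-year survey timing structure beyond
a uniform month, and mortality-driven selection. Passing tests therefore
demonstrate correctness of the *method* under its own assumptions, not
performance on real survey data.

**Study sizes.** The simulation studies are desk-scale by design: the
recovery study uses a 16×16-pixel, 10-year world with 60 point clusters per
year and 10 replicates (truth ρ = 0.8, range = 6 px, σ² = 0.5); the
formulation study a 12×12, 6-year world with 60 clusters/year and a strong
nonlinear covariate signal (tanh/abs/sin transforms of moderately rough
fields, smoothing σ = 1.5 px) so that the ensemble has real structure to
capture that neither a linear model nor cross-block GP interpolation can
reach; the raking study a 10×10, 6-year world. These sizes keep a full
validation run in minutes on one CPU while leaving the estimands
identifiable; measured behaviour at these sizes: ρ and range recovered
within the stated bands in ≥ 8/10 replicates, pooled 95 % coverage ≈ 92–94 %,
median raking factor within a few percent of 1.

## 10. Numerical details and edge cases

* Logit epsilon 1e-6 at the [0, 1] boundary; learner features clipped ±12.
* Jitters: 1e-8 on spatial correlation diagonals, 1e-10 on AR1 and final
  Hessians; covariance matrices are checked PSD after jitter.
* Newton: max 40 iterations, gradient tolerance 1e-4 (likelihood gradients
  scale with ΣN, so this is conservative), 30-step backtracking.
* Matérn at `d = 0` returns σ² exactly; `K_ν` underflow at large distances
  maps to 0.
* Ties in population-weighted classes break by pixel index; `0^0 = 1` makes
  γ = 0 the uniform-weight limit of the AROC scheme.
* Degenerate fits: < 10 observations refused; all-zero/all-one responses
  fall back to clipped constants (learners) or are handled by the prior
  (geostat); a fully masked region cannot host clusters and raises.
* Determinism: every stochastic step derives its generator from
  (seed, stage-name) via `SeedSequence`; identical configs give identical
  outputs, verified end-to-end by manifest checksums.

## 11. Known limitations

* Empirical-Bayes Laplace underestimates hyperparameter uncertainty
  relative to full MCMC; the Gaussian-at-the-mode θ sampling recovers most
  but not all of it (pooled pixel coverage sits ~1–3 points below nominal,
  inside the accepted band). The MCMC oracle check bounds the latent-field
  approximation error at < 0.05 logit units on small instances.
* The dense engine limits runs to a few thousand observations; the
  continental problem needs sparse solvers that are deliberately out of
  scope.
* Raking above prevalence 1 is clamped; alternatives (logit-shift raking)
  are not implemented.
* The seasonal model uses month resolution only, and the injected seasonal
  signal lives in microdata z-scores, not in cluster counts.
* Survey design weights are carried on records but unused by default (the
  design-correction for areal assignment is an open question in the source
  material).
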