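# Methods

## Scientific setting

`beescape` models how local wild-bee visitation responds to the amount and
timing of floral resources in the surrounding agricultural landscape over
one season.  The observation unit is a transect (default 30 m × 4 m) at a
sampling location inside a resource-providing land patch, visited in up to
four within-season time periods (T1 late spring … T4 late summer).  The
response is the count of flower visits by a focal bee genus during a timed
observation bout; the predictors are floral-resource volumes measured at
the transect and integrated over the landscape within 250/500/750 m
buffers.

## Floral reward proxy

Per-flower rewards (nectar sugar, pollen) are expensive to measure, so a
flower is idealised as an elliptic cylinder: receptacle length and width
give the ellipse semi-axes `a = max(l, w)/2`, `b = min(l, w)/2`, and the
receptacle-to-longest-sexual-organ height gives `h`.  Surface area is
`A = πab` (mm²) and volume `V = πabh` (mm³).  Validation computes log–log
Pearson correlations between each dimension and published per-flower
nectar (µg sugar/day) and pollen (µl) values, pairwise-complete per
reward, with exact t-based p-values on n − 2 df.  An ANCOVA of
`log(reward) ~ log(volume) * source` tests (sequentially, interaction
last) whether the measurement source (field calipers, literature, or a
combination) changes the reward–volume slope; sums of squares are the
explicit extra-sum-of-squares form.  Natural logs are used throughout
(correlations are base-invariant; stated for reproducibility).

## Landscape resource integration

Quadrat counts (three 1.5 m × 1.5 m quadrats per transect; a fourth only
when the first three held no open flowers, averaged equally) are expanded
to flowers (capitula count as single flowers), multiplied by per-flower
volume, and converted to a transect density in mm³/m².  The sample median
of transect densities per (land type, period) — pooled across all sites —
is multiplied by the exact polygon∩disc area of each land type within each
buffer radius.  Geometry is planar (a projected metric CRS is required);
discs are 1024-gon approximations (relative area error < 1e-5), and
patches are indexed with an STR-tree.

Land falls into four categories.  Non-resource land contributes zero.
Resource-providing land contributes area × median density.  Unknown land
is imputed two ways, and every downstream model is run under both: the
*median* variant assigns the median of the densities of the land types
present within that specific buffer and period; the *minimum* variant
assigns zero.  Soybean — a crop of uncertain reward value — is treated as
unknown land only during its flowering periods (T2–T3 by default) and as
zero otherwise.  A resource-providing land type with no sampled median for
a period is demoted to unknown with a warning.  Observation bouts are
screened by weather: shaded temperature strictly above 11.9 °C, mean wind
strictly below 1.9 m/s, maximum wind strictly below 4 m/s.

## Temporal predictors

All resource volumes are cube-root transformed.  For a taxon first
observed foraging in period `f`, the regressors at period `k` are:
`TransectFR` (local density, cube-rooted), `PresentFR` (landscape total,
period `k`), `FirstTimePeriodFR` (landscape total at `f`), `ChangeInFR`
(the sum of negative period-to-period changes from `f` to `k`; increases
count as zero, so the value is ≤ 0), `CumulativeFR` (the running sum from
`f` through `k`), plus `AllOtherVisits` (visits by all non-focal bees in
the same transect and period) and a log observation-time offset
(1 minute per 4 m² of transect; 30 min for the default transect).

The transform-vs-difference order is genuinely ambiguous for `ChangeInFR`
and `CumulativeFR`; the package default applies the cube root per period
*before* the temporal operators, and `transform_first=False` switches to
differencing raw volumes with a signed cube root afterwards.  Rows for
unsampled location × period combinations are absent, not zero-filled.

## ZINB-GLMM

Visit counts follow a zero-inflated negative binomial: with probability π
a structural zero, otherwise NB2 (variance μ + μ²/θ) with
log μ = xᵀβ + offset + u_site + v_period, u ~ N(0, σ²_site),
v ~ N(0, σ²_period) crossed.  Zero inflation is intercept-only.
Estimation is maximum likelihood (never REML, so AICc is comparable
across fixed-effect structures) with a Laplace approximation over the
stacked random-intercept vector:

* inner problem: damped Newton with analytic gradient and Hessian of the
  joint log-likelihood in (u, v); the Hessian's site×period cross blocks
  are assembled exactly; steps are capped at 4 in sup-norm and
  backtracked; solved to max-gradient 1e-10;
* outer problem: L-BFGS-B over (β, log θ, logit π, log σ_site,
  log σ_period) with forward-difference gradients (step 1e-6, far above
  the inner solve's noise floor); box bounds keep θ, π, σ in numerically
  safe ranges;
* the marginal log-likelihood is f(ẑ) − ½(J log σ²_site + K log σ²_period)
  − ½ log det(−f″(ẑ)), the q/2·log 2π terms of the Laplace correction and
  the Gaussian priors cancelling.

Wald 95% CIs come from the inverse observed information
(central-difference Hessian of the Laplace objective); a fit is
`converged` only when the optimiser succeeds and the information matrix
is positive definite (up to finite-difference noise), and unconverged
fits are excluded from model selection.  Validated against brute-force
adaptive Gauss–Hermite quadrature on small crossed instances (within
0.5% of |loglik|) and against an independent fixed-effects ZINB
implementation when random effects are disabled (agreement to 1e-3).

AICc is −2ℓ + 2k + 2k(k+1)/(n−k−1) with k counting every estimated
parameter: fixed effects, θ, the zero-inflation intercept, and each
variance component; n is the number of observation rows.

Diagnostics: observed/expected-zero ratio against an NB-only fit;
randomized-quantile residuals from 250 simulations of the fitted model
(conditional on the estimated random-intercept modes) KS-tested against
Uniform(0,1) with flagging at α = 0.001; pairwise Pearson correlations
and VIFs of the fixed-effect design; Moran's I with inverse-distance
(not row-standardised) weights, expectation −1/(n−1) and a
normality-assumption variance for the two-sided p.

## Hypothesis families and selection

Per taxon: H0 (other bees' visits only), H1 (+TransectFR), H2
(+PresentFR, at each radius), H3a (FirstTimePeriodFR + ChangeInFR, at
each radius; single-brood-capable genera only), H3b (CumulativeFR, at
each radius; multi-brood-capable genera only).  Halictus and Lasioglossum
carry both brood classes; squash bees (Peponapis) drop ChangeInFR because
their resource series never declines within their foraging window.  Each
family is fitted full and reduced (every subset of {AllOtherVisits,
TransectFR} dropped), under both imputation variants.

Eligibility: a genus is analysed when present in ≥4 of 27 sites in ≥2
distinct periods.  The two-period requirement reproduces the analysed set
of the motivating survey exactly (genera reaching the bar in a single
period are excluded); genera whose visits are spatially autocorrelated
across all periods (inverse-distance Moran's I) are screened out.

Selection takes, within each variant, the lowest-AICc surviving model per
(hypothesis, scale), computes ΔAICc against the variant's overall best,
and ranks by the *sum* of the two variants' deltas; ties break toward
fewer parameters and then the smaller scale (ties are not expected in
practice; the rule makes the ranking total).  Coefficients of the winning
hypothesis are model-averaged per variant over its models with ΔAICc < 7:
Akaike weights w ∝ exp(−Δ/2), full (zero-substitution) averaging by
default with Burnham–Anderson unconditional SEs; conditional averaging is
available behind a flag.

## Synthetic data

The generator emulates the survey's structure, not any particular
landscape: 27 sites as independent 2.5 km Voronoi-tessellated tiles
(~40 irregular patches each) spaced 20 km apart; land categories drawn
per patch with area proportions 45.2% non-resource, 40% resource
(6 types), 4.8% unknown, 10% soybean (the survey's reported shares, with
the unmeasured balance in resource land); 102 sampling locations over
1–6 per site, placed ≥10 m inside resource patches when wide enough;
4 periods with land-type-specific seasonal density curves peaking at
2×10⁴ mm³/m²; a ~30-species log-normal floral pool including two
cucurbit crops and capitulum-counted composites; negative-binomial
quadrat counts (dispersion 1.5) whose expectation equals the land-type
truth, with empty quadrats recorded explicitly as zero counts; and ZINB
visits (θ = 1.5, π = 0.15, σ²_site = 0.25, σ²_period = 0.09, intercept 1)
whose linear predictor carries the generating hypothesis's effect
(standardized regressors, |β| = 1 by default; negative on PresentFR under
dilution).  Genus foraging windows fix each taxon's first period
(e.g. squash bees start mid-summer).

A fast panel path draws the predictor panel directly — site-level
log-normal resource baselines with declining trajectories for half the
locations — for estimation and selection simulations at arbitrary n
without geometry.  On that path there is no unknown land, so the two
imputation variants coincide and each candidate model is fitted once and
registered under both.

What the generator does *not* emulate: real spatial autocorrelation of
land cover between neighbouring sites, within-period resource dynamics,
bee movement or depletion feedbacks, and measurement error in patch
digitisation.  Passing recovery tests therefore show the estimator and
selection machinery are correct under the model's own assumptions, not
that the model is correct for any field system.

## Problem sizes and numerical choices

Simulation-based checks use sizes chosen to make each check decisive at
desk scale: parameter recovery at n = 2000 (25 sites × 4 periods × 20
transects) over 200 replicates; hypothesis recovery on study-shaped
panels (27 sites × 4 locations × 4 periods ≈ 430 rows) with a single
500 m radius in the candidate set and a handful of replicates per
generating hypothesis (the standardized unit effect makes selection
nearly deterministic); Laplace accuracy on 100 random 2–3-level crossed
instances against adaptive 10-node tensor Gauss–Hermite; buffer geometry
on random mosaics against 10⁶-point rejection sampling, judged per land
type at max(0.5% of the exact area, 4 Monte-Carlo SEs) since the Monte
Carlo estimate of a sliver has more than 0.5% relative error of its own.

Known limitations: the intercept of the visit model is confounded with
the realised means of the random intercepts (only 4 period levels), so
its single-season sampling spread (~0.1) exceeds any estimator bias and
its CI under-covers; interpretation should rest on the resource
coefficients, which recover cleanly.  With ≤4 period levels σ²_period is
estimated with large noise; boundary estimates near zero are common and
benign for the fixed effects.  Moran's I uses the normal approximation,
anti-conservative below ~10 sites.
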