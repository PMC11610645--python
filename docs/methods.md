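# Methods

This note documents the models, conventions, and numerical choices behind
`stygoscale`, and what its synthetic experiments do and do not establish.

## Study system and pipeline

Each *site* is a drinking-water extraction point with planar coordinates
(m), an elevation, amphipod presence/absence, optionally a nitrate
concentration (mg/L), and optionally a protection-zone extent (m). The
landscape substrate is a DEM raster and a categorical land-use raster
(forest, pasture, crop, construction, other) on a shared planar grid.
The pipeline extracts per-buffer land-use proportions, scans buffer sizes
for the scale of effect on presence, fits spatial mixed models for
nitrate and presence, and compares the identified scale against
protection-zone extents.

## Buffers

* **Round buffer** of radius *r*: all cells whose *centers* lie within
  *r* of the site. Membership is center-in-circle rather than
  area-weighted; the discretization error vanishes with resolution and is
  bounded in tests (area within 5% of πr² for r ≥ 20 cells).
* **Catchment buffer**: within the round buffer, cells with elevation ≥
  site elevation − `drop_m` (default 5 m, absorbing small local maxima)
  that are *connected* to the site. Connectivity is gap-bridged region
  growing: a qualifying cell joins the region if its center is within
  `gap_m` (default 50 m, Euclidean) of any cell already in the region,
  starting from the site cell. Implementation is masked binary
  propagation with a disk structuring element of radius `gap_m`; a
  brute-force pairwise-distance/connected-component oracle verifies it
  cell-for-cell. With `gap_m ≥ resolution·√2` the disk already contains
  the 8-neighborhood, so no separate 4/8 switch is needed; for
  `gap_m = 0` a `connectivity` argument (4 or 8) is exposed.
  `drop_m = ∞` reduces the catchment to the round buffer; `gap_m = ∞`
  keeps every qualifying cell.
* Whether the 50 m rule of the field protocol is a gap-bridging distance
  or a minimum-width rule is ambiguous at operator level; gap-bridging
  was chosen because it directly encodes "discard higher ground not
  adjacent to the site" while tolerating sub-threshold interruptions.
* Proportions are per-class cell counts over the region (rasterized, not
  vector-area weighted). Sites whose buffer at a given size leaves the
  raster are dropped from that size with a logged warning.
* Default raster resolution for synthetic work is 10 m (not the 2 m of
  survey-grade DEMs) to keep desk-scale runtimes; it is a config knob.

## Scale scan

* One binomial (logit) GLM per (size, type, class):
  `presence ~ coverage%`, coverage in percentage points (0–100), so
  slopes are per percentage point. Fits use IRLS (statsmodels) with
  deviance tolerance 1e-10; coefficients beyond ±15 on the logit scale
  mark separation and clear the `converged` flag.
* McFadden's pseudo-R² = 1 − deviance/null deviance, clipped to [0, 1]
  with a warning if numerically negative. The intercept-only model scores
  exactly 0, and the one-covariate model never scores below it
  (nested-model deviance monotonicity).
* Uncertainty: SD (denominator n−1) of the pseudo-R² over `reps`
  subsamples of 70% of sites drawn *without* replacement; subsamples with
  a single-class response are redrawn and counted. Subsample indices are
  drawn independently per scan cell from per-cell seeds.
* The scale of effect is the size maximizing the mean pseudo-R² across
  the class × buffer-type combinations; the SD of the mean divides the
  across-combination SD by √k. Ties break toward the smallest size
  (conservative toward local effects).
* The zone summary reports the median extent, the fraction of zones below
  the scale interval's lower edge, and the interval as a fold range of
  the median (low/median, high/median).
* No multiple-testing correction is applied across scan cells; the scan
  is a profile, not a family of hypothesis tests.

## Spatial mixed models

Model: g(E[y_i]) = x_i'β + b_i with b ~ N(0, λ C(ν, ρ)), where C is the
Matérn correlation over site coordinates in the (ν, ρ) convention in
which ρ multiplies distance (units 1/m): corr(d) =
2^(1−ν)/Γ(ν)·(ρd)^ν·K_ν(ρd). ν = 0.5 gives exp(−ρd); a fitted ρ of
6.1e-4/m therefore implies a multi-km range. This convention is stated
because several incompatible Matérn parameterizations are in circulation.
Families: binomial-logit (presence) and Gamma-log (nitrate; shape
estimated by ML jointly with everything else).

Estimation is Laplace-approximate maximum likelihood:

* Random effects are parameterized b = Lv (L the Cholesky factor of C),
  v ~ N(0, λI). The inner Newton maximizes the penalized log-likelihood
  over (β, v), tolerance 1e-8, ≤50 iterations, step-halving line search.
* The outer Nelder-Mead searches (log λ, log ν, log ρ[, log shape]) on
  the Laplace marginal ℓ(η̂) − v̂'v̂/2λ − (n/2)log λ − ½log det(L'ŴL + I/λ),
  tolerance 1e-6, ν bounded to [0.05, 10]. Matérn Cholesky factors are
  cached per (ν, ρ) and pairwise distances computed once per fit.
* Because each site contributes a single observation, the joint (β, v)
  mode systematically attenuates fixed effects for binary responses
  (the classic penalized-quasi-likelihood shrinkage). The reported β
  therefore re-maximizes the Laplace objective itself at the selected
  covariance parameters, with the inner mode over v alone. In recovery
  simulations this step removes an ~8–10% downward slope bias, leaving
  ~3%.
* Wald inference throughout: SEs from the fixed-effect block of the
  inverted penalized joint Hessian; 95% CIs at ±1.96·SE.
* AIC = −2·logLik + 2·(#fixed effects + 3 covariance parameters
  [+1 Gamma shape]). Stepwise backward selection refits the covariance
  parameters at every candidate removal and drops the term whose removal
  most lowers AIC until none does; the intercept and the spatial random
  effect are never dropped. Note AIC retains a 1-df pure-noise term with
  asymptotic probability ≈ P(χ²₁ > 2) ≈ 0.16 — that is a property of the
  selection rule, not a defect.
* The autocorrelation-range diagnostic reports the smallest distance at
  which the fitted correlation falls to a threshold (default 0.05, a
  convention), by bisection.
* Duplicated coordinates are jittered by ≤1 m (logged); n < 30 is
  refused; non-convergence is flagged, and a flagged refit during
  stepwise selection retains its term.

Known limitations: λ̂ is noticeably downward-biased with one binary
observation per site (weak per-latent information — visible against the
simulation truth), and ν is weakly identified and often drifts to its
bounds; fixed-effect estimates and their coverage are insensitive to
both in the recovery simulations, which is why acceptance checks target
the fixed effects.

## Site comparison and composition summaries

* Random reference sites are uniform within (optionally stratified)
  geometries, with largest-remainder quotas per stratum.
* The comparison unit is the per-site proportion of a class (one Wilcoxon
  rank-sum test per class across sites); displayed percentages are
  cumulated coverage shares per group. The rank-sum test uses the exact
  null distribution for tie-free samples with both n ≤ 12 and the normal
  approximation with tie and continuity corrections otherwise.
* Bonferroni correction uses m = number of classes compared (default 4:
  forest, pasture, crop, construction; configurable to 5). Stars follow
  *** p<0.001, ** p<0.01, * p<0.05, ns otherwise.
* The forest–agriculture gradient is 100·forest/(forest+pasture+crop);
  sites with no forest, pasture, or crop have an undefined gradient and
  are excluded (logged). Ternary coordinates normalize the same triple
  to sum 1.

## Synthetic data: what it emulates, and what it does not

* **DEM**: Gaussian-kernel-smoothed white noise (wrap-around boundary),
  standardized, scaled to `dem_amplitude` (SD in meters).
  `dem_corr_length` is the kernel bandwidth in meters. Default 1500×1500
  cells at 10 m (15×15 km), amplitude 50 m, bandwidth 1000 m — rolling
  molasse-plateau relief rather than alpine terrain.
* **Land use**: an independent smoothed field sliced at rank quantiles,
  giving contiguous patches with class fractions exact to one cell.
  The band order from low to high field value is forest | other |
  construction | pasture | crop, so the two agricultural classes jointly
  displace forest across the mosaic — the forest-agriculture opposition
  that structures real extraction-site landscapes and underlies the
  ternary gradient (a band order with pasture adjacent to forest would
  leave pasture uncorrelated with forest and no direction to its scan
  slope). Default composition forest 0.30, pasture 0.20, crop 0.20,
  construction 0.15, other 0.15; patch bandwidth 200 m, in the range of
  agricultural parcel and small woodlot sizes.
* **Presence**: Bernoulli with logit p = β₀ + β_f·forest% in the buffer
  of the *true* scale (default 600 m catchment). Defaults β₀ = −2.5,
  β_f = 0.06/pp give prevalence ≈ 1/3 (as in a 162/484-type survey) and
  an effect strong enough that the scale of effect is identifiable from
  n = 300 sites — a design-power choice made once, after a pilot showed
  that with materially weaker slopes the pseudo-R² profile is too flat
  for any scan to resolve adjacent sizes. A single driver (forest) keeps
  the true scale unambiguous.
* **Nitrate**: Gamma with log mean = log(15) + 0.015·crop% − 0.007·forest%
  (slopes at the magnitudes the nitrate models are expected to recover),
  shape 5 (CV ≈ 0.45), hence strictly positive concentrations around
  15 mg/L.
* **Protection zones**: log-normal with median 327 m and log-SD 0.46 —
  the log-SD chosen so ~67% of extents fall below 400 m, consistent with
  the median; positive and right-skewed like regulatory zone extents.
* **Covariates** for the final presence model (altitude from the DEM,
  aquifer distances, glaciation indicators) are synthetic stand-ins that
  do *not* affect simulated presence, so selection should discard them.

Not emulated: hydrological realism (flow accumulation, aquifer
structure, recharge), any real CRS or geodata, spatial sampling bias of
real monitoring networks, measurement error in nitrate, and spatial
autocorrelation in presence beyond what the shared landscape induces.
Passing tests therefore demonstrate that the *machinery* identifies known
truth under clean conditions — not that any particular field dataset
satisfies these models.

## Problem sizes and determinism

Experiments and tests run at: scale recovery 20 replicates × 300 sites ×
7 sizes × 2 buffer types; GLMM recovery 30 replicates per family at
n = 250 (covariance truth ν 1.26, ρ 6.1e-4/m, λ 1.32 binomial / 0.2
Gamma); nitrate sign recovery at n = 149 sites; catchment oracle on 100
random 50×50 DEMs; Wilcoxon calibration on 1000 null simulations of
50 + 50. Smaller grids (400–1000 cells square) back the unit tests.
Every generator and experiment derives its seeds from
`numpy.random.SeedSequence` chains on a single master seed; identical
configurations produce byte-identical pipeline outputs, recorded in the
run manifest with a config hash.
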