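# Methods

This note documents the models, algorithms and design choices behind
`patchscape`, in the spirit of a statistical package's model documentation.

## The occupancy model

The observation unit is a habitat patch surveyed `J` times (default 2).
True occupancy `z_i ~ Bernoulli(ψ_i)` is latent; survey outcomes are
`y_ij | z_i ~ Bernoulli(z_i · p_ij)`. Both probabilities carry logit links:

    logit(ψ_i) = x_i' β        logit(p_ij) = w_ij' α

The marginal likelihood per site integrates over `z`:

    L_i = ψ_i ∏_j p_ij^y_ij (1−p_ij)^(1−y_ij)          if Σ_j y_ij > 0
    L_i = ψ_i ∏_j (1−p_ij) + (1−ψ_i)                    otherwise

Assumptions: closed population within the season (no colonization or
extinction between the two surveys), independent surveys given `z`, no
false positives, and no missing surveys.

### Estimation

Maximum likelihood with analytic gradients and quasi-Newton (BFGS)
minimization from five jittered starts (the jitter is seeded; the first
start uses logit naive rates for the intercepts). The analytic score was
chosen over finite differences because the bootstrap goodness-of-fit and
all-subsets stages refit the model thousands of times; it is verified
against central differences in the test suite. Probabilities are clipped
to `[1e-10, 1−1e-10]`; fits with any coefficient beyond ±15 on the logit
scale are flagged as boundary estimates (e.g. complete separation, all-ones
histories). The optimizer targets a gradient tolerance of 1e-6; the
`converged` flag trips when the final gradient norm exceeds 1e-3.

Wald standard errors come from the finite-difference Hessian of the
analytic score (observed information). Covariates are z-scored over sites
at model construction — survey-varying covariates over all site × survey
values — so coefficients are on the standardized scale and comparable
across variables; the training means/SDs are stored for prediction in
original units.

### Derived statistics

* AIC = −2ℓ + 2K and AICc = AIC + 2K(K+1)/(n−K−1) with `n` = number of
  sites (not site × survey records). AICc ranks the detection-structure
  scan; plain AIC is the default for all-subsets selection, AICc by flag.
* Nagelkerke R² uses the intercept-only-ψ-and-p model as the null — the
  only null nested in every candidate — with
  `R² = [1 − exp(2(ℓ0−ℓ1)/n)] / [1 − exp(2ℓ0/n)]`.
* The MacKenzie–Bailey goodness of fit compares observed counts of the
  `2^J` detection histories with their model expectations
  (`E_h = Σ_i Pr(h | ψ̂_i, p̂_ij)`), and calibrates the chi-square by
  parametric bootstrap: `B` datasets simulated from the fit, each refitted
  (warm-started, single start), giving the p-value and
  `c_hat = χ²_obs / mean(χ²_b)`. With `J = 2` the statistic has only four
  cohorts and is strongly right-skewed, so `c_hat` from a single dataset is
  a noisy ratio; it is calibrated in the mean across datasets, which is how
  the verification suite asserts it. `c_hat` is reported, not used to
  re-scale criteria (no QAIC adjustment).

## Landscape metrics

Vector polygons are authoritative for geometry; the raster for
composition; cell membership is cell-center-in-region. All coordinates are
planar meters.

* Composition at scale `s`: proportions over classified cells whose
  centers fall in the ring `0 < d(center, patch) ≤ s` — measured from the
  patch boundary, excluding the focal patch interior (other patches'
  habitat cells stay in the denominator). The aggregate `habitat` class is
  the sum of the configured habitat-type proportions.
* Proximity index: `Σ_k A_k / d_k` over every non-focal patch that
  intersects the buffer at least partially (counted in full), with
  edge-to-edge distances floored at one cell size so touching patches do
  not divide by zero. The squared-distance variant used by FRAGSTATS is
  available via `squared=True`; the linear form is the default definition
  here.
* `np_dist`: minimum edge-to-edge distance to any other patch; undefined
  (reported as NaN) for a single-patch landscape.
* Distance to a raster class treats cells as filled squares (a patch
  touching a class cell is at distance 0) and expands the search window
  until no closer cell can exist outside it; distance to the river is
  polygon-to-polyline.
* Geometry: `per_area = P/A`; `shape_index = P / (4√A)`, 1 for a square.
  Note the ≥1 guarantee applies to rectilinear shapes (cell-aligned
  patches); smooth convex shapes can score below 1 in vector form, unlike
  rasterized perimeters.

## Habitat quality

FHD is the Shannon entropy (natural log; log₂ by option) of a plot's
coverage vector over the nine structural classes; all nine classes enter
by default, with a mask available to exclude non-foliage categories.
Plot FHD is pooled by habitat type across patches (types are rarely
replicated within a patch), and patch `veg_str` is the habitat-type-area
weighted mean of the pooled values — a convex combination. Slope is Horn's
3×3 finite-difference slope on the 30 m DEM averaged over cells inside the
patch; radiation is accepted as a supplied covariate (no solar model).

## Scale of effect and model selection

Each scale-dependent variable gets one univariate occupancy fit per buffer
scale (detection structure fixed at the full three-covariate model, which
is also how the pipeline proceeds after the detection scan); the scale of
effect maximizes Nagelkerke R², ties resolved to the smallest scale.

Collinearity: Spearman `|r_s| > 0.60` pairs lose their weaker member —
"strength" defined as the univariate R² at the variable's own scale of
effect — unless a pair is flagged as ecologically important, in which case
both members survive through alternative model sets (one set per
combination of pair members, Cartesian over pairs). Survivors then pass
iterative VIF pruning (drop the highest until all `< 10`).

Global models are single-scale (every composition variable and `prox` at
one scale, plus configuration, geometry and quality variables) or
multi-scale (each scale-dependent variable at its own scale of effect).
All-subsets expansion fits every ψ-subset crossed with every subset of the
three detection covariates (`2^k · 8` fits, guarded at 50 000), and models
within ΔAIC < 2 of the best are retained and evaluated.

## Spatial diagnostics

Residuals for spatial checks are conditional-occupancy residuals
`z*_i − ψ̂_i`, where `z*_i` is 1 for detected sites and the posterior
probability `ψ̂q̂/(ψ̂q̂ + 1 − ψ̂)` (with `q̂` the probability of an all-zero
history given occupancy) otherwise — the literature does not fix a
residual type for occupancy models, and this is the package's documented
choice. Global Moran's I uses inverse-distance weights between
patch centroids and a two-sided permutation test (999 permutations,
seeded) against the null expectation −1/(n−1).

When Moran's I is significant at α = 0.05, a single spatial autocovariate
is added: PCNM eigenvectors are built by truncating the distance matrix at
the longest minimum-spanning-tree edge (distances beyond it replaced by
4t), double-centering −D²/2, and keeping positive-eigenvalue axes; the
axis with the largest |Spearman correlation| with the residuals enters the
global model as one extra fixed ψ covariate. Because that axis is chosen
by maximum correlation among ~n/2 candidates, it can lower AIC noticeably
even for spatially unstructured residuals; what the construction
guarantees — and what the tests assert — is that it essentially never
*worsens* AIC by 2 or more.

## Evaluation

Observed "presence" is naive occupancy (detected at least once); predicted
presence thresholds the unconditional ψ̂ (predicted at or above the
threshold counts as presence). PCC and Cohen's Kappa are reported at 0.5,
AUC is the rank-based Mann–Whitney statistic (ties share), and Kappa is
additionally maximized over the 101-point threshold grid 0.00–1.00 in
steps of 0.01, ties to the smallest threshold. For binary data `p_e = 1`
can only occur together with perfect agreement, where Kappa is reported
as 1.

## Synthetic data

The generator emulates the study conditions the analysis was designed for:
~40 patches per region (the field study surveyed 42 and 33), two surveys
per patch, and a low landscape habitat proportion (~12%, matching the
reported 11–13%). Patches are cell-aligned rectangles, roughly half
extended into L-shapes so the shape index varies, placed disjointly
(≥2 cells apart) in a blocky crop/urban matrix crossed by a one-cell-wide
river; the DEM is a gentle plane with smoothed random relief at 30 m.
Vegetation plots are Dirichlet coverage draws whose concentration profile
depends on the habitat type, pooled into `veg_str` exactly as the real
pipeline does. Occupancy and detection are drawn from logit-linear models
on z-scored covariates, so true coefficients live on the same scale as
fitted ones. True detection coefficients default to
(α₀, α_veg, α_day, α_area) = (0.85, −0.4, 0.3, 0.2) — detection around
0.7 at covariate means, reduced by vegetation, as field experience with
visual lizard surveys suggests — and occupancy defaults to β = (0, 1.5) on
the habitat proportion at the true scale of effect (250 m).

The default desk-scale scenario uses a 4 km × 4 km extent at 10 m cells —
large enough for 3 km buffer rings to be meaningful, small enough that a
full pipeline run takes tens of seconds. The `SimulationConfig` default
cell size remains 5 m for parity with typical classified-map resolution.

For recovery experiments a lightweight ring-based sampler
(`simulate_occupancy_study`) replaces the raster: each annulus between
consecutive scales receives an independent habitat density (truncated
normal, mean 0.12, SD 0.08 — the heterogeneity a fragmented agricultural
landscape shows between neighboring rings), and the proportion at scale
`s_k` is the area-weighted cumulative mean of ring densities. This
reproduces the nested-buffer geometry — and hence the characteristic
correlation between adjacent scales — without rasterization, which is what
makes 100-replicate scale-recovery experiments affordable.

What the generator does *not* emulate: realistic vegetation succession,
spatially autocorrelated occupancy beyond what covariates induce,
multi-polygon patches, missing surveys, and observer heterogeneity.
Passing recovery tests therefore demonstrate correctness of the estimation
and selection machinery under the model's own assumptions, not robustness
to their violation in field data.

## Numerical choices and limitations

* Probability clipping at 1e-10; Hessian steps `1e-5 · max(1, |θ|)`.
* Exact ties in the scale scan and the Kappa grid resolve to the smallest
  scale/threshold.
* Spearman, VIF (statsmodels), eigendecompositions (LAPACK via numpy) and
  the MST (scipy) are delegated to standard libraries; the occupancy
  likelihood, landscape metrics, PCNM construction, Moran permutation test
  and evaluation indices are implemented here and each is tested against
  an independent brute-force or closed-form oracle.
* Problem sizes in the verification suite — 200 replicates at n = 200 for
  slope recovery, 100 replicates for scale recovery, 50 × B = 200 for GOF
  calibration — were chosen to bound Monte-Carlo error at single-CPU
  desk scale.
* v1 handles single-season data only, with complete survey records; no
  model averaging; `c_hat` is reported but not propagated into QAIC.
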