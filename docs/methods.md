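# Methods

This note documents the statistical model, the synthetic-data generator,
the numerical choices, and the design decisions behind `bearshield`. It
states how quantities are computed; every empirical number it mentions is
produced by the test suite, the analysis scripts, or
`scripts/acceptance.py`.

## The selection model

Resource selection is estimated with a use–availability design: each
mother-year contributes her retained GPS fixes as "used" rows (y = 1) and
an equal number of uniform random points from her availability domain as
"available" rows (y = 0). The model is a logistic regression with crossed
random intercepts,

    logit P(y_i = 1) = x_i'β + (x_i · s_i)'γ + u_bear(i) + u_year(i),
    u_bear ~ N(0, σ²_id),   u_year ~ N(0, σ²_year),

with `x` the landscape covariates and `s` the litter-survival flag
(0 = complete loss, 1 = survived). Main effects `β` are the selection of
unsuccessful mothers; `β + γ` is the selection of successful mothers; the
interactions `γ` carry the scientific contrast. A survival main effect is
included whenever any interaction is present (hierarchical
well-formedness); with count-matched per-mother availability it is
design-confounded and expected near zero, and it is reported but not
interpreted.

Under this design the logistic slope identifies the exponential RSF
exactly: within an availability domain, used points with density
∝ exp(η(x)) against uniform available points give
P(used | x) = expit(η(x) + const), so no rare-event approximation is
involved.

### Covariates

Continuous: Euclidean distance (km) to the nearest human habitation,
high-traffic road, and forest road; NDVI. All four are standardized to
mean 0, variance 1 (denominator n−1) pooled over every row of the
use–availability table — both response classes and all bear-years — since
one joint model is fitted. Land cover enters as six 0/1 dummies (bog,
tree-rich bog, clearcut, young, mid-aged, old forest) against the
implicit "other" baseline. Models are fitted on the natural "distance to"
orientation; for reporting, distance estimates (mains and their
interactions) are sign-reversed so positive reads "selection for
proximity". The reversal is a pure reporting transform: standard errors,
likelihoods and AICc are untouched, and applying it twice is the
identity.

### Collinearity screen

Ordinary VIF (1/(1−R²) from OLS of each predictor on the rest) is
computed for every predictor. For *screening*, the land-cover dummy block
is assessed jointly with the Fox–Monette generalized VIF, df-adjusted
(GVIF^(1/d)), because individual dummy VIFs depend on the arbitrary
baseline-class choice: with a 10% baseline, single-dummy VIFs of 3–4
appear even when the block is unproblematic. Continuous covariates are
screened at VIF < 3; the land-cover block at GVIF^(1/d) < 3. Screened-out
terms are removed from every candidate model.

## Estimation: Laplace-approximated maximum likelihood

With crossed random factors the marginal likelihood has no
product-of-one-dimensional-integrals form, so it is approximated by a
Laplace expansion around the joint mode of the stacked random effects
`u`:

    ℓ(β, θ) = f(β, u*, θ) + (q/2) log 2π − ½ log det H,

where `f` is the penalized log-likelihood (Bernoulli log-likelihood plus
Gaussian prior terms including their normalizing constants), `u*` its
mode in `u` at fixed (β, θ), `H = Z'WZ + D⁻¹` the curvature there, and
`q` the number of random levels. θ = (log σ²_id, log σ²_year).

The fixed effects appear in ℓ both through `f` and through `log det H`
(the mode and the weights move with β). Profiling β inside the penalized
solve ignores the determinant term and biases small-sample estimates, so
`fit_model` optimizes (β, θ) **jointly on the exact Laplace objective**
with an analytic gradient obtained by implicit differentiation through
the mode:

    dη/dβ_j = x_j − Z H⁻¹ Z' W x_j
    dℓ/dβ_j = x_j'(y − μ) − ½ Σ_i c_i s_i (dη_i/dβ_j),

with `c = w(1−2μ)` and `s_i = (Z H⁻¹ Z')_{ii}`, and the analogous
expression for θ. The gradient is verified against central differences to
1e−8 in the tests. Optimization is L-BFGS-B; a damped joint Newton solve
of the penalized problem provides the starting point. Because the
criterion's curvature in θ is O(number of levels) while in β it is O(n),
the θ coordinates are rescaled by a factor of 10 to keep L-BFGS's
implicit Hessian well conditioned (same optimum, about half the
iterations).

Numerical choices:

* Estimation is plain ML, not REML-type, because candidate models differ
  in fixed effects and are compared by AICc.
* Variance components are optimized on the log scale with a floor of
  σ² = 1e−10; fits at the floor are reported as 0.
* Inner-mode Newton tolerance scales with the data (1e−9·n on the
  gradient max) and line-search acceptance uses a relative threshold
  (1e−9·|objective|): with |log L| ~ 10⁴ the double-precision noise floor
  is ~1e−12 absolute, and absolute thresholds below it make the line
  search spin.
* Outer gradient tolerance 5e−4 (projected-gradient max): at likelihood
  curvatures of order n/5 this pins coefficients to ~1e−6.
* Standard errors come from the fixed-effect block of the inverse joint
  curvature in (β, u) at the optimum — the conditional-information
  estimator standard for this model family.
* A separation heuristic flags any standardized |β̂| > 10 with a warning.
* AICc = −2ℓ + 2k + 2k(k+1)/(n−k−1), with k = fixed effects (intercept,
  mains, survival main, interactions) + number of variance components and
  n = used + available rows; both are recorded in every `FitResult`
  because conventions differ across software.

### Validation oracles

Three independent routes check the fitter:

1. **Adaptive Gauss–Hermite quadrature** (`quadrature.py`): for
   single-factor models the marginal likelihood factorizes per group and
   is evaluated to near machine precision with 64 mode-centred,
   curvature-scaled nodes; a Nelder-Mead fit on that likelihood is the
   primary oracle. Laplace and AGHQ fits agree within 0.05 log-units and
   0.01 per coefficient on the test toys.
2. **IRLS logistic regression** (statsmodels GLM): with no random
   factors the fit must match to 1e−6 in coefficients and likelihood.
3. **lme4** (via Rscript, when available): one test compares a crossed
   two-factor fit against `glmer(..., nAGQ = 1)` — agreement to ~1e−3.

## Model set, ranking, and interaction importance

Fifteen a-priori candidates combine three covariate themes —
anthropogenic (the three distances), land cover (six dummies), vegetation
(NDVI) — each with and without survival interactions, from the full
interaction model down to the random-intercepts-only null; the set is
config-overridable (`build_candidate_set(specs=...)`), since any
real-data reanalysis must supply its own list. Models are ranked by AICc
with Akaike weights; Δ AICc ≥ 4 flags a model inconclusive. Importance of
interaction j in the best model is ΔAICc_diff(j) = AICc(best) −
AICc(best without j), with j's main effect kept; reported sign-reversed
(larger = more important) with the ≥ 4 conclusiveness threshold. Fit
failures are logged and never abort a ranking.

## The synthetic study

The generator emulates the monitored design so that every downstream
stage is testable without any download. Defaults:

* **Landscape**: one 400×400 grid of 25 m cells (10×10 km). Habitations
  are a homogeneous point process (40 points ≈ 0.4 km⁻²); roads are
  random crossing polylines (3 high-traffic, 14 forest roads,
  approximating the study system's 0.14 and 0.7 km km⁻² densities at
  this window size); land cover is a smoothed Gaussian field thresholded
  by rank into the seven classes at target proportions (10% bog, 10%
  TRB, 15% clearcut, 20% young, 20% mid-aged, 15% old, 10% other), so
  realized fractions are exact up to rounding and the mosaic inherits
  the field's patch structure; NDVI is an independent smoothed field
  rescaled into [0, 0.9].
* **Sample structure**: 19 successful bear-years over 16 individuals and
  11 unsuccessful over 10 (a few mothers re-monitored in a second year),
  years drawn from 2005–2012 (the crossed design). Home ranges are 2 km
  discs (~12.6 km², a mating-season scale); the pipeline never assumes
  disc shape — it re-estimates MCPs from the fixes.
* **Telemetry**: 48 scheduled fixes/day (30-min schedule) from 1 May,
  each acquired with probability 0.95; acquired fixes get DOP from a
  mixture with 37% mass on [5, 12] and the rest on [1, 5), so ~60% of
  scheduled fixes survive the DOP < 5 filter — the net retention the
  monitoring reported. Fix locations are rejection-sampled in the home
  disc with acceptance exp(η − η_max), the exponential RSF; scores with
  |η| > 50 raise rather than underflow.
* **Selection coefficients**: group-specific vectors on the standardized
  (cell-population moments), distance-oriented scale, set to the fitted
  values the monitored study reported — e.g. unsuccessful mothers avoid
  habitation (+0.210 on distance) while successful mothers select it
  (−0.524), with the largest group contrast on habitation and smaller
  contrasts on clearcut, roads and forest age classes.
* **Litter fates**: loss probability 0.35 (the population's average
  annual cub mortality) when fates are drawn stochastically
  (`simulate_fates`); the study constructor uses the fixed 19/11 design
  instead. Loss dates follow Beta(2, 3) rescaled onto 1 May–16 June —
  an assumed early-season skew, exposed in config, because only the
  season bounds are documented, not the empirical density.

What the generator does **not** emulate: temporal autocorrelation of
fixes (points are conditionally independent given the RSF, as the
fitted model also assumes), DOP-dependent position error, road-network
topology, multi-year demography, or any foraging/diet mechanism. Passing
tests therefore show the pipeline recovers a known exponential-RSF
signal under the monitored design's sampling structure — not that real
bear telemetry satisfies those assumptions.

## Telemetry preparation

* DOP filter: keep exactly `dop < 5` (the boundary value is removed).
* End dates for successful mothers are drawn from a Gaussian KDE
  (Silverman bandwidth on day-of-season integers) over the observed loss
  dates, rejected and redrawn until inside [season start, truncation
  date]; a single loss event degenerates to that date. Draws are
  independent per bear-year. Loss days are aligned by calendar day
  across years (leap-safe reference year).
* The analysis window is the closed interval [1 May, end], end = loss
  date or assigned end date, never past the study-wide truncation date
  (last observed loss); dates compare at day resolution and a fix on the
  end date is retained.
* Mothers with partial litter loss are excluded, as are bear-years with
  < 2 monitored days or < 50 retained fixes (configurable), with logged
  reasons.
* Cluster sites (≥ 3 consecutive fixes within 15 m) use a running
  centroid rule — every member must stay within 15 m of the recomputed
  centroid as the run extends — matching the revisited-location
  semantics; a first-fix-reference variant is available by flag.
  Clusters are diagnostics; the models do not use them.

## Home ranges and availability

The availability domain is the 100% MCP: the convex hull of all the
bear-year's retained fixes (collinear boundary points are excluded from
the vertex list; fewer than 3 non-collinear points is an error).
Point-in-polygon is boundary-inclusive, so hull vertices are valid
availability draws. Availability is uniform rejection sampling from the
polygon's bounding box, matched in count to the retained used points,
from a random stream that depends only on the seed — never on the used
locations. Second-order (study-area) availability uses the union extent
of all MCPs, or a supplied polygon.

**MCP attenuation.** Because the MCP is the hull of the used points
themselves, it under-covers edge habitat the animal avoids, which
slightly compresses the used-versus-available contrast: selection
estimates under MCP availability are attenuated by a few percent,
worst for smooth long-range covariates such as distance to a sparse road
network. This is a property of the availability protocol, not of the
estimator; the parameter-recovery harness therefore draws availability
from the generator's true home discs, while the pipeline and the
importance analyses use the MCP protocol as specified.

## Validation studies and problem sizes

* **Parameter recovery** (harness + acceptance test): 20 replicates of
  the full design (30 bear-years, ~500 retained fixes each, ~30 000
  rows). Scored as pooled 2-s.e. coverage over the 20 fixed effects ×
  20 replicates (≥ 90%, against a ~95% nominal rate; the margin absorbs
  the mild extra dispersion from per-range intercept heterogeneity,
  which the Gaussian random intercept only approximates), a 75% per-term
  floor, and the qualitative habitation sign pattern in ≥ 95% of
  replicates. Generating coefficients are mapped to the analysis scale
  by the exact identity β·sd_sample/sd_cell (two standardizations of the
  same raw covariate).
* **Importance ranking**: 20 replicates with the group contrast only on
  distance-to-habitation, and 20 with identical groups. These use a
  sparser 8 fixes/day schedule (~85 retained fixes per bear-year, ~5 000
  rows) so that each replicate's eleven model fits stay cheap; the
  habitation contrast is far above the detection threshold at that size,
  so the ranking check loses nothing.
* The analysis scripts and `scripts/acceptance.py` run reduced replicate
  counts of the same studies; `tests/test_acceptance.py` runs the full
  designs.

## Repository shape

The package is organised as an analysis project: `src/bearshield/` holds
every computational step as an importable, tested library;
`analysis/01…05` are thin narrative drivers that run the study and write
`results/`; `pipeline.run_pipeline` is the one-call orchestration used by
both. No shell CLI is shipped — the scripts and the library are the
interface. Every output CSV carries a seed + config-hash stamp and each
run writes `runinfo.json`, so any stage is exactly reproducible from
(config, seed).

## Known limitations

* Random-intercept shrinkage only approximates the per-home-range
  normalizing constants of the RSF; with strong between-range
  availability differences the coverage of nominal standard errors is
  slightly optimistic (quantified by the recovery study).
* The Laplace approximation is the standard estimator for crossed
  binary GLMMs but has no exact-likelihood guarantee; its error is
  bounded empirically by the AGHQ oracle on single-factor designs only.
* The 15-model candidate list follows the described pattern (thematic
  subsets × interaction sets); a real-data reanalysis must supply the
  original list.
* Second-order availability uses a rectangular study-area extent unless
  a polygon is provided.
* No temporal covariates, random slopes, or autocorrelation structures.
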