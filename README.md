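# bearshield

Habitat selection contrasted by litter fate in brown-bear mothers — a
use–availability resource selection analysis asking whether mothers whose
litters survive the mating season shelter near people ("human shields")
while mothers that lose their litters avoid human footprint.

## The scientific problem

In Scandinavian brown bears (*Ursus arctos*), sexually selected
infanticide (SSI) by adult males is the dominant cause of cub mortality
and is concentrated in the mating season (May–mid July). Adult males
strongly avoid human footprint; mothers with cubs may therefore exploit
human-proximate habitat as a refuge. If that strategy works, habitat
selection should predict litter survival: mothers keeping their cubs
should select areas near habitation, and mothers losing them should not.

The analysis contrasts GPS-collared mothers that were **successful**
(litter survived) and **unsuccessful** (complete litter loss) with a
resource selection function (RSF): GPS relocations are "use" (y = 1),
random locations within each mother's 100% minimum convex polygon home
range are "availability" (y = 0, matched 1:1 in count), and selection is
estimated by a logistic mixed model

```
logit P(y=1) = x'β + (x ∘ s)'γ + u_bear + u_year,
u_bear ~ N(0, σ²_id),  u_year ~ N(0, σ²_year)
```

where `x` holds the standardized landscape covariates (distance to
habitation, road and forest road in km; NDVI; six land-cover dummies
against an "other" baseline), `s` is the litter-survival flag, and the
interactions `γ` carry the group contrast. The marginal likelihood over
the crossed random intercepts is evaluated by a Laplace approximation and
maximized directly (ML). Fifteen a-priori candidate models are ranked by
AICc with Akaike weights; the importance of each survival interaction is
`ΔAICc_diff` — the AICc change from refitting the best model without that
one interaction — reported sign-reversed so that values ≥ 4 are
conclusive. For display, signs of "distance to" estimates are reversed so
positive always reads "selection for".

Because the original collar data are proprietary, the package ships a
synthetic-data generator with known ground truth: a landscape raster
stack (25 m grid), habitation/road features, and per-mother telemetry on
the 30-min collar schedule with DOP-contaminated fixes and early-season
litter-loss dates, drawn from an exponential RSF with group-specific
coefficients. Every downstream stage is validated against that truth.

## Worked example

The numbered scripts under `analysis/` run the study end to end and write
tables and figures under `results/`. `python analysis/02_prepare_telemetry.py`
prints the monitoring structure of the simulated sample:

```
kept 30 bear-years; excluded 0
mean retained fixes: successful 495, lost 492
fix rates 0.601 vs 0.594: Welch t_27.1 = 1.069, p = 0.295 (no group difference, as required)
study truncated at 03 June (last observed loss)
```

i.e. 19 successful and 11 unsuccessful bear-years, ~60% of scheduled
fixes surviving the DOP < 5 filter, and monitoring windows truncated at
the last observed loss date. `python analysis/04_habitat_selection.py`
then fits and compares the models:

```
best model: full + all interactions (AICc weight 1.000)

interaction importance (sign-reversed delta AICc_diff; >= 4 conclusive):
            term  estimate       se  reported_importance  conclusive
 dist_habitation -0.831387 0.030079           772.546757        True
        clearcut  1.066323 0.107481            97.000965        True
       dist_road -0.170853 0.026357            40.201031        True
             old -0.460371 0.099825            19.289697        True
             bog -0.365151 0.140153             4.799507        True
        mid_aged  0.211690 0.096980             2.755029       False
...
habitation selection by group (sign-reversed: positive = selects proximity):
           term        group  estimate       se        lo        hi
dist_habitation unsuccessful -0.233922 0.023405 -0.279797 -0.188048
dist_habitation   successful  0.597464 0.018652  0.560906  0.634022
```

Reading: the full interaction model takes all the Akaike weight; the
habitation × survival interaction towers over every other term; and the
sign-reversed group estimates say unsuccessful mothers avoid habitation
(−0.23 ± 0.02) while successful mothers select it (+0.60 ± 0.02) — the
human-shield pattern the generator encodes and the analysis must find.
`python analysis/05_validation.py` runs the recovery and
importance-ranking checks against the generating coefficients.

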