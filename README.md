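# leatherback-pva

Population viability analysis for the Eastern Pacific (EP) leatherback
turtle (*Dermochelys coriacea*), the most endangered sea turtle population
in the world.  The package is aimed at quantitative conservation
biologists who need to (i) project the EP metapopulation under current
conditions and under hypothetical conservation interventions, (ii)
estimate adult survival, transience and remigration from nesting-beach
capture–recapture data, and (iii) translate survivorship targets into
concrete numbers of turtles that bycatch-reduction efforts must save.

## The model

**Projection.**  A female-only, pre-breeding-census matrix model with
eight life stages per nesting subpopulation (Costa Rica/Nicaragua and
México; sixteen named stages in all): yearling *Y*, juvenile *I1* (2 yr),
subadult *I2* (9 yr), *Breeder*, at-sea remigration stages *A2*, *A3*,
*A4+*, and a *Transient* stage for females that nest once and never
return.  Hatchling production per female is

    H = f · es · w · fem        (Costa Rica / Nicaragua)
    H = f · hw · fem            (México, where egg-to-water survival hw
                                 is known directly)

and the fertility coefficient is `F = H · S1` (first-year survival folded
in by the census convention).  Multi-year stages are age-expanded by
default: each year of *I1*/*I2* is its own matrix class, which reproduces
the published calibration that juvenile survival `S2 = 0.5` holds the
population stationary once adult survival exceeds 0.90.

The headline deterministic growth rate is the mean annual rate of the
100-year projection started from the observed population state (176
annual breeders split by nesting shares, plus the hatchlings they
produce); the dominant eigenvalue (asymptotic rate) is reported
separately.  The stochastic rate λ_s comes from Monte-Carlo trajectories
with beta-distributed survivals and proportions (sampling variance from
published confidence intervals, yearly process variance at a 5% CV,
fecundity from a mean-corrected truncated normal), and quasi-extinction
is declared when the subadult + adult female pool drops below one.

**Scenarios.**  Conservation interventions are declarative
`ScenarioSpec`s: relative increases in adult/subadult survival (a proxy
for bycatch-mortality reduction, optionally as a stepwise schedule),
egg-harvest eradication, emergence-success lifts, loss of clutch
relocation, and head-starting.  Ten canonical combinations and four
stepwise ramps ship as packaged presets.

**Capture–recapture.**  A multi-event model with twelve hidden states
(breeder, at sea 1–10 years, dead), binary detection of breeders only,
and a three-step transition decomposition (transience, survival,
recruitment).  Likelihoods are hidden-state forward recursions fitted by
multi-start quasi-Newton ML with √ĉ-inflated standard errors and QAICc
model selection; immediate trap-dependence and logit-linear climate
covariates (e.g. an ENSO index on survival) are available.

**Bycatch accounting.**  Gear-stratified interaction records with 5%
(longline) / 33% (net) mortality defaults, and the two published routes
to the "turtles saved per year" target for a 20% bycatch-mortality
reduction.

## Worked example

```bash
$ leatherback-pva project --seed 1 --out results
            quantity     value
lambda_deterministic  0.871892
   lambda_asymptotic  0.901039
            lambda_s  0.870214
     lambda_s_ci_low  0.841617
    lambda_s_ci_high  0.896813
        p_extinction  1.000000
 t_extinction_median 57.000000
```

Under current conditions the population shrinks about 13% per year
(`lambda_deterministic` ≈ 0.87), every Monte-Carlo trajectory falls below
one subadult/adult female within the century, and the median
quasi-extinction time is under 60 years.  The asymptotic eigenvalue is
higher (0.90) because the observed stage structure is far from the stable
one — the projected early decades decline faster than the long-run rate.

```bash
$ leatherback-pva bycatch --out results
...
         interactions_total 440.0000
      interactions_per_year  96.9163
           model_deaths_now 369.1600
        model_deaths_target 107.3920
                model_saved 261.7680
        model_females_saved 218.0880
```

The packaged regional records sum to 440 bycaught leatherbacks (~97 per
year).  With ~1,678 subadults and adults in the population, raising
late-stage survivorship from 0.78 to 0.936 (a 20% increase, the level at
which projections turn positive) would spare ≈ 262 turtles (≈ 218
females) per year.

The full scenario table (ten interventions, 1000 trajectories × 100
years, a few minutes on one core):

```bash
leatherback-pva scenarios --seed 1 --out results
```

From Python:

```python
from leatherback_pva import (load_table1, StochasticSpec, project_ensemble,
                             project_result, ScenarioSpec)

base = load_table1()
spec = StochasticSpec(n_trajectories=1000, horizon=100, seed=1)
cut20 = ScenarioSpec(label="bycatch -20%", bycatch_reduction=0.20)
res = project_result(project_ensemble(base, spec, cut20.bind(base)))
print(res.lambda_s)          # ~1.004: the population stabilises
```

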