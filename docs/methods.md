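# Methods

## Life cycle and matrix structure

The projection model is female-only with a pre-breeding census.  Each of
the two demographic units (Costa Rica — whose rates Nicaragua shares —
and México) has eight stages: yearling `Y`, juvenile `I1` (ages 1–3),
subadult `I2` (ages 3–12), `Breeder`, at-sea stages `A2`/`A3`/`A4+`
indexed by years since last breeding, and `Transient` for females that
nest in a single season and are never seen again.  Transients breed once
(their column carries the fertility coefficient) and then leave the
modelled population; given mark–recapture data alone this is
indistinguishable from death or permanent emigration.  The two blocks are
uncoupled; Nicaragua's 2.4% nesting share is folded into the Costa Rica
block because the rates are identical.

Fertility is `F = H · S1` with `H` the female hatchlings reaching the
water per nesting female.  The remigration loop applies survival `S3`
jointly with the breeding propensities: `B → B` with `S3·B1`,
`B → A2` with `S3·(1−B1)`, `A2 → B` with `S3·B2`, and so on; `A4+`
self-loops with `S3·(1−B4)`, pooling all intervals of four or more years
on the single published `B4`.

### Stage durations

The multi-year stages need a within-stage rule, and the choice moves the
growth rate by several percent.  Two rules are implemented:

* **age-expanded** (default): every year of `I1`/`I2` is a separate
  matrix class (17 classes per block, 34 × 34 overall, aggregated back to
  the 16 named stages for reporting).  Stage durations are then exact.
* **geometric**: one class per stage (16 × 16) with stay probability
  `S·(1−1/d)` and advance probability `S/d`.

The age-expanded rule is the default because it uniquely reproduces an
internal calibration of the source parameterisation: juvenile survival
`S2 = 0.500` was chosen to make the population stationary when adult
survival is ≥ 0.90 without anthropogenic mortality, and under the
age-expanded rule stationarity at `S3 = 0.90` requires `S2 = 0.495`
(the geometric rule would require `S2 ≈ 0.39`).

## Growth rates

With the two blocks uncoupled, the dominant eigenvalue of the full matrix
is the larger block eigenvalue (0.901 for Costa Rica, 0.836 for México at
current rates) and ignores both the declining mixture and the observed
stage structure.  The headline deterministic rate is therefore defined as
the **realized mean annual growth of the 100-year projection** from the
observed initial state: 176 annual breeders split 75.4 / 24.6 between the
México and Costa Rica (+Nicaragua) blocks, plus the hatchlings those
breeders produce, with the unobserved juvenile and at-sea pools empty.
This definition gives 0.872 under current conditions; the eigenvalue is
reported alongside as the asymptotic rate.  An SSD-scaled initial vector
is available as an option.

The stochastic rate is `λ_s = exp(grand mean of per-trajectory mean
annual log growth of total females)` over the full horizon, with the 95%
interval taken as the 2.5/97.5 percentiles of the per-trajectory rates.
Averaging over the full horizon (rather than truncating at
quasi-extinction) keeps the zero-variance model exactly equal to the
deterministic rate; the rates-based projection never reaches true zero.

## Variance model

* **Sampling (parameter) uncertainty** — drawn once per trajectory,
  independently per block, as betas matching the published 95% CIs
  (CI width / 3.92 as SE): adult survival `S3` (0.750–0.807 CR,
  0.675–0.741 MX) and transient probability (0.157–0.346 CR, 0.106–0.560
  MX).  No other parameter has a published interval in the main text.
* **Process (environmental) variance** — drawn each year with a 5% CV
  (configurable) on every survival, breeding propensity and proportion.
  Yearly deviates are shared between blocks through a Gaussian copula
  (same environment), while the beta marginals differ per block.
* **Fecundity** — eggs/female/season from a zero-truncated normal whose
  CV propagates the published clutch-size and clutch-frequency SDs
  (16.6/3.1 CR, 16.5/2.2 MX; CVs ≈ 0.57 and 0.45).  The truncated
  location is rescaled so the draw's mean equals the estimated mean.
  Fecundity dispersion is switched off together with the process CV.
* Draws are independent across years (no autocorrelation), and breeders
  and non-breeders share the same annual survival draw.

The probability-of-extinction of knife-edge scenarios (5–10% bycatch
reductions) is sensitive to the parameter-uncertainty structure; the
source analysis used a full variance–covariance matrix that is not
published, so those probabilities are reproduced only approximately here.

## Quasi-extinction

A trajectory is quasi-extinct in the first year the subadult + adult
female pool (`I2` onward) falls below one female.  The late-stage pool is
the observable segment of the population — abundance statements such as
"≈1,678 subadults and adults" refer to it — and using it avoids declaring
persistence on the strength of model-bookkeeping hatchling counts.  Both
the threshold and the monitored stage set are configurable.  The median
extinction year is reported across extinct trajectories and is undefined
when fewer than 0.5% of trajectories go extinct (the dashes of the
scenario table).

## Scenarios

* **Bycatch reduction** multiplies `S3` by `1 + r` (capped at 0.98, a
  guard that current parameter values never reach), optionally through a
  piecewise-constant schedule of `(start_year, r)` steps.
* **Harvest eradication** multiplies hatchling output by
  `1/(1 − harvest)` (1% CR, 4.2% MX): the measured success rates already
  reflect current egg take.
* **Emergence increase** lifts emergence success toward a 0.60 target:
  the Costa Rica lift is the ratio `0.60/0.40` on hatchling output; for
  México only the combined egg-to-water proportion (0.47) is known, and
  it is raised to 0.60 directly.  This combination yields ≈ 7,800
  additional female hatchlings per year at current breeder numbers, the
  published 7–8k range, whereas a proportional 1.5× lift on both blocks
  would imply ≈ 12,500.
* **No relocation** applies a hatchling-output penalty of 0.918,
  calibrated once by 1-D root-finding so that removing relocation lowers
  the deterministic rate by 0.004 (the published contrast); no direct
  relocation-benefit measurement exists.
* **Head-starting** caps the annual cohort at the hatchlings actually
  produced in Costa Rica that year and accounts it net: the cohort is
  withdrawn from the wild pool (forgoing wild first-year survival `S1`)
  and released into the yearling stage at a release survival that
  defaults to `S1` itself, following the description of the intervention
  as applying year-one survivorship to 50 individuals.  Under this
  default the packaged scenario's demographic effect is nil by
  construction — matching the published finding that head-starting at
  realistic scale is negligible — and optimistic captive survival can be
  explored via `headstart_release_survival=1.0`.  A gross-addition helper
  (`headstart_injection`) is exposed for direct vector manipulation.

Scenario tables run all scenarios on common random numbers, so
differences between rows are intervention effects only and an identity
scenario is bit-identical to the status quo.  The packaged scenarios 8–10
include harvest eradication: the published table marks them "no", but the
accompanying text describes them as achieving *full nest protection*
together with increased emergence; the conflict is resolved toward the
text (the numerical consequence is < 0.001 on λ_s).  The stepwise presets
11, 13 and 14 are plausible ramps, not published parameterisations; only
scenario 12's schedule (5 status-quo years, then 5-year blocks at 5%,
10%, 20%) is described in the source.

## Capture–recapture estimator

Twelve hidden states (breeder; at sea 1–10 years since breeding; dead)
with binary events (seen nesting / not seen) and detection only in the
breeder state.  Transitions decompose into transience (first transition
after initial capture only: a transient permanently leaves the observable
population), survival, and recruitment (`B1`–`B4`, with the pooled `B4`
for at-sea years 4–10; the at-sea-10 state self-loops when not
recruiting).  Likelihoods condition on first capture in state `B`.

Time-constant models use a suffix-aligned forward recursion over unique
histories (padded steps apply a row-stochastic transition and an
all-ones event vector, leaving the mass invariant); covariate models run
on the calendar axis.  Fitting is multi-start (default 10) L-BFGS-B on
the logit scale, standard errors from a central-finite-difference
Hessian inflated by √ĉ, Wald intervals transformed from the logit scale,
and estimates with |logit| > 7 flagged as boundary cases.  Overdispersion
ĉ is an input (the source's values: 1.638 México, 3.053 Costa Rica);
goodness-of-fit testing itself is out of scope.  Trap awareness is
implemented as immediate trap-dependence — detection probability switches
on whether the individual was seen at the previous occasion — which is a
simplification of memory-model formulations.  `n_eff` for QAICc is the
number of individuals.

## Synthetic data

Generators emulate the undeposited field data: clutch-level nesting
records (shifted-Poisson clutch counts with the published mean clutch
frequency, truncated-normal clutch sizes, binomial emergence and
reaching-water), encounter histories from the hidden-state model, and
Poisson/binomial bycatch records.  They reproduce configured means by
construction and are seeded; they do **not** emulate beach-coverage
gaps, within-season detection, tag loss, individual heterogeneity, or
temporal trends, so passing recovery tests demonstrates estimator
correctness under the model, not robustness to real-data violations.

## Problem sizes and numerics

Monte-Carlo results use 1000 trajectories × 100 years (the study design);
unit tests use smaller ensembles (50–500 trajectories) chosen for
precision of the property under test.  The CI-coverage experiment uses
100 replicates of 3,000 individuals × 22 seasons.  Beta draws with zero
variance return the mean exactly; infeasible parameterisations
(variance ≥ mean(1−mean)) raise errors at validation.  Eigen-computations
use dense LAPACK routines with a 1e-10 residual check on the stable stage
distribution; reducible matrices with tied dominant eigenvalues are
flagged as non-unique.

## Known limitations

* No density dependence, demographic (individual-level) stochasticity,
  spatial exchange between subpopulations, or climate trends in vital
  rates.
* The block-mixture stable stage distribution implies ≈ 2,800 late-stage
  females at 176 breeders/yr — about twice the published ≈ 1,398 —
  and no stage subset of the calibrated model reproduces that figure;
  the published mortality-target arithmetic is therefore computed from
  its stated inputs (1,678 / 1,398) rather than re-derived.
* Scenario extinction probabilities near the persistence boundary and CI
  widths inherit the unpublished variance–covariance structure (see
  above) and are approximate.
* The exact candidate model set of the source capture–recapture analysis
  (its supplement) is not reproducible; the module exposes the building
  blocks, not that model list.
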