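# Methods

This note records the statistical model behind `roostnet`, the choices
that were genuinely open when it was built, and what its synthetic-data
experiments do and do not demonstrate.

## Data model

The sampling unit is the *group capture*: one day roost netted on one
date, with every caught bat identified. Capture events are derived by
grouping records on (date, roost); two captures of the same roost on
different dates are distinct events, because association is defined as
occupying the same day roost at the same time. Roosts belong to exactly
one of two populations (the populations are genetically distinct and
closed to each other at the roosting time scale), and the calendar year
of an event is its year stratum. Reproductive status is optional
everywhere; composition classes (all-male / all-female / mixed) are
computed from sex alone. The analysis set is produced by an adults-only
filter followed by a minimum-sightings filter counted *within* the
adult records ("captured at least four times as an adult",
default threshold 4); the filter is idempotent.

## Association and social differentiation

Dyadic association is the simple ratio index over sampling periods:

    SRI(a, b) = x / (x + y_ab + y_a + y_b)

`x` = periods with a and b in the same group; `y_ab` = both seen,
never together; `y_a`, `y_b` = only one seen. The denominator is the
number of periods in which at least one of the pair was seen. More
elaborate indices (half-weight and relatives) are deliberately not
implemented: they only improve on the SRI under specific missed-
observation models and are harder to interpret.

**Sampling-period convention (open choice).** Whether the period is the
capture event itself or the (date, population) pair is not dictated by
the definition. The default here is (date, population): two bats caught
the same day in different roosts of one population are *seen apart*
(`y_ab`), which the event-level convention cannot express. The
event-level alternative is selectable (`period="event"`); with it
`y_ab` is structurally zero. Cross-population dyads get a defined SRI
(near zero) but are excluded from within-population analyses by
masking; dyads never co-sampled (zero denominator) are flagged
undefined and dropped listwise everywhere.

Social differentiation is the coefficient of variation of the SRI over
defined dyads, population-sd convention by default (`ddof=0`;
sample-sd switchable). A zero mean SRI makes the CV undefined (NaN),
reported as such.

## Datastream permutation null

The null generator swaps the identities of two individual observations
drawn from one (population, roost, year) stratum, rejecting swaps that
would place a bat twice in one event, and rebuilds the association
network every `swaps_per_sample` accepted swaps after `burn_in_swaps`
accepted swaps. Every sampled network preserves exactly: event group
sizes, per-bat sighting counts, per-bat stratum visit counts, and
within-event uniqueness. Consequently any association attributable to
*where* and *when* a bat was seen survives into the null, and the test
isolates preference beyond those confounds — including confounds from
biased detectability, since the same biased sample is permuted.

**Burn-in and thinning (open choice).** No published values exist for
this design; the defaults (1000 burn-in, 100 swaps per sample, counted
on an accepted-swap clock so sparse strata do not stall the chain) follow
common datastream-permutation practice and are config-exposed. The
small-study experiments use 300/20, which the toy-configuration
uniformity check (all 12 reachable configurations of a 3-event stratum
visited uniformly) and the calibration experiment support. Before any
sampling the generator verifies a valid swap exists somewhere and
errors otherwise (a reverse swap always exists afterwards, so the chain
cannot dead-end later).

Empirical p-values are tail proportions with ties counted as extreme;
two-sided values are twice the smaller tail, capped at 1. A zero tail
count is reported as the bound `< 1/n` rather than 0.

## Matrix tests

Mantel tests correlate vectorised lower triangles of two aligned dyadic
matrices (Pearson), with nulls from jointly permuting the second
matrix's labels. QAP regression fits OLS (intercept included, raw
scale; z-scoring switchable) over defined dyads, with null coefficients
from either node permutation of the response or — for association
responses — the datastream null networks regressed against the
*unpermuted* predictors. Dekker-style semi-partialling is not used:
the headline analyses test one predictor at a time against custom
nulls, and a multi-predictor call is documented as a joint refit.
Collinear predictors (including a constant relatedness matrix within a
subset, common when every pair is unrelated) raise an error; the
kin-bias battery skips such subsets and says so.

Sex-subset analyses (females-only, males-only) subset the bats first
and rebuild the dyad set; SRI values are unchanged by subsetting since
each dyad's index depends only on its own observations. The Mantel
dyad-type analyses accept an explicit bat list because the genotyped
set need not coincide with any sighting-threshold set.

## Univariate permutation tests

Group-difference tests are permutation-only: the mean-difference test
(10 000 label shuffles by default) and the variance-ratio test (5000),
both with the two-sided-doubled convention and exact enumeration
available for small groups. The variance-ratio orientation follows the
declared group order and is always reported. Philopatry is tested on
juvenile-to-adult recapture spans (days between first juvenile and last
adult capture). The two-male relatedness null resamples, for each group
with exactly two reproductive (scrotal) males, two distinct adult males
captured in the same population and calendar year — the operational
reading of "the same times and locations", narrowable to same-roost —
and reports the 2.5/97.5 percentile band of the replicate means.
Per-bat roost spread is the mean pairwise distance between the distinct
roosts a bat used; single-roost bats contribute 0 (not missing), which
keeps them in the sex comparison. Registries declare their coordinate
system: planar metres (Euclidean) or lon/lat (great-circle).

## Synthetic data generator

The generator produces the structure the analysis assumes, with known
truth:

- **Pedigree**: overlapping generations; founders are established
  adults split across two closed populations; each adult female has at
  most one pup per year (probability `pup_rate` = 0.5/yr) sired by a
  random resident male; adults survive each year with probability 0.88;
  locally born males face an annual emigration hazard
  (`male_dispersal_prob` = 0.85) from maturity — so natal males are
  essentially never present as older adults — while immigrant adult
  males arrive at ~3 per population-year; females are philopatric.
- **Relatedness** is twice the kinship coefficient from the standard
  tabular recurrence (clamped to [0, 1], as a marker-based estimator's
  range), plus truncated Gaussian noise (sd 0.05 by default)
  emulating the error of a marker-based relatedness estimator.
- **Roosting**: each population keeps `groups_per_day` roosts open;
  each open roost relocates wholesale to an unused roost with
  probability 0.15/day (fission–fusion switching at the ~0.1–0.5 km
  roost-spacing scale). Bats re-assort daily, sequentially in random
  order, joining the open roost that maximises
  `π·(mean past association) + κ·(mean relatedness to female members;
  female choosers only) − male_avoidance·(males present; male choosers)
  − crowding·(members present) + Gumbel(0,1)`.
  The crowding term models limited roost capacity; without it,
  preference reinforcement collapses each population into one permanent
  group instead of fission–fusion subgroups. With all four social terms
  zero the rule is exactly uniform-random assignment — the calibration
  null.
- **Capture**: per year, a fixed number of occupied roost-days are
  netted; each present bat is detected independently (default 0.7,
  bats escape); pups of the year roost with their mother and are
  recorded as juveniles.

Default scale (60 founders, 6 years, 16 roosts and 8 open
roosts/population, 18 captures/year) yields ≈ 150–170 marked bats,
≈ 105 group captures, ≈ 450–550 individual observations, median group
size 4–5, and ≈ 40–50 adults seen ≥ 4 times with a balanced sex ratio —
the scale of a multi-year two-population field study, so power numbers
computed on it are field-relevant.

**What the generator does not emulate**: immigration of related males,
seasonal reproduction and seasonal roost preferences, inter-annual
site fidelity drift, tag loss, capture avoidance after handling, and
genotyping error structure beyond i.i.d. Gaussian noise. Passing tests
therefore show the *machinery* is correct and calibrated for data with
the assumed structure, not that real data meet those assumptions.

## Calibration and power experiments

- **Calibration** (type-I error): 500 replicate no-preference studies
  (κ = π = male_avoidance = crowding = 0; 24 founders, 2 years, 3 open
  roosts of 5 per population, 20 roosting days and 16 captures per
  year, detection 0.9, relatedness noise sd 0.05), 200 null networks
  each (300 burn-in, 20-swap thinning), sighting threshold 3. Both the
  CV test and the female-subset QAP relatedness test must reject at
  α = 0.05 within the binomial 99% band. With 200 networks the doubled
  empirical p is discrete (rejection iff a tail count ≤ 5), so the
  exact attainable level is ≈ 0.06, inside the band.
- **Power** (parameter recovery): 100 replicates at the documented
  point κ = 8 (females only), π = 3, crowding 0.6, male_avoidance 0
  (40 founders, 4 years, 30 days and 20 captures per year, detection
  0.9). Success = female-subset relatedness beta positive and
  significant *and* male-subset beta non-significant at α = 0.05;
  the observed pattern rate is ≈ 0.9, against the ≥ 0.8 requirement.
  Note the male side of the pattern fails ~5% of the time by
  construction (it is a true-null test at α = 0.05), so the ceiling is
  ≈ 0.95 × female power.

Replicate sizes, network counts, and permutation settings in these
experiments are the package's documented experimental conditions,
chosen so hundreds of full-pipeline replicates are routine.

## Numerical notes and edge cases

- Zero-variance vectors are detected with an exact max==min test, not
  a floating `std == 0` comparison.
- `empirical_p` accepts ±inf statistics (orderings remain defined; the
  variance ratio is flagged infinite when the denominator group has
  zero variance) and rejects NaN.
- Matrix alignment is by explicit bat lists; subsetting is always by
  id, never positional.
- Undefined dyads (zero SRI denominator, ungenotyped pairs) are
  dropped listwise from matrix tests; a dyad with a positive
  denominator and no joint sightings is a true zero and retained.
- Dates are calendar dates; the year stratum is the calendar year.
- The two-male resampling redraws (up to 20 times) around missing
  relatedness values instead of treating them as zero.

## Known limitations

- The QAP null for sex subsets subsets the full-network permutations
  rather than re-permuting within the subset; this matches the custom-
  null design (the datastream null is defined on the full records) but
  means subset tests inherit the full network's mixing.
- The Mantel implementation permutes one matrix's labels (node
  permutation) only; datastream nulls for Mantel are not implemented
  because the headline analyses use QAP for association responses.
- Group assembly is sequential-greedy; it produces fission–fusion
  mixing but is not a mechanistic model of roost choice, and π, κ are
  in noise units, not measurable field quantities.
- At exactly the default sampling intensity (18 captures/year,
  detection 0.7) the CV and kin-bias tests have modest power: single
  simulated studies frequently fail to reach significance at the
  default preference strengths even though the structure is real.
  Detection becomes reliable at ~30 captures/year with detection 0.9
  (the power experiment's conditions); field detections at lower
  effort imply either stronger true structure or stabilising features
  (e.g. long-term individual site fidelity) the generator does not
  model.
- When the observed data contain strong partner preference, the
  custom-null betas of *nuisance* predictors are slightly too narrow
  (the permuted networks carry no preference), inflating their type-I
  error a little above nominal; the calibration experiment bounds this
  under the null, but interpret marginal nuisance-predictor p-values
  cautiously.
- With very sparse strata the accepted-swap chain can mix slowly;
  the conservation invariants still hold exactly, but p-values from
  under-mixed chains are conservative. Check `PermutationState`
  acceptance counts when in doubt.
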