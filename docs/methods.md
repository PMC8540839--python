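# Methods

This note documents the models and estimators implemented in `gallwasp`,
the defaults of the synthetic-data generator, the numerical conventions,
and the design choices made where the underlying field methodology leaves
the implementation genuinely open. It states no empirical result that the
test suite or `scripts/acceptance.py` does not itself compute.

## Temperature downscaling and cumulative °C

Locality-level daily mean temperatures are estimated from a single
reference station by the *monthly delta* method: for calendar month *m*,

    offset_m = locality monthly normal_m − station monthly normal_m

and every day of the station record receives the offset of its month. This
is the simplest estimator consistent with anomaly-based downscaling from
historical normals; it preserves the station's day-to-day variability and
shifts its level. No smoothing is applied across month boundaries (offsets
change stepwise on the 1st), and no elevation lapse-rate correction is
applied — the monthly normals already embody each locality's elevation.
Both choices are deliberate simplifications; the delta method is isolated
in `thermal.downscale_daily` so alternatives can be swapped.

*Cumulative °C* at a target date is the sum of daily mean temperatures over
the half-open window (anchor, target] — the anchor day itself is excluded,
so accumulation starts the day after the anchor. The anchor is the previous
season's flight-peak date when one exists; otherwise a configurable
fallback, default **1 July of the prior year**, chosen because adult flight
spans late spring to mid-summer and oviposition follows the flight peak. No
lower development threshold is subtracted by default (the accumulation is a
raw thermal sum, so negative winter means subtract); `base_temp > 0`
switches to conventional degree-days, where each day contributes
max(tmean − base, 0). Dates are ISO-8601 calendar dates; leap days are
summed like any other day.

The half-open window makes cumulative °C exactly additive over a split,
C(a→t₂) = C(a→t₁) + C(t₁→t₂), which the suite verifies against brute-force
day-by-day summation.

## Stage profiles and survival estimation

Dissection records carry per-bud counts of the six stages
{egg, L1, L2, L3, pupa, adult}. A *stage profile* for one
(locality, cohort, sampling date) gives mean individuals per bud (stage
total / buds dissected) and relative stage abundances (stage total / grand
total; flagged undefined when nothing was found). The *mean development
stage* is the abundance-weighted mean of stage indices, egg = 0 … adult = 5.

Because sampling is cross-sectional and destructive (each date dissects
fresh buds), per-stage survival cannot be followed on marked individuals.
The estimator used is the **peak-ratio rule**: survival of transition
s → s+1 is the across-date peak of stage s+1's per-bud density divided by
the across-date peak of stage s's density. The rationale: stages occupy
overlapping but distinct time windows, and at the height of a stage's
window essentially every surviving cohort member is in that stage, so the
peak density approximates the number that ever reached it. Raw ratios above
1 — expected occasionally from sampling noise — are capped at 1 and
flagged, since a survival is a probability. The estimator is isolated in
`lifetables.transition_survivals` so a different rule (e.g. final-census
ratios) can replace it. Total egg-to-adult survival is the product of the
five transitions.

Accuracy of this estimator at field-realistic scale is quantified by
`validation.survival_recovery`: cohorts generated with known survivals
(0.9, 0.85, 0.8, 0.75, 0.9) at 500 buds per sampling, 20 seeds; the suite
requires mean absolute error ≤ 0.05 per transition and mean relative R₀
error ≤ 10 %.

## Life tables and population parameters

The life table assigns each stage an age x (years since oviposition),
survivorship lₓ (cumulative product of transition survivals, l₀ = 1) and
fecundity bₓ. The species is parthenogenetic and univoltine, so bₓ is
concentrated at the adult stage; the default stage ages
(0, 1/12, 0.75, 0.83, 0.92, 1.0) encode the field calendar — hatching about
a month after summer oviposition, L1 overwintering in the bud until spring
bud burst, the later instars and pupa through late spring, adults one year
after oviposition.

Fecundity here is *effective* fecundity: offspring that appear as eggs in
sampled buds the next season per adult, either user-supplied or estimable
as next-cohort eggs-per-bud over current-cohort adults-per-bud. It is far
below the physiological egg load because not all eggs land in the sampled
bud population.

From a table, `population_parameters` derives R₀ = Σ lₓ·bₓ and then follows
one of two chains:

* **census chain** (two successive annual egg-density censuses given):
  λ = N_{t+1}/N_t, r = ln λ / Δt, T = ln R₀ / r. The cohort's census
  density N_t is eggs per bud at the first sampling — eggs are the cohort's
  birth class.
* **life-table chain** (no censuses): T = Σ x·lₓ·bₓ / R₀, r = ln R₀ / T,
  λ = e^{rΔt}.

Either chain is algebraically closed: e^r = λ and R₀ = λ^T hold to 1e−12,
and the trend classification (R₀ vs 1, r vs 0, λ vs 1) is consistent by
construction. A cohort with R₀ = 0 is returned as degenerate (r = −∞,
λ = 0) rather than raising, since total cohort failure is a legitimate
field outcome. Reported values are conventionally rounded to two decimals
(`PopulationParameters.rounded`).

`params_from_growth_rate` supports desk calculations from published point
values (λ = e^{rΔt}; T = ln R₀ / r when R₀ is supplied). Note that a
published generation time recovered this way can exceed 1 year even for a
univoltine species when the printed r and R₀ derive from a census chain —
an inconsistency of the source values, not of the algebra; the package
exposes both chains rather than resolving it.

## Flight phenology

Each trap exposure (3–4 days) yields one interval-censored count. The daily
rate of an interval is the mean count across the traps actually present
divided by the exposure days, stamped at the interval midpoint (the
midpoint convention is a choice; rates are interval aggregates, not daily
observations). Missing traps reduce the divisor and are logged. The
seasonal total per trap is the season's summed counts over distinct traps.

The flight window is defined by observable catch semantics: start = deploy
date of the first interval with any catch (the day trapping could first
have caught flying adults), end = collect date of the last such interval,
peak = midpoint of the maximum-rate interval with ties broken to the
earliest. Whether "flight start" means first capture or first deployment
with captures is ambiguous in field usage; the deploy-date convention is
the default, and a cumulative-quantile alternative (e.g. 5 %/95 %) is a
straightforward extension of the rate series. An all-zero season has an
undefined window — a valid outcome, not an error.

When every trap is present in every interval, the seasonal total equals the
exposure-weighted integral of the rate series exactly; the suite checks
this identity at 1e−9.

## Tree damage

Per tree: the fraction of sampled sprouts with ≥ 1 gall, and mean galls per
sprout over **all** sprouts (zeros included). "Number of infested sprouts
per tree" is deliberately implemented as a fraction of sampled sprouts, not
an absolute count, because sampled sprout numbers vary by tree and the
field quantity of interest is the infestation *rate*. Sprout identity is
keyed by (tree, sprout), so repeated sprout labels across trees are
distinct. These summaries are order-invariant and satisfy
mean galls ≥ infested fraction.

## Inference layer

Models are ordinary least-squares fits with **sequential (Type I) sums of
squares in the order the terms are listed**, matching the convention of
reporting main effects before interactions; each term is tested against the
full model's residual mean square. Sequential SS is computed from
incremental design matrices (patsy) and their residual sums of squares, so
the listed order is honoured even when it is not monotone in interaction
degree; on degree-monotone models the tables match statsmodels
`anova_lm(typ=1)` exactly (cross-checked in the suite). Sequential SS of
all terms plus the residual reproduces the total SS to 1e−9 relative.

Degenerate inputs: a constant response yields F = 0, p = 1, R² = 0 for
every term; a saturated model (residual df = 0 — e.g. a locality × year
interaction with one observation per cell) raises an error naming the term
to drop; aliased terms (zero added rank) are rejected.

The **multiple-response model** (six per-stage bud counts as joint
responses) uses sequential hypothesis SSCP matrices H_k and the full-model
residual SSCP E. Each term is tested with Pillai's trace
V = tr(H(H+E)⁻) converted to an approximate F by the standard
(s, m, n) rule. Two implementation choices:

* the *effective* number of responses is the rank of the total response
  SSCP, so duplicated or collinear responses collapse — one response (or
  six identical copies) reduces exactly to the univariate sequential F;
* the model-level R² is 1 − tr(E)/tr(T), the explained share of total
  response variance, a single-number analogue of the univariate R².

Pillai's trace is used because it is the most robust of the classical
multivariate statistics to mild assumption violations; nothing hinges on
the choice and the per-term SSCP matrices are available for alternatives.
Gaussian errors are assumed throughout; non-Gaussian families are out of
scope.

**Tukey HSD**: pairwise level differences with the Tukey–Kramer standard
error SE_q = sqrt(MSE/2 · (1/nᵢ + 1/nⱼ)) and adjusted p from the
studentized range distribution (scipy's implementation; numerical tolerance
well below 1e−6) with k = number of levels and the fit's residual df. For
k = 2 this reduces to the unadjusted two-sample p (q = √2·|t|), and the
adjusted p never falls below the unadjusted one. On a 4-level null layout
the family-wise error is nominal; the suite requires 0.05 ± 0.01 over 2000
simulations.

Model specs validate that sampling date and cumulative °C never co-occur in
one model: within a season the accumulation is a strictly increasing
function of date, so the pair is collinear by construction.

## Synthetic-data generator

The generator emulates the statistical structure each pipeline stage
assumes, not chestnut-orchard climatology. One master seed spawns fixed,
per-generator and per-locality-year substreams
(`SeedSequence(seed, spawn_key=...)`), so outputs are byte-identical under
a fixed seed and adding a generator never perturbs the others. Every
dataset ships with a `truth.json` manifest (true survivals, emergence
modes, infestation matrix) enabling the recovery tests.

Defaults — the "malaga-like" profile:

| parameter | default | rationale |
|---|---|---|
| localities | the six study sites, annual means 13.1–15.7 °C | packaged fixture |
| monthly normals | annual mean ± 8 °C sinusoid, July peak | Mediterranean-continental seasonal swing; monthly cycle averages to zero so the published annual means are preserved exactly |
| reference station | 15.0 °C annual mean, same shape | plausible for the Ronda-area station; only parameterises the generator |
| daily noise sd | 1.5 °C | typical day-to-day residual after the seasonal cycle |
| oviposition | day-of-year 180 | late June, just after the flight peak |
| eggs per bud | NB, mean 6, size k = 10 | multi-egg buds at outbreak densities; mild clumping (females spread eggs among available buds) |
| stage thresholds | 700, 3400, 4000, 4450, 4900 °C·day | hatching ≈ 1 month after summer oviposition; L1 overwinters to spring bud burst; instars/pupa ≥ ≈3 weeks each, resolvable by fortnightly sampling |
| threshold jitter sd | 30 °C | mild between-bud asynchrony (microclimate) |
| transition survivals | 0.9, 0.85, 0.8, 0.75, 0.9 | moderate, stage-dependent immature mortality |
| adult residence | 500 °C | adults remain in galls ≈ 2–3 weeks before emerging; later samplings read all-zero buds |
| effective fecundity | 3 | yields R₀ ≈ 1.4 — within the observed range of cohort growth |
| sampling | 23 buds per date; monthly through winter, fortnightly from 1 March | field campaign cadence |
| emergence threshold | 5050 °C from the 1 July anchor | places flight in June–July, warmer localities weeks earlier, all within the June–August trap season |
| emergence spread | 6 days (Gaussian) | between-individual asynchrony |
| trap design | 5 trees × 2 traps, alternating 3/4-day exposures, June–August | field protocol |
| trap rate scale | 40 | expected season total per trap (tens of individuals) |
| damage | 10 trees, Poisson sprouts mean 15.5; infestation ~0.7 → 0.55 → 0.35 → 0.5 across years with small locality offsets; infested sprouts carry 1 + NB(mean 1.2, k = 1) extra galls | initial outbreak, decline, partial rebound; overdispersed gall loads |

What the generator does **not** emulate: real interannual climate anomalies
(every year shares one sinusoid), spatial correlation among nearby
localities beyond their mean offsets, density dependence and parasitoid
(*Torymus sinensis*) mortality, non-infested buds (dissection records
emulate the field practice of discarding egg-free buds), trap saturation,
and within-tree damage heterogeneity. Passing recovery tests therefore
demonstrates that the estimators recover the generating parameters under
the assumed structure — not that the structure captures every feature of
real orchard data.

Problem sizes used by the suite and the acceptance script were chosen to
estimate each Monte-Carlo quantity to well inside its stated tolerance:
20 seeds × 500 buds for survival recovery, 20 seeds for flight-peak
recovery, 200 seeds × 199 permutations for the power comparison, 2000
simulations for the family-wise error, and one full-profile double run
(seed 42) for byte-level determinism.

## Known limitations

* The peak-ratio survival estimator is biased when a stage's occupancy
  window is short relative to the sampling cadence (its peak is then
  under-observed and the downstream ratio inflates toward the cap at 1);
  the default thresholds keep every window resolvable at the fortnightly
  cadence.
* Survival capping at 1 truncates the estimator's sampling distribution;
  no standard errors or confidence intervals are provided for R₀, r, λ
  (a cohort bootstrap would be the natural extension).
* Flight windows are left-truncated by the trap season: a locality whose
  emergence precedes the first deployment reports the first deploy date as
  its start.
* The monthly-delta downscaling cannot create variance differences between
  localities, only level shifts; whether annual rather than monthly deltas,
  or a lapse-rate correction, better matches any particular station
  network is an empirical question the module does not answer.
* The multiple-response F is an approximation (exact only in the standard
  special cases of Pillai's trace), and sequential SS makes every table
  order-dependent by design: reordering terms is a different analysis.
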