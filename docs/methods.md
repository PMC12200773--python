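# Methods

## Scope and data model

The package links a gridded monthly drought index to survey respondents and
estimates exposure–outcome associations. Its inputs are (a) monthly SPEI
series on a 0.5° grid (long CSV or CF-style NetCDF), (b) a cell→district
coverage-weight table, and (c) a respondent table with country, district,
interview month, four covariates, and the two violence indicators (lifetime,
and the skip-patterned 12-month follow-up). Computing SPEI itself from
precipitation and evapotranspiration is out of scope — the published global
SPEI product is consumed as-is — as are wealth-index construction (the
cohort carries a binary poverty flag directly) and map rendering.

Calendar months are held as a single integer index (year·12 + month − 1).
All exposure windows are closed month ranges of 48 months ending the month
*before* the interview month: the interview month itself is excluded, since
it is generally only partially observed by a monthly index. This is a
convention choice; sensitivity to it is one month out of 48.

## Drought measures

A month is dry when SPEI ≤ −1 (inclusive). Maximal runs of consecutive dry
months are the unit of analysis:

* count method — a run of ≥ 5 dry months is a duration drought;
* sum method — a run with summed SPEI ≤ −17.5 is an intensity drought.

Design choices where the definitions are genuinely open:

* The sum method is applied to maximal dry runs of **any** length: a
  4-month run at −4.5/month qualifies. The two methods are treated as fully
  independent criteria; duration constraints belong only to the count
  method.
* When a run qualifies, **all** of its months are flagged, not only the
  months after the running sum crosses the threshold — symmetric with the
  count method's whole-run flagging.
* The slight-to-moderate band is strictly −1 < SPEI < 0. SPEI = −1 is
  already a dry month and is not double-classified as mild.
* A drought cycle spans its whole qualifying run (first month of dryness to
  the last month meeting the dry threshold).

The standardized dryness intensity is sdi = S / (n/k), with S the summed
SPEI over sum-method cycles, n the total sum-method drought months and k
the number of cycles; it is undefined (NaN, never 0) when k = 0, and a unit
without sum-method cycles can never be classified very dry.

The recent-and-long measure truncates each dry run to the trailing
24 months of the window and takes the longest truncated overlap: exposure
is the months *experienced* inside the recent period, not the run's origin.
The category requires strictly more than 12 such months (a 12-month run
does not qualify; a 13-month run does).

### Category thresholds

The two extreme categories use empirical decile cutoffs computed across the
sample of district-window units: very dry ⇔ sdi ≤ the 10% quantile of
defined sdi values (most-negative tail); prolonged-and-extreme ⇔
both-months > 0 and ≥ the 90% quantile of the both-months count. Quantiles
use linear interpolation and ties at the cutoff are **included** (an
inclusive reading of "top 10%"). Ranking is over district-window units, not
person-months; thresholds are invariant to unit ordering and to sample
replication.

## Grid-to-district aggregation

Default mode (`cell_then_average`): every drought measure is computed per
cell and then coverage-weight-averaged to the district; fractional month
counts are kept as reals and compared against thresholds without rounding
(recent-and-long uses weighted-mean recent run > 12). sdi is averaged only
over cells where it is defined, with the defined-cell weight mass
renormalised; a district with no sum-method cycle in any covering cell has
undefined sdi. The alternative mode (`average_then_index`) averages the
SPEI series first and indexes the district series, for sensitivity
analysis; categorical thresholds are applied after aggregation in both
modes. Weight tables are the canonical spatial interface — deriving them
from polygons is deliberately left outside the package so no geospatial
stack is required.

## Outcome and covariates

The 12-month outcome is recoded from the skip-patterned raw response:
yes → 1, no → 0, not-applicable (asked only after a lifetime disclosure;
lifetime = no) → 0, missing → dropped. A not-applicable code together with
a positive lifetime indicator is an inconsistency error. Missing outcomes
or covariates are handled by complete-case analysis with mandatory
dropped-row accounting in the report (model-based imputation is out of
scope). Age enters in raw completed years (13–24); standardisation is
available by flag but off by default. Survey weights are used for
prevalence estimation but not in the model likelihood; a weighted
pseudo-likelihood is not provided.

## Association model

One fit per exposure category, each with a single binary indicator whose
implicit reference group is all other respondents:

logit P(y=1) = a_c + β·exposure + γ'z, a_c ~ N(μ, σ²),
β, γ, μ ~ N(0, 1), σ ~ Half-Normal(1).

The half-normal scale prior is the package's choice: the zero-centred
unit-SD prior family is specified for location coefficients, and a scale
needs a weakly informative positive prior. The headline "Estimate" is the
posterior mean; the posterior median is also reported. OR = exp(mean) and
the credible interval is exp of the 2.5/97.5 coefficient quantiles.

### Sampling

Posterior draws come from a package-internal Hamiltonian Monte Carlo
sampler: jittered leapfrog trajectories of fixed length 3.0, dual-averaging
step-size adaptation (target acceptance 0.9), and a diagonal mass matrix
initialised from the logistic observed-information diagonal and refined
from mid-warmup draws. Defaults: 4 chains × 750 draws after 500 warmup
iterations. Two geometry devices matter:

* Covariates are mean-centred internally with an exact prior correction
  (the N(0,1) priors stay on the raw-scale coefficients), removing the
  near-perfect posterior correlation between the age coefficient and the
  intercepts.
* Country intercepts are sampled in the centred parameterisation when a
  moment estimate shows their spread is clearly data-identified (excess
  variance of crude per-country logit intercepts > 4× their mean sampling
  noise), and in the non-centred parameterisation otherwise. The centred
  form mixes far better when data are strong but develops an arbitrarily
  deep funnel when the posterior is consistent with σ ≈ 0; the selector is
  deterministic in the data.

Transitions with non-finite energy or an energy error above 1000 are
counted as divergent; a fit with more than 2% divergent transitions is
retried once with doubled warmup and target acceptance 0.98 (the same
remedy practitioners apply by raising Stan's `adapt_delta`), and raises an
error carrying its diagnostics if the retry also fails. Fits are reproducible bit-for-bit under
a fixed seed (chains are seeded by spawning from one root sequence).

### Diagnostics

Split-R̂ and bulk ESS follow the rank-normalised definitions (split chains,
inverse-normal rank transform, Geyer initial positive/monotone sequence for
ESS); they agree with an independent reference implementation to well
within 1%. Pipeline gates: R̂ ≤ 1.01 and bulk ESS ≥ 400 for every reported
parameter (the exposure and covariate coefficients, μ and σ). A fit that
misses a gate is rerun once with doubled draws and longer warmup before
being reported — the usual "sample longer" response to marginal
convergence — and the rerun decision is deterministic in the seed, so
pipeline reruns remain reproducible. Constant
chains return NaN as an explicit degenerate flag. Posterior predictive
checks redraw the outcome vector from the fitted likelihood for evenly
thinned posterior draws and compare replicate outcome means to the observed
mean (density-overlay data are emitted as binned JSON, not images).

## Synthetic data

The SPEI generator produces a stationary AR(1) Gaussian baseline with unit
marginal variance (a standardized index is ~N(0,1) at every location;
default lag-1 correlation 0.3, a moderate persistence typical of a 6-month
accumulation scale) and injects drought episodes as blocks overwritten with
N(mean depth, 0.3) draws clipped to ≥ −6. Episode depths vary so sum-method
totals are realistic rather than exact multiples.

The cohort generator mirrors the association model exactly: uniform ages
13–24; school / ever-partnered / poor rates 0.50 / 0.64 / 0.40; 14
countries × 10 districts; ~35,000 respondents; country-intercept SD 0.5
(chosen from the spread of country-level outcome prevalences the study
setting exhibits, roughly 5–21%, i.e. a logit spread of ±0.85); exposure
effects default to the preset log-ORs {−0.008, −0.156, 0.046, 0.197};
covariate effects default to γ_age = 0.03, γ_school = −0.2,
γ_partnered = 0.7, γ_poor = 0.15 — plausible epidemiological magnitudes
(partnership status is the strongest documented correlate of the outcome;
the others are modest). The global intercept −3.27 is calibrated so the
*expected* marginal outcome prevalence is 9.9%; a single realization moves
±1–2 pp because only 14 country intercepts are drawn. The lifetime
indicator is minimal — recent OR an independent Bernoulli(0.123), lifting
lifetime prevalence to ~21% — and exists solely to exercise the skip
pattern. Survey weights are log-normal(0, 0.25).

The end-to-end fixture bundle (48 cells, 24 districts, 6 countries, 6,000
respondents, 72 months) computes district exposure flags with the real
engine and then generates the cohort from those flags, so linkage output
can be compared to designed truth exactly. A few districts are given
persistently wet windows: under a standardized index every district would
otherwise record at least one mildly dry month in 48, making the
slight-to-moderate flag constant and its model non-identifiable. Climates
are redrawn (deterministically in the seed) until every category varies
across districts.

What the generator does *not* emulate: spatial correlation between cells,
real country geographies, informative missingness, or any dependence of
the outcome on drought beyond the specified logistic model. Passing tests
therefore demonstrate correctness of the pipeline's computations and
calibration of its inference under the model's own assumptions — not the
substantive validity of any real-data finding.

## Problem sizes and numerical choices

Parameter recovery uses n = 20,000 respondents in 10 countries with a true
exposure log-OR of 0.20 and σ = 0.3; the null-coverage calibration uses 100
replicates of n = 2,000 in 6 countries with 2 chains × 400 draws each —
sizes at which the whole experiment runs comfortably on one CPU while
Monte-Carlo error on coverage (binomial SE ≈ 2.2 pp at 95%) stays well
inside the ±5 pp band being checked. The demonstration pipeline uses the
6,000-respondent bundle. Quantile interpolation is linear throughout;
undefined sdi propagates as NaN and is never coerced to 0; weighted means
renormalise weight masses on load so weight tables need not be
pre-normalised.

## Known limitations

* The four category fits are separate models on overlapping exposures;
  no joint model or multiplicity adjustment is attempted.
* The skip-pattern recode maps not-applicable to outcome 0, which conflates
  "no lifetime violence" with "no recent violence"; that is the only
  reading compatible with a full-sample model given the instrument.
* Static-trajectory HMC is tuned for this model family; very small strata
  or quasi-separated exposures may still mix slowly and are surfaced by
  the R̂/ESS gates rather than silently accepted.
* The polygon→weight helper is intentionally absent; users supply coverage
  weights.
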