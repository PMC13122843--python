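# Methods

## The standard as executable rules

MIReVTD (Minimum Information standard for Reporting Vector Trait Data) is a
checklist, not a template: a reported trait measurement is reusable only if it
carries its organism descriptors (taxonomy, life stage, sex, an identifier for
individually measured data, the pathogen in transmission studies), a trait
description (name, numeric value, units in a separate field, numerator and
denominator for proportions), and the axes of variation along which it was
measured, each with its own units — in the least-aggregated form available,
with citation/submitter/embargo metadata alongside.

The standard deliberately fixes no field names. This toolkit therefore defines
one canonical snake_case data standard (`default_mirevtd_schema()`), with an
alias map so foreign headers (e.g. VecTraits-style CamelCase) bind to canonical
fields at read time. Requirement levels translate the checklist's must/should
language: `required` fields must be non-empty in every row; `conditional`
fields become required when the dataset's metadata carries the matching
condition tag (`transmission_study`, `field_study`, `aggregated_data`,
`proportion_trait`) — the triggers are user-declared because they are not
machine-decidable from the cells alone; `recommended` fields are never errors.
Field names and text cells are capped at 255 characters, matching common
database column restrictions.

### Severity policy

The rule engine assigns ERROR to violations that destroy machine reusability
(missing required descriptors, values mixed with units, non-numeric axis
levels, uninterpretable dates, out-of-range coordinates, missing metadata,
incomplete aggregation, missing pathogen in a transmission study) and WARNING
to stylistic or heuristic findings (non-ISO-but-recognizable dates, non-ASCII
characters, suspected abbreviations, exact-duplicate identifiers, missing
field-study location, and the standing notice that aggregated data are less
reusable). A dataset is *compliant* iff it has zero ERRORs. Where a field has
its own dedicated rule (units, pathogen, location, aggregation, proportions),
the generic required-field rule defers to it, so each defect maps to exactly
one ERROR rule — this is what makes the per-rule fixture suite discriminating.

Design choices worth noting:

- **Missing values.** The empty string and the sentinel `NA` both mean
  missing. Both are flagged when the field is required.
- **Dates.** Only `YYYY-MM-DD` naming a real calendar date passes. A date in a
  recognizable non-ISO layout (`DD/MM/YYYY`, `March 1, 2022`, ...) is a
  WARNING — interpretable but ambiguous; anything else is an ERROR — unusable.
- **Abbreviations.** Detection is a heuristic (a small blacklist plus "at most
  three letters ending in a period") and is therefore capped at WARNING;
  absence of abbreviations is not machine-provable.
- **Special characters.** Every code point above 127 is flagged, and nothing
  else; there is no principled shorter list.
- **Duplicate identifiers.** Repeat measures — the same identifier at
  *different* axis levels — are a legitimate design and pass; the same
  identifier with identical values on every axis is flagged as a suspected
  accidental duplicate (WARNING, since panel designs can legitimately repeat).
- **Single reporting language.** The checklist's one-natural-language rule has
  no reliable desk-scale detector and is deliberately not implemented.
- **Frequency of observations.** Granular data with an explicit time or
  gradient axis make the sampling design self-evident; the schema invariant
  requiring at least one axis-of-variation block is how this is enforced, and
  no separate rule exists.

CSV handling is fixed to RFC 4180 (comma separator, minimal quoting, CRLF,
UTF-8); cells are stored verbatim and the write→read round trip is the
identity on cells and order. Metadata travels as a JSON sidecar, never as
in-band CSV comments. Validation findings carry an `anchor` string restating
the checklist item they enforce, so reports are self-documenting.

## Aggregation

`aggregate_by_axis` produces one group per distinct axis level (exact numeric
equality after parsing; fuzzy binning is out of scope) with the mean, the
standard error of the mean (sample SD with the n−1 denominator over √n), and
n. SE is the canonical variability metric because it is the checklist's named
example; the `variability_metric` field is free text so other metrics can be
recorded. A group of one has an *undefined* SE — reported as missing, never as
zero — which correctly triggers the incomplete-aggregation error downstream.
Nothing reconstructs individuals from summaries: aggregation is treated as an
irreversible loss of information, which is the point of the experiment below.

## Thermal performance curve model

The trait model is the Briere-1 curve, the standard asymmetric form for
arthropod development rate:

    rate(T) = q · T · (T − T_min) · √(T_max − T)   for T_min < T < T_max,
    rate(T) = 0                                     otherwise.

The peak temperature has the closed form T_pk = [(4·T_max + 3·T_min) −
√(16·T_max² + 9·T_min² − 16·T_min·T_max)] / 10 (the quadratic root of
d log rate/dT = 0 that maximizes the curve; with T_min = 0 this reduces to
0.8·T_max, and when T_min < 0 both roots can lie inside the support, so the
implementation evaluates the curve at both and keeps the larger). T_pk is
independent of q.

Observations are modelled as Normal(briere(T), σ²), with independent uniform
priors on (q, T_min, T_max, σ). Defaults: q ∈ (0, 1], T_min ∈ [−10, 25] °C,
T_max ∈ [25, 50] °C, and σ ∈ (0, 10 × SD of the observations] via
`PriorSpec.for_data` (or a fixed (0, 10] when no data scale is supplied) —
diffuse on whatever scale the trait is measured. The same prior object is
shared verbatim between the individual-level and the aggregated fit. A
degenerate bound (lo = hi) pins a parameter and removes it from sampling,
which is how the one-free-parameter correctness oracle runs through the real
sampler. Aggregated fits treat each group mean as one plain observation with
the same likelihood — no SE weighting — mirroring the common practice of
fitting published single-point averages as if they were data.

### Sampler

Single-chain random-walk Metropolis with component-wise Gaussian updates.
Per-parameter proposal scales start at 10% of each prior width and are
multiplied by exp(window acceptance − 0.325) every 50 burn-in sweeps —
targeting the 25–40% acceptance band — then frozen, so the sampling phase
satisfies detailed balance exactly. The initial point is drawn uniformly from
the prior support (redrawn until T_min < T_max). Defaults are 20 000 kept
sweeps after 5 000 burn-in; replicated experiments use 12 000 / 4 000 (the
measured integrated autocorrelation time on these posteriors is 4–7 sweeps,
so effective sample sizes stay above ~1 500). A chain whose post-burn-in
acceptance falls below 1% is flagged degenerate rather than silently
summarized. Extremely peaked posteriors (near-zero noise) need a longer
burn-in for the adaptation to find and scale to the mode; the noiseless
recovery test uses 20 000 burn-in sweeps for this reason. No gradients, no
dependencies beyond numpy — everything is seeded and exactly reproducible.

The 95% HPD interval is the shortest contiguous window containing
⌈0.95·n⌉ sorted samples, ties broken toward the lowest start.

## The synthetic generator

`simulate_individual_dataset` emulates a juvenile development-rate (or
lifespan) experiment on *Aedes aegypti* across a temperature gradient,
optionally crossed with an initial-resource-concentration axis (the classic
two-stressor layout; the resource axis is recorded as an axis of variation but
does not modify the curve). Reference study conditions, fixed once: truth
q = 7 × 10⁻⁵, T_min = 10 °C, T_max = 38 °C — peak rate ≈ 0.12 day⁻¹ near
31.6 °C, realistic for mosquito juvenile development — noise SD 0.01 on the
rate scale (≈ 8% of the peak), 8 temperatures from 16 to 36 °C, 20
individuals per temperature. Rates are max(curve + Normal noise, 10⁻⁶); the
lowest design temperature sits ≈ 3σ above zero, so the positivity floor
essentially never binds and the likelihood the fitter assumes matches the
generator. Lifespan datasets are the rounded reciprocal in whole days, an
approximation recorded as such. Field vocabulary (taxonomy, life stages,
units) uses the standard's printed example values, so fixtures double as
documentation.

What the generator does *not* emulate: real mosquito data are
heteroscedastic, right-skewed near the thermal limits, censored by mortality,
and batch-structured. Passing tests therefore demonstrate that the machinery
is correct under its own assumptions — not that the Gaussian-Briere model is
adequate for any particular real dataset.

`perturb_for_fixture` plants exactly one rule violation per registered rule
(blanking a cell, mixing a unit into a value, a non-ISO date, a diacritic, an
out-of-range latitude, a condition tag without its fields, ...), chosen so no
*other* ERROR rule fires — warnings may legitimately co-occur.

## Reference experiments

- **Parameter recovery** (100 replicates at the reference conditions): the
  95% HPD should cover each generating parameter at close to its nominal
  rate; the test accepts 85–99 of 100, the binomial range around 95%. The
  posterior median of T_max is required to sit within 1 °C of truth in median
  absolute terms.
- **Information loss** (50 replicates): each dataset is fitted twice — raw
  individuals versus its 8 per-temperature means — with identical priors and
  chain settings. The HPD width ratio (aggregated / individual) for T_max
  exceeds 1 in ≥ 80% of replicates. The single-replicate ratio is noisy
  (occasionally below 1, occasionally enormous when the aggregated posterior
  wanders to its prior bound), which is why the claim is a replicate fraction
  and not a per-dataset inequality.
- **Sampler correctness**: with q, T_min, σ pinned at truth the posterior is
  one-dimensional; the sampled CDF must match direct quadrature within
  Monte-Carlo error (sup distance < 0.06 ≈ 3 × the KS fluctuation at the
  chain's effective sample size). With zero observations the sampler must
  reproduce its uniform priors (KS test at α = 0.01 on a chain thinned by 40,
  well past the measured autocorrelation time; T_min/T_max supports are taken
  disjoint there so each marginal is exactly uniform).

## Known limitations

- The validator checks interpretability, not scientific correctness of
  values; a plausible-looking wrong number passes.
- The abbreviation and special-character rules are heuristics; they can
  miss and they can overflag (hence WARNING).
- The sampler is a desk-scale random-walk Metropolis: robust and dependency-
  free, but inefficient for very peaked or strongly correlated posteriors;
  no convergence diagnostics beyond the acceptance-rate degeneracy flag are
  computed.
- Uniform priors make the posterior proper but bound-sensitive: an
  aggregated fit with only a handful of points can pile mass at a prior
  bound, which is itself a faithful display of how little those points
  constrain the model.
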