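# Methods

This note records the statistical model, the numerical choices and the
design decisions behind `oameta`, and what the synthetic-data checks do
and do not demonstrate about real data.

## Effect sizes

The unit of analysis is one treatment-vs-control contrast per study ×
experiment × species × biological response × CO₂ category.  The effect
size is the log response ratio `LnRR = ln(mean_E) − ln(mean_C)`, chosen
for its robustness at small sample sizes and its proportional-change
interpretation.  Responses carry a direction label: where a larger raw
value means harm (shell dissolution, larval abnormality), the sign of
the LnRR is inverted so that positive always denotes benefit.  Inverting
the sign of the ratio — rather than negating a mean, which would leave
the logarithm undefined — preserves both the magnitude and the intended
reading of the convention.

Two variance conventions are exposed because extracted tables are
ambiguous about whether the dispersion column is an SE or an SD:

* `paper_literal` (default): the reported dispersion S enters
  `v = S_E²/(n_E·mean_E²) + S_C²/(n_C·mean_C²)` unchanged.  With S an
  SE this under-states the sampling variance by a factor of n per arm;
  it is retained as the default because it reproduces analyses that use
  the formula this way, and because within a corpus of similar n it
  mostly rescales weights rather than reordering them.
* `hedges`: S is converted SE→SD (SD = SE·√n) first, making v the
  standard delta-method variance of a log ratio.  This is the mode to
  use when the absolute scale of v matters — in particular for τ²
  estimation, and it is the mode the parameter-recovery checks run
  under, since "τ̂² recovers the generating τ²" is only a well-posed
  check when v estimates the actual sampling variance.

Effects with v = 0 (both dispersions zero) are excluded from weighted
pooling with an audit entry, since 1/v is undefined; equal-weight
pooling still accepts them.

## Random-effects model

Within each pooling cell, observed effects follow
`y_i ~ Normal(θ, v_i + τ²)` with known v_i.  τ² is estimated by REML:
Fisher scoring on τ² using the standard restricted score and expected
information, with step-halving whenever a step would decrease the
restricted log-likelihood, truncation at 0, a relative convergence
tolerance of 1e-10 on τ², and a cap of 200 iterations (the
DerSimonian–Laird estimate, truncated at zero, is the starting value).
Sampling variances below 1e-12 are floored there to keep weights
finite.  The pooled effect uses w_i = 1/(v_i + τ²); its 95% CI is Wald
(z), not Knapp–Hartung, matching the conventional summary-ratio CI of
the reference R implementation's default reporting.  Cochran's Q uses
fixed-effect weights 1/v_i against χ² with k−1 df.  Significance of a
cell means its 95% CI excludes zero.

An equal-weight ("unweighted") pooling mode is available behind the
`weights` flag as the companion analysis; on synthetic data its
conclusions track the weighted mode.

Known limitation, by design: Wald intervals undercover slightly at
moderate k because the uncertainty in τ̂² is ignored.  At k = 20 with
τ² = 0.05 the measured coverage sits near 93% rather than 95%.  This is
the documented behaviour of the chosen interval, not an implementation
defect, and it is reported rather than patched (e.g. with
Knapp–Hartung) to keep the pooling definition conventional.

## Carbonate-system conversion

pH-reported treatments are converted to μatm pCO₂ by solving the
seawater CO₂ system at the record's temperature, salinity and total
alkalinity (or DIC).  Parameterisations: Weiss (1974) K0; K1/K2 from
the Mehrbach data as refit by Dickson & Millero (1987) on the seawater
scale (default) or Lueker et al. (2000) (selectable); Dickson (1990)
boric-acid and bisulfate constants; Millero (1995) water; Perez & Fraga
(1987) HF; Uppström (1974) total boron.  Input pH on the total, free,
seawater or NBS scale is converted to the seawater scale first (NBS via
the Takahashi activity-coefficient approximation).  With pH known both
branches are closed-form: the non-carbonate alkalinity terms (borate,
hydroxide, free H⁺, bisulfate, HF) are evaluated at [H⁺] and subtracted
to give carbonate alkalinity, or DIC is speciated directly; [CO₂*]/K0
is the partial pressure.  The inverse problem (pH from pCO₂ and TA,
used in round-trip checks and synthetic pH generation) is solved by
Brent root-finding on pH ∈ [2, 12].  Records that do not declare a pH
scale are assumed total, and this assumption is recorded in the run
log.  Nutrient alkalinity (phosphate, silicate) is omitted; output is
pCO₂, with the Weiss fugacity correction available behind a flag.
Surface pressure only — no pressure corrections are applied.

Verification uses two layers: published check values for the constants
at S = 35, 25 °C (Lueker pK1 = 5.8472, pK2 = 8.9660; ln K0 = −3.5617;
pK_S = 0.9987), and a dual-route solve (closed-form alkalinity
decomposition vs. finding DIC by root-finding and speciating it) that
agrees to ~1e-13 relative.  Because the source studies rarely state
which constants their conversion used, exact per-record reproduction of
published converted levels is constants-set dependent; the choice is
explicit and configurable.

## Boxplot-summary conversion

Records reporting medians and quartiles are converted with
quantile-based estimators: the mean as
`(0.7 + 0.39/n)·(q1+q3)/2 + (0.3 − 0.39/n)·m` (the two weights sum to
one for every n, so a degenerate summary returns the median exactly),
and the dispersion as `S = (q3 − q1)/η(n)` with
`η(n) = 2Φ⁻¹((0.75n − 0.125)/(n + 0.25))`, the expected IQR of a
standard normal sample.  Note that a printed variant of the mean
formula with "(q1+q2)/2" is interpreted as (q1+q3)/2, the mid-quartile
point of the source estimator literature; the literal reading
double-counts the median and breaks the q1 = m = q3 identity.  S
estimates a standard deviation; because downstream tables treat the
column as a standard error, both a `paper_literal` mode (S used as SE)
and a `corrected` mode (SE = S/√n) are provided, defaulting to
`paper_literal` for reproduction.  η(1) = 0, so a single observation
with a non-zero IQR is rejected as contradictory.

Growth rates from cell concentrations use μ = ln(N_t/N_0)/t per day.

## Screening and treatment resolution

Filters run in a fixed order (duration → co-stressor → ambient-control)
for a deterministic audit trail; the kept set is order-invariant and
every exclusion carries one reason code plus the rule parameters.
Defaults: experiments longer than 31 days are excluded as acclimation
studies ("weeks, up to a month" made concrete); records whose other
stressors were not at ambient are excluded; records whose control arm
exceeds 500 μatm by more than 10% are excluded ("substantially exceeds
≈500" made concrete; both numbers configurable).  The control arm is
the flagged one, else the arm closest to a 400 μatm ambient reference
with ties toward lower CO₂.  Treatment arms are binned into half-open
real-valued bands (500, 800], (800, 1000], (1000, 1500], (1500, 2000],
(2000, ∞) — the integer category names are display labels — plus a
sub-ambient pre-industrial band, bounded at 300 μatm by default since
no published bound exists; values within ±10% of the ambient reference
are treated as ambient.  Within a multi-treatment category the highest
level is used, except in the pre-industrial band where the lowest is.

## Grouping and thresholds

Fits are produced at four grouping levels: trophic level; taxon group;
group × response; and, for phytoplankton only, response ×
single-species-vs-community.  Verdicts are a function of the CI
endpoints alone (positive / negative / no_effect, or no_data for an
empty cell); cells with fewer than 3 effects are flagged low-confidence
(the "few data points" cutoff is configurable — published tables mark
such cells but state no number).  A group's threshold is the lower
bound of the lowest elevated category whose verdict is negative and
that stays negative (or has no data) at every higher category; the
category's display name is reported alongside the numeric bound because
published threshold tables label by category.  No negative category →
"no_effect"; alternating verdicts, or negatives supported only by
low-confidence cells → "uncertain" with a sub-reason.  The
alternation→uncertain rule is this package's own formalisation of a
narrative convention.

## Synthetic-data generator

The generator emulates exactly the structure the random-effects model
assumes: per-cell true effect θ_cell; per-study θ_i ~ N(θ_cell, τ²);
a fixed positive control baseline (100 units) with treatment mean
baseline·e^{±θ_i} (sign per the direction label); n replicates per arm
drawn Normal(mean, (cv·mean)²) and summarised to a sample mean and SE.
Defaults describe a realistic short-term perturbation corpus: τ² = 0.02
on the LnRR scale, 20 studies per cell, 6 replicates per arm, 10%
within-arm CV, 10% of records emitted as boxplot summaries (quartiles
of the generating normal), 25% reported as pH (back-solved from the
target pCO₂ at T = 1 °C, S = 34, TA = 2300 μmol/kg — cold Antarctic
surface water), ambient at 400 μatm and one representative treatment
level per category.  Replicate draws are floored at 1% of baseline so
log ratios stay defined; truncation events are counted and are rare
(<0.1%) under defaults.  Randomness is split per cell — each cell's
stream is seeded by (seed, crc32(cell key)) — so adding cells never
perturbs existing cells' draws and tables are byte-reproducible.

What passing synthetic checks does **not** show: real corpora have
correlated effects within studies, non-normal and occasionally
asymmetric reporting, heterogeneous n and cv across studies, digitised
(rounded) values, and a covariate distribution nothing like uniform
cells.  The generator makes no attempt to mimic the real corpus's
covariate distribution; recovery results certify the machinery, not the
field inference.

## Verification quantities and problem sizes

`scripts/acceptance.py` recomputes, at run time, with sizes chosen to
make Monte-Carlo error small relative to the tolerances: REML vs. a
staged brute-force grid search of the restricted likelihood resolved to
a 1e-7 lattice (100 random instances, k ≤ 8, agreement ≤ 1e-6);
full-pipeline recovery of θ = −0.4 and τ² = 0.02 from 200 synthetic
studies (CSV → ingest → conversion → screening → effects → REML, in
`hedges`/`corrected` modes for the reason given above); Q-test type-I
error at α = 0.05 over 10,000 homogeneous replicates of k = 10; Wald
CI coverage over 2,000 meta-analyses of k = 20 at τ² = 0.05; carbonate
round-trip closure and dual-route agreement over T ∈ {−1.8, 0, 4} °C ×
S ∈ {33, 34, 35} × TA ∈ {2200, 2300, 2400} × pH ∈ [7.4, 8.2]; the
quartile-estimator identities (weights summing to one, the η(n) → 1.349
limit, SD recovery from normal quartiles at n = 1000); and the
benefit-then-harm knee recovery rate over 500 replicates at 20
effects/cell with within-cell variance 0.01.  Every quantity is
reported with the problem size that produced it; nothing is hard-coded.
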