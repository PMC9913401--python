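# Methods

## The relative-survival setting

For a patient with follow-up time `t` since diagnosis, age at diagnosis
`age`, deprivation score `EDI` and demographics `z` (sex, region, calendar
time, and — when available — deprivation quintile), the observed mortality
hazard is decomposed as

    λ(t, age, EDI, z) = λ_E(t, age, EDI) + λ_P(age + t, year + t, z)

where `λ_P` is the all-cause hazard of the matched general population read
from a life table and `λ_E` is the excess (cancer-related) hazard.  Net
survival is `S_E(t) = exp(−Λ_E(t))`.  No cause-of-death information is used;
everything rests on the life table being correct for the patient.  The
package's purpose is to study what happens when the life table ignores the
social gradient of background mortality, and to support sensitivity analyses
with *simulated* deprivation-specific tables.

## Life tables

Rates are expected deaths per person-year, piecewise-constant on unit
age × unit calendar-year cells (`floor` of both coordinates).  An annual
death probability `q` can be supplied instead and is converted at read time
via `λ = −log(1 − q)`; which encoding a given national table uses is a
property of the source, so both are supported and neither is assumed.
`Λ_P(t)` is integrated exactly along the diagonal (age+u, year+u), splitting
at every integer age and year crossing.  Ages above the table maximum and
years outside coverage are clamped to the nearest covered cell (and logged):
registry follow-up routinely outlives the oldest tabulated age, so clamping
is preferred to failure.  The region label is opaque — no spatial semantics.

## Simulating deprivation-specific life tables

An external source provides smoothed mortality rates by deprivation level
(5 levels, or 20 income vingtiles averaged in blocks 1–4, 5–8, 9–12, 13–16,
17–20).  For each stratum the level-to-overall rate ratio is formed,
`rr_d = rate_d / overall`; when the source publishes no overall rate it is
reconstructed as the level-weighted mean (both conventions are supported
because sources differ).  Years missing from the ratio table are filled by
carrying the nearest covered year outward (last year forward, first year
backward).  The simulated table is then

    λ_sim(sex, age, year, region, d) = λ_base(sex, age, year, region) × rr_d(sex, age[, year])

with nearest-age matching when the external age grid is coarser than the
base table's.  No renormalization is applied by default — the plain
rate-ratio product is the transparent reading of the construction — but an
optional flag rescales the ratios so the level-weighted average reproduces
the base rate exactly.  A moving-average age smoother (window 5) is
available for raw, unsmoothed sources; it is off by default because
published gradient sources are typically already smoothed.

## Pohar–Perme net survival

The cumulative excess hazard weights each subject's counting process by the
inverse of their expected survival `S_Pi(u) = exp(−Λ_Pi(u))`:

    Λ̂_E(t) = Σ_{events u ≤ t} [Σ_i dN_i(u)/S_Pi(u)] / [Σ_i Y_i(u)/S_Pi(u)]
            − ∫₀ᵗ [Σ_i Y_i(u) λ_Pi(u)/S_Pi(u)] / [Σ_i Y_i(u)/S_Pi(u)] du

with variance `V̂(t) = Σ_{events ≤ t} [Σ dN_i/S_Pi²] / [Σ Y_i/S_Pi]²`.  The
event-time sum is computed exactly at every distinct death time; the
population integral uses the trapezoid rule on a grid holding every
follow-up time and evaluation time, refined so no step exceeds 1/52 year —
a resolution at which the quadrature error is far below the estimator's
sampling noise.  Ties between deaths and censorings follow the standard
risk-set convention `Y_i(u) = 1{T_i ≥ u}` (deaths first).  The estimator is
unconstrained and can exceed 1.  Evaluation times beyond the last follow-up
are reported as NaN with a warning rather than extrapolated.

Age-standardized net survival averages group-specific curves over five age
groups ([15,45), [45,55), [55,65), [65,75), [75,∞)) with ICSS-style weights
(0.07, 0.12, 0.23, 0.29, 0.29).  These are conventions, fully configurable;
none of the package's conclusions depend on the specific weights.  Empty
groups renormalize the weights with a warning.  The deprivation gap is
`100·(ASNS_Q1(h) − ASNS_Q5(h))` at horizon `h` (default 5 years) with the
delta-method variance `Var(NS) = NS²·V̂` and a symmetric 95% CI on the plain
scale, matching how such gaps are conventionally printed.

## Flexible excess-hazard models

`log λ_E` is modeled with cubic B-spline bases:

| form | structure | meaning |
|------|-----------|---------|
| 1 | tensor(t, age) | no EDI effect |
| 2 | tensor(t, age) + smooth(EDI) | proportional EDI effect |
| 3 | tensor(t, age) + smooth(EDI) + interaction(t, EDI) | time-dependent |
| 4 | tensor(t, age, EDI) | time- and/or age-dependent |

Form 3 spans the same space as `tensor(t,age) + tensor(t,EDI)` but is written
identifiably: the EDI main effect and the pure t×EDI interaction use
sum-to-zero-constrained marginal bases (the raw additive tensor pair shares
all functions of `t` alone, which would make the penalized Hessian
singular).  Form 4 replaces the baseline with the full three-way tensor; its
default marginal bases are coarser than the others so the coefficient count
stays near 80 — consequently the unpenalized likelihoods of the four forms
are only guaranteed to nest when a configuration with shared marginals is
used.

Default knots: time — boundary (0, 6) years with interior knots at 0.25, 1
and 3 (early follow-up is where excess hazards move fastest); age and EDI —
boundary at the cohort range with one interior knot at the median.  All are
configurable.  Follow-up is truncated at 6 years for modelling; the study
design implies at most 7.5 years of follow-up and curves are reported to 5.

The penalized log-likelihood is

    ℓ_pen(β) = Σ_i [δ_i log(λ_E(T_i) + λ_Pi(T_i)) − Λ_E(T_i)] − ½ Σ_m s_m β'P_mβ

with `λ_P` a fixed offset (used exactly, not approximated), `Λ_E` by
Gauss–Legendre quadrature (12 nodes per subject by default; doubling the
node count moves the log-likelihood by well under 1e-6 relative on standard
fits).  Penalties are exact integrated-squared-second-derivative (curvature)
matrices per marginal basis, embedded in tensor blocks Kronecker-style.
Curvature penalties were chosen over coefficient-difference penalties
because, with quantile-placed (hence uneven) knots, difference penalties
shrink exactly-linear effects and visibly biased recovered hazard ratios in
simulation; the curvature penalty's null space contains linear functions, so
a log-linear deprivation effect is never shrunk.

Optimization is damped Newton with the analytic gradient and Hessian,
Levenberg ridge when the Hessian is not negative definite, step-halving line
search, convergence at max |score| < 1e-6 (relative to |ℓ| when ℓ is large),
and up to five perturbed restarts before raising a diagnostic error.
Initialization sets a flat log-hazard at the crude event rate.

Smoothing levels minimize the corrected AIC

    AICc = −2ℓ̂ + 2·EDF + 2·EDF·(EDF+1)/(n_events − EDF − 1)

where `ℓ̂` is the *unpenalized* log-likelihood at the penalized optimum and
`EDF = tr(H_pen⁻¹ H_unpen)`.  The default search applies one shared level to
all penalties on a log10 grid (10⁻² … 10⁶, step 1), warm-starting from
smooth to rough; an optional coordinate-wise refinement sweep over the same
grid is available.  The shared-level default was chosen because AICc is very
flat in log-smoothing and a full per-penalty coordinate search multiplies
the cost of every replicate simulation several-fold without changing
selection or recovery behaviour.  Model selection fits all four forms and
takes the AICc minimum, breaking ties (< 1e-6) toward the lower form code.
The AICc value is used only to compare forms within this implementation,
never across implementations.

EHR curves are delta-method contrasts on the log scale:
`EHR(e) = λ̂_E(t₀, age₀, e)/λ̂_E(t₀, age₀, ref)` over an EDI grid with
reference −3.9 (the national p10), and `EHR(t) = λ̂_E(t, age, 4.4)/λ̂_E(t,
age, −3.9)` over time at the cohort's age quartiles.  Whether published
analyses modeled the proportional EDI term as a spline or linearly is an
open convention; the default is a (curvature-penalized) spline with a
linear option (`edi_linear`).

## Synthetic cohorts and their ground truth

The generator encodes the study conditions: diagnoses uniform over
[2006, 2010), administrative censoring at mid-2013 (so 3.5–7.5 years of
potential follow-up), ages truncated-normal (mean 70, sd 12, within
[15, 95]), an even sex mix, and an EDI marginal given by a shifted lognormal
calibrated to median ≈ −0.75 and range ≈ (−17, 51).  A shifted lognormal
cannot simultaneously match the median, the range, and the p10/p90 values
(−3.9 / 4.4); the median and range were matched, and the EHR reference
abscissas remain the fixed constants −3.9 and 4.4 (they are reference
points, not sample quantiles).  Quintile cut points default to the
theoretical quintiles of that distribution; ties go to the lower quintile.

Background mortality is Gompertz, `a₀·exp(b·age)` with `a₀ = 5·10⁻⁵`,
`b = 0.092` (roughly 3% per year at age 70, doubling every ~7.5 years), a
−1%/year calendar drift, a female/male factor of 0.7, and a per-quintile
rate-ratio gradient (default (0.80, 0.90, 1.00, 1.15, 1.35) Q1→Q5 — a
plausible magnitude for an education/income gradient without claiming any
country's exact values; the inflation experiments use
(0.85, 0.92, 1.00, 1.12, 1.275), i.e. exactly rr_Q5/rr_Q1 = 1.5).  The
excess hazard is Weibull (shape 0.8, scale 8 — 5-year net survival ≈ 50%, a
mid-prognosis cancer) with the EDI effect `λ_E(t, edi) = λ₀(t)·exp(b(t)·edi)`
where `b(t)` is zero (form 1), constant (form 2), or constant until a cutoff
`τ` then zero (form 3) — the step form keeps every cumulative hazard in
closed form, so survival times come from exact inversion and the ground
truth (net survival per EDI, EHR_p90/p10 over time) is analytic.  Background
death times are drawn by exact linear inversion of the piecewise-constant
life-table cumulative hazard; a target beyond the table's mass returns +inf
(censored by design).  All draws come from a single seeded PCG64 generator,
so cohorts are bit-reproducible across platforms.

What the generator does *not* emulate: cancer-site- or stage-specific
incidence, spatial autocorrelation of deprivation, non-administrative
censoring, regional heterogeneity (one region by default), or the true
French EDI distribution beyond its summaries.  Passing tests therefore show
that the estimators behave correctly under the assumed decomposition — not
that any particular registry estimate is right.

## Comparison pipeline and concordance labels

`run_comparison` analyzes one cohort under the main (unstratified) table and
each simulated stratified table: gaps at 1 and 5 years, ASNS per quintile,
AICc-selected form, and EHR curves.  Each sensitivity analysis is labeled
against the main one with explicit rules, checked in order: **inversed**
(gap sign flips with non-overlapping CIs), **inconsistent** (selected form
changes to or from "no effect"), **attenuated** (same sign, strictly smaller
sensitivity gap), **consistent** (same form and overlapping CIs), otherwise
inconsistent.  The published reading of such comparisons is narrative; this
classifier is a declared operationalization, with thresholds in the run
configuration, not a claim of equivalence.

## Problem sizes

The replicate experiments use the sizes at which their conclusions are
stable: the gap-inflation experiment runs 50 replicates of n = 20 000; EHR
recovery and model selection use 25 replicates each in the test suite
(n = 20 000 and n = 5 000 respectively), and `scripts/acceptance.py` re-runs
the same experiments with 50/10/10 replicates, which reproduces every rate
and mean to well within its Monte-Carlo noise.
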