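# Methods

## Cohort operationalization

The analysis universe is payer claim records: hospitalization claims (with
admission/discharge dates, main ICD-10 diagnosis, reperfusion procedure flags
and reimbursed cost) and outpatient claims (service date, cost), linked to
patient demographics and a provider roster.

* **Index event.** The earliest hospitalization per patient with main
  diagnosis matching the prefix `I63` (all cerebral-infarction subcodes),
  admitted within the study window.  Same-day ties are broken by the lower
  claim id — a deterministic, arbitrary rule; claims data give no better
  ordering.
* **Eligibility.** Age at the index admission ≥ 18 completed years
  (calendar-exact, not day-count division); `index_date + 90 days ≤
  study_end` so every episode has full follow-up.  Records with missing
  birth dates or unparseable diagnoses are rejected, never silently fixed.
  Every rejection carries a reason code (`UNDER18`, `LATE_INDEX`,
  `LOW_VOLUME`, `BAD_RECORD`) and the manifest reconciles cohort N against
  the exclusion tallies.
* **Intervention.** From the index claim's flags with hierarchy
  thrombectomy > thrombolysis > other, so bridging therapy (lysis before
  retrieval) counts as thrombectomy and the three groups partition the
  cohort.
* **Volume filter.** Providers with fewer than 30 index events are removed
  in a single pass on pre-filter counts.  An iterated filter could cascade
  (removals never change other providers' counts here, but the single-pass
  rule makes the estimand explicit).

## Episode window and costing

Day 1 is the index admission day; the episode is the half-open interval
`[index, index + 90d)` applied uniformly to hospital admissions, outpatient
service dates and deaths.  A death at offset exactly 90 is a survivor; an
admission at offset 89 is in, at 90 out.  A later hospitalization is in the
episode if its *admission* is in the window, and then its full cost counts —
claims are indivisible payer units, so no prorating across the boundary.
Costs decompose exactly: `total = primary + other_hosp + outpatient`, an
identity asserted in code rather than recomputed downstream.

## Indirect age standardization

The reference population is the analyzed cohort itself.  Default age bands:
[18, 45), [45, 55), [55, 65), [65, 75), [75, 85), [85, ∞) — decade-width
bands over the bulk of the stroke age distribution, with wider tails where
events are sparse; configurable.  Stratum rates `r_a` are raw band death
rates; empty bands inherit the overall rate `r̄`, so expected probabilities
are total on the age range.  A group's standardized mortality is
`(O/E)·r̄`.  Two consequences used as test invariants: a group whose age mix
equals the reference mix standardizes to its crude rate, and the E-weighted
mean of all provider rates is exactly `r̄` (because `ΣE = ΣO` when the
reference is fit on the pooled cohort).  Rates above 1 are possible in tiny
groups with large excess mortality; they are reported untruncated with a
warning, since downstream funnels work on the `O/E` ratio scale.  A logistic
regression of death on age (statsmodels) is available as an alternative
`p_i` estimator; stratum rates are the default for transparency.  No
adjustment is made for sex, comorbidity or stroke severity — severity is
simply absent from claims, which is the method's key limitation.

## ECPS

`ECPS = ΣC_i/(N − D)` uses crude deaths `D`, the literal definition; the
group tables also show standardized mortality, so the two can disagree
slightly — a reconstruction of ECPS from a printed standardized rate is
expected to land within a few tenths of a percent, not exactly.  Display
rounding (costs to whole EUR, mortality to one decimal percent, shares under
10% with one decimal) lives in a formatting layer; all stored values are
full precision.  No confidence intervals are attached: a ratio of a skewed
sum to a binomial count has no clean small-sample interval, and the
indicator is intended as a supporting, not primary, measure.

## Funnel limits

For a proportion with in-control value θ₀ observed on n patients, the exact
limits invert the Binomial(n, θ₀) CDF with continuity interpolation: find
the smallest integer r with F(r) > p, set λ = (F(r) − p)/(F(r) − F(r−1)),
and use (r + ½ − λ)/n.  Placing each probability atom at the centre of its
unit cell makes the limits of a symmetric distribution symmetric (θ₀ = ½
gives mirror-image limits at every n) and the band's true coverage close to
nominal (at n = 200, θ₀ = 0.15: 95.25% and 99.80% for the nominal 95%/99.8%
bands).  In the far lower tail the interpolated quantile can cross zero;
limits are clamped to the indicator's range, which also means the
band-width-versus-precision monotonicity holds only where limits are
interior.  Standardized-mortality funnels put the Poisson-based limits on
the O/E scale against E as the precision parameter (an option renders the
x-axis as patient volume instead, for readers who prefer it).  Cost funnels
use μ₀ ± z·σ₀/√n with μ₀ the cohort grand mean and σ₀ the pooled
within-provider SD; a log-scale variant computes limits on log costs and
exponentiates, since claim costs are approximately lognormal — raw scale is
the default.  Boundary points count as inside.  No overdispersion inflation
is applied by default; `estimate_overdispersion` provides the winsorized
z-score mean square φ̂ for users who want inflated limits.

`flag_units` recomputes exact limits at each unit's own precision instead of
interpolating the exported grid: linear interpolation between grid nodes can
misflag points near a limit, and the exact computation is cheap.  The grid
exists purely for plotting and CSV export.

## Synthetic claims generator

The generator emulates the structure the analysis assumes, not any real
person: one index-eligible I63 hospitalization per patient; age from
Normal(70.6, 12.4) truncated at 18 (the completed-years age is the rounded
draw, so the reported age mean matches the target); 47% female; a provider
roster (13 CSC, 32 PSC, 25 SRH, 15 other) with expected patient shares
35/46/17/1.9% and per-tier intervention mixes taken from the observed
column-wise composition of a 23,568-patient cohort (e.g. 88% of
thrombectomies at CSCs); lognormal costs per (intervention, component) with
location/scale solved from observed mean/median pairs, which reproduces the
heavy right skew (median ≪ mean); secondary hospitalizations with
probability 0.35 (matching a zero median for that component) plus
deliberately out-of-window claims to exercise the boundary; length of stay
from a gamma with mean 8.8 and SD 7.3 days; and 90-day death from a logistic
model in age (log-odds +0.7 per decade) whose per-intervention intercepts
are solved numerically so the marginal rates over the age distribution equal
29.3% (thrombectomy), 14.9% (thrombolysis) and 14.4% (other).  Edge cases —
under-18 admissions, repeated I63 events, admissions too close to the study
end, and a deliberately low-volume provider — are injected in configured
counts.

What the generator does **not** emulate: diagnosis-coding noise, transfers
within a stay (drip-and-ship pathways), reimbursement tariff structure,
regional geography, correlation between severity, cost and death beyond the
shared age effect, and provider-level quality differences (none are injected
by default, which is what makes the null funnel-coverage tests meaningful).
Passing tests therefore demonstrate the pipeline's arithmetic and rules, not
that any real provider difference is causal.

## Problem sizes and numerics

Tests run the generator at 300–20,000 patients; the full-scale default
(23,568) runs in seconds.  The standardization unbiasedness check uses 500
providers × 200 patients; funnel coverage checks use 2000 binomial units and
10⁴ normal units.  Quantiles use linear interpolation between order
statistics (numpy default); single-member groups report SD 0.  Monetary
values are kept as floats in EUR; a single configurable currency scale
factor supports CZK-denominated inputs, deliberately without any historical
exchange-rate logic.
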