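# strokecost

Claims-based analysis of 90-day costs, mortality and provider variability
after ischemic stroke.

Administrative (payer) claims are often the only population-scale source for
comparing what acute stroke care costs and what it achieves across hospitals.
`strokecost` implements a complete, tested pipeline for that comparison:

1. **Cohort construction** — the index event is a patient's earliest
   hospitalization with main ICD-10 diagnosis I63 (cerebral infarction) inside
   the study window; patients under 18 at admission and index events with
   fewer than 90 follow-up days before the study end are excluded, and
   providers reporting fewer than 30 index events are dropped for data
   reliability.  Treatment is classified from the index claim as mechanical
   thrombectomy, intravenous thrombolysis, or other (no reperfusion therapy),
   with thrombectomy taking precedence when both are coded.  Providers are
   tiered as comprehensive stroke centres (CSC), primary stroke centres
   (PSC), stroke-ready hospitals (SRH) or other.
2. **Episode costing** — payer costs over the half-open 90-day window
   `[index, index + 90d)`, split into primary hospitalization, other
   hospitalizations (any diagnosis, by admission date) and outpatient care;
   90-day all-cause mortality on the same window.
3. **Risk standardization** — indirect age standardization in the style of
   the AHRQ quality indicators: with age-stratum death rates `r_a` from the
   whole cohort as reference, each patient contributes an expected death
   probability `p_i`, and a group's standardized mortality is
   `(O / E) · r̄` with `O` observed deaths, `E = Σ p_i` and `r̄` the reference
   crude rate.
4. **Indicators** — per-group summaries (N, mortality, mean/SD/median/IQR of
   each cost component) and the *effective cost per survivor*

   ```
   ECPS = Σᵢ Cᵢ / (N − D)
   ```

   where `Cᵢ` is patient *i*'s total 90-day cost and `D` the 90-day deaths.
5. **Funnel plots** — Spiegelhalter control limits at the two-sided 95% and
   99.8% levels for three indicator families: proportions (exact
   continuity-interpolated binomial limits), standardized ratios `O/E`
   against `E` (exact interpolated Poisson limits) and continuous means
   (`μ₀ ± z·σ₀/√n`).  Units are flagged `inside` / `outside_95` /
   `outside_998` with direction.
6. **Synthetic claims** — a seeded generator reproducing the statistical
   structure of a Czech-scale stroke claims database (23,568 patients, age
   70.6 ± 12.4, 47% female, right-skewed lognormal costs, age-dependent
   logistic mortality, deliberate edge cases), because real insurer data
   cannot be shared.  Every downstream stage is testable against it.

## Worked example

Simulate a full-scale cohort and run every stage:

```bash
$ strokecost run --outdir demo --seed 42 --log-level WARNING
cohort N = 23441; outputs in demo

$ strokecost summarize --episodes demo/episodes.csv --outdir demo --by intervention
```

which prints (columns abridged):

| intervention | n | crude mortality | standardized | total cost mean | ECPS |
|---|---|---|---|---|---|
| other        | 18,137 | 14.4% | 14.4% |  2,712 |  3,168 |
| thrombectomy |  1,273 | 29.9% | 30.4% | 13,641 | 19,467 |
| thrombolysis |  4,031 | 15.9% | 15.8% |  4,230 |  5,030 |

Reading the row for thrombectomy: 1,273 patients, the highest 90-day
mortality (≈30%) and the highest mean 90-day cost (≈13.6 k EUR); dividing the
group's total cost by its 892 survivors gives an ECPS of ≈19.5 k EUR — the
cost the payer incurred per patient alive at day 90.  The `other` group is
the cheapest per survivor despite similar mortality to thrombolysis.

```bash
$ strokecost funnel --episodes demo/episodes.csv --outdir demo --plot
61 unit/family combinations outside the limits -> demo
```

`funnel_points.csv` flags each provider against the exact limits at its own
volume.  On this simulated cohort the cost funnel flags 48 of 80 providers
outside the 95% band (provider case-mix shifts mean costs strongly) while the
standardized-mortality funnel flags only 5 — costs vary across providers far
more than risk-adjusted outcomes, which is the pattern the method is designed
to expose.

Ingesting real data instead: put `patients.csv`, `providers.csv`,
`hosp_claims.csv`, `outpatient_claims.csv` (schemas in
`src/strokecost/io.py`; ISO-8601 dates, costs in EUR or any currency via the
configurable scale factor) in a directory and run
`strokecost build --input-dir DIR`.

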