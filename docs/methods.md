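# Methods

## Problem and design

`phenoval` implements and tests a validation workflow for EHR phenotyping
algorithms: rules that flag clinical events from coded data (here, acute
cerebrovascular disease in a hospital-based cancer registry) whose accuracy
must be established by chart review before the codes can serve as research
outcomes. The pipeline is

1. **registry cleaning** — drop duplicate patient registrations and rows with
   impossible dates, with a one-reason-per-row audit log;
2. **code extraction** — select diagnosis records matching an ICD-10 code set
   (stroke: categories I60, I61, I63 plus the exact TIA codes G458 and G459);
3. **same-day deduplication** — collapse repeat registrations of the same
   code for the same patient on the same day (different departments entering
   the same diagnosis);
4. **arm classification** — test each record against algorithm arms that
   combine the billing certainty flag ("definite" vs "suspected") with brain
   imaging linkage (none required / any order for the patient / an order
   within W days of the code date);
5. **validation** — per arm, a uniform 100-record sample is reviewed and the
   positive predictive value (PPV) estimated, overall and split by code
   position (primary vs secondary-or-others), with a breakdown of the
   false-positive mechanisms.

A synthetic-EMR generator stands in for the hospital database and the manual
review, so every stage is exercised end to end with known latent truth.

## Conventions and numerical choices

* **Dates** are day-resolution ISO-8601; all window arithmetic is in whole
  calendar days, because the source tables carry no time of day.
* **ICD-10 codes** are stored uppercase and dot-free (`I63.9` → `I639`).
  Code sets match by exact code, 3-character category prefix, or inclusive
  category range (block notation, e.g. hypertension I10–I15). G458/G459 are
  exact members: the rest of the G45 category is deliberately excluded.
* **Duplicate patients**: the earliest registration survives; on a
  registration-date tie a row with consistent dates is preferred, then file
  order, which makes the retained *count* invariant under row permutation. A
  row that is both a duplicate and has death-before-birth is logged once, as
  a duplicate, keeping the exclusion reasons disjoint and the conservation
  identity (retained + excluded = input) exact.
* **Same-day dedup survivor**: highest code position (primary > secondary >
  other), ties by file order; certainty groups are deduplicated
  independently.
* **Imaging windows** default to two-sided, |offset| ≤ W: the data cannot
  distinguish pre-admission imaging from confirmatory imaging ordered just
  after coding, and both are clinically plausible. One-sided variants
  (`after_only` / `before_only`) are one configuration flag away. "Within 1
  day" therefore means same day, previous day, or next day. The nearest
  offset reported for a record minimizes |offset| with a +d/−d tie resolved
  to +d.
* **Arms overlap** rather than partition: each is sampled and reviewed
  independently, matching a design where every arm gets its own 100-record
  review. Counts always nest: within-1 ⊆ within-30 ⊆ any-imaging ⊆
  certainty-alone.
* **Sampling** is uniform without replacement via `numpy.random.default_rng`;
  when an arm is smaller than the design size the whole arm is reviewed and
  a warning emitted.
* **Intervals**: Clopper–Pearson exact 95% CIs (via
  `statsmodels.stats.proportion.proportion_confint(method="beta")`), chosen
  because PPVs near 0.9 at n = 100 make normal approximations poor; the
  exact method is conservative by construction. Wilson is available through
  `ci_method="wilson"`.
* **Rounding** of reported percentages is nearest integer, ties away from
  zero. Pooling position strata sums integer numerators and denominators
  before any rounding, so the pooled PPV equals the sample-size-weighted
  mean of stratum PPVs exactly.

## The synthetic generator

`generate_cohort` emulates a hospital-based cancer registry of ~25,827
patients (49.5% female, age 61.6 ± 15.7 years at registration, cancer-type
and stage mixes from typical comprehensive-cancer-center composition) over a
2007–2015 window, with 2,083 injected duplicate registrations and 22
death-before-birth mistakes upstream of cleaning. Every stroke-code record
traces to exactly one mechanism:

| mechanism | certainty | truth | imaging offset model (default) |
|---|---|---|---|
| true_event | definite | positive | 0 or ±1 day |
| history_of_stroke | definite | negative | none (60%) or beyond ±30 days |
| stroke_mimic | definite | negative | ±1 day (58.3%) or 2–30 days |
| blood_or_imaging_tests | definite | negative | none |
| ruleout_suspected | suspected | 7% positive | 0 or ±1 day |

### Calibration of the default rates

Write t, m₁, m₃₀, h, e for the per-patient rates of true events, mimics with
imaging within 1 day, mimics with imaging at 2–30 days, history-of-stroke
coding, and test-only coding, and f for the fraction of history coders with
(distant) imaging. The expected full-arm PPVs are

* within-1-day arm: t / (t + m₁)
* within-30-days arm: t / (t + m₁ + m₃₀)
* any-imaging arm: t / (t + m₁ + m₃₀ + f·h)
* definite arm: t / (t + m₁ + m₃₀ + h + e)

Setting these to 0.90 / 0.84 / 0.51 / 0.22 and scaling the total definite
rate to 912 events per 25,827 patients gives (with f = 0.4) the shipped
defaults: t = 0.007769, mimic rate 0.001480 with a 0.58333 within-1-day
share, history rate 0.014962, test-only rate 0.011103. The suspected rate
0.008828 targets 228 rule-out codes with a 7% true fraction. The calibration
targets the PPV gradient, not the arm sizes: full-arm PPVs are a modeling
choice (only 100-record samples are ever reviewed), and matching both the
gradient and all raw arm sizes simultaneously would over-determine the
mechanism mix. The exact flow counts are instead reproduced by the
deterministic fixture mode.

Same-day duplication re-registers each code event a geometric number of
extra times (parameter 0.54, mean ≈ 1.17 extras), reproducing the observed
expansion from ~912 distinct definite events to ~1,991 records. One master
seed drives ordered sub-streams per table, so changing one mechanism's rate
never perturbs draws for mechanisms generated before it — this is what makes
the paired-seed monotonicity property (raising the test-only rate lowers the
definite-arm PPV while leaving the within-1-day arm PPV exactly unchanged)
hold deterministically.

### What the generator does *not* emulate

Background brain imaging is assigned only to patients **without** stroke
codes, so that the mechanism offset models fully control arm membership; in
a real EMR, coded patients also receive imaging unrelated to the code, which
would soften the arm gradient. There are no clinical narratives, no survival
process interacting with coding, no department-level coding-style clusters,
and offsets are independent across a patient's orders. Passing tests
therefore demonstrate that the pipeline arithmetic, linkage logic, and
interval behavior are correct under a known generative model — not that any
particular hospital's codes have these PPVs.

### Fixture mode

`generate_fixture` deterministically realizes exact pipeline counts: one
event per patient (so patient-level imaging linkage cannot leak between
events), imaging offsets laid out in bands (within 1 day / 2–30 days /
beyond 30 days / none), totals expanded by same-day re-registrations with
position "other" so dedup survivors are the original events, and optional
padding of imaging orders on stroke-free patients up to a configured total.
Truth labels are deterministic and approximate the observed full-arm PPV
gradient (≈ 24.5 / 50.9 / 84.1 / 90.1 / 7.0% across the five arms);
infeasible count combinations (broken nesting, too few patients) raise a
named error at specification time.

## Problem sizes in the tests

The default suite runs in well under a minute: property tests use random
bundles of ≤ 200 rows against brute-force all-pairs oracles; interval
coverage uses 2,000 simulated 100-record reviews at each of five true rates
(0.07, 0.22, 0.51, 0.84, 0.90); generator parameter recovery draws 500
seeded 100-record reviews per arm from one full-scale calibrated cohort and
checks that the estimate's 95% CI captures the realized full-arm truth
fraction at least 95% of the time (review sampling is without replacement,
so the binomial-based exact interval is conservative there too).

## Known limitations

* The duplicate-patient rule is identity-based (repeated `patient_id`); no
  probabilistic record linkage.
* Imaging records are treated as performed studies; the schema calls them
  orders and no completion status exists.
* Sensitivity, specificity, and NPV are out of scope by design: validation
  reviews only algorithm-flagged records, so false negatives are unobserved.
* Three-level code position is preserved in data but collapsed to
  primary vs secondary-or-others for reporting.
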