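# phenoval

Validation tooling for EHR **phenotyping algorithms** — rules that identify
clinical events from coded electronic-medical-record data. The package
implements the full workflow for validating stroke ICD-10 diagnostic codes
in a hospital-based cancer registry: registry cleaning, code-set extraction,
same-day deduplication, diagnosis–imaging temporal linkage, chart-review
sampling, and positive-predictive-value (PPV) estimation — plus a
synthetic-EMR generator with latent ground truth that stands in for the
hospital database and the manual chart review.

It is written for clinical epidemiologists and medical informaticians who
need to quantify, before running a study on coded outcomes, how often a
diagnostic code actually corresponds to the disease.

## The method

Diagnosis codes alone overstate disease: codes are entered for rule-outs,
old events, and test ordering. The algorithm under validation tightens a
code-based case definition stepwise with clinical information:

1. **definite** — a "definite"-flagged stroke code (I60, I61, I63, G458,
   G459), after collapsing same-day duplicate registrations;
2. **definite + any imaging** — plus any brain CT/MRI order for the patient;
3. **definite + imaging within 30 days** of the code date (|offset| ≤ 30);
4. **definite + imaging within 1 day** (|offset| ≤ 1);
5. **suspected + any imaging** — the rule-out codes, as a floor.

For each arm, a uniform random sample of n = 100 records is chart-reviewed
and the PPV estimated as

&nbsp;&nbsp;&nbsp;&nbsp;PPV = (confirmed acute cerebrovascular events) / n,

reported overall and by code position (primary vs secondary-or-others) with
exact Clopper–Pearson 95% intervals; position strata pool by summing
numerators and denominators. False positives are broken down into history of
stroke, stroke mimics (seizure, syncope, tumor, ...), and codes entered only
for blood/imaging tests.

## Worked example

Pooled PPV arithmetic from reviewed stratum counts
(`python examples/worked_ppv_arithmetic.py`):

```
arm                            primary  secondary  pooled  95% CI (pooled)
definite code alone                57%        19%     22%  [0.14, 0.31]
+ any brain imaging                57%        51%     51%  [0.41, 0.61]
+ imaging within 30 days           75%        85%     84%  [0.75, 0.91]
+ imaging within 1 day             86%        90%     90%  [0.82, 0.95]
suspected + any imaging              -          -      7%  [0.03, 0.14]
```

Reading: one in five "definite" stroke codes reflects a real acute event;
requiring brain imaging within a day of the code raises the PPV to 90%.

A full synthetic validation study — generate a 25,827-patient cohort with
latent truth, run the pipeline, review 100 records per arm with the
simulated reviewer, estimate PPVs
(`python examples/simulate_validation_study.py`):

```
cohort: 25827 patients, 2651 stroke-code records, 1193 after dedup
arm sizes: {'definite': 961, 'definite_any': 403, 'definite_w30': 236, 'definite_w1': 218, 'suspected_any': 232}

arm                n   PPV  95% CI        full-arm truth
definite         100   19%  [0.12, 0.28]   19.3%
definite_any     100   48%  [0.38, 0.58]   45.9%
definite_w30     100   83%  [0.74, 0.90]   78.4%
definite_w1      100   83%  [0.74, 0.90]   84.9%
suspected_any    100    4%  [0.01, 0.10]    4.3%
```

Each estimate's interval covers the latent full-arm truth fraction that only
the generator can see — the property the validation design relies on.

`python examples/flow_count_fixture.py` runs the deterministic exact-count
fixture: 27,932 registry rows clean to 25,827 patients (2,083 duplicates, 22
impossible dates excluded); 2,654 stroke-code records deduplicate to 912
definite + 228 suspected; the arms contain 912 / 438 / 239 / 212 / 228
records.

## Command line

A thin CLI wraps the same functions:

```bash
phenoval simulate --fixture --seed 5 --out synth/
phenoval clean    --patients synth/patients.csv --out-dir cleaned/
phenoval classify --bundle-dir cleaned/ --out assignments.csv
phenoval sample   --assignments assignments.csv --arm definite_w1 \
                  --n 100 --seed 20071231 --out worksheet.csv
phenoval estimate --worksheet worksheet.csv --labels synth/truth.csv \
                  --out report/
```

`worksheet.csv` is what a human reviewer would fill in; `truth.csv` from the
generator plays that role here.

## Layout

- `src/phenoval/emr_tables.py` — typed EMR tables, strict CSV I/O
- `src/phenoval/cohort_cleaning.py` — registry exclusions with audit log
- `src/phenoval/code_sets.py` — ICD-10 normalization, code sets, prevalence
- `src/phenoval/phenotyping.py` — same-day dedup and imaging-linkage arms
- `src/phenoval/validation_study.py` — sampling, PPV + exact CIs, reports
- `src/phenoval/synthetic_emr.py` — cohort generator and exact-count fixture
- `docs/methods.md` — modeling assumptions, calibration, limitations
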