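# Methods

## Problem and scope

`precohort` supports a form of personalized comparative-effectiveness
analysis on administrative claims data.  Instead of estimating an average
treatment effect over a heterogeneous population, the workflow trims a
conventionally selected study cohort down to a *precision cohort* — the
patients most similar to one index case — and compares treatment arms
within that subset.  The package covers the whole chain: a synthetic claims
generator, cohort selection, mixed-type similarity, distribution charts,
and Kaplan–Meier comparison.  Confounding control (propensity scores,
weighting, outcome models) is deliberately out of scope: in the synthetic
data, treatment is assigned by design independently of the covariates, and
on real data such adjustments should be inserted between cohort selection
and similarity search.

## Claims-data model

Three CSV tables with daily date granularity: `INSURANTS(ID, SEX,
DATEOFBIRTH, DATEOFDEATH)`, `PRESCRIPTIONS(ID, ATC, DATE)`, `DIAGNOSES(ID,
ICD, DATE)`.  Birth dates are calendar years only, so every age in the
package is a year difference; death dates are absent for patients alive at
the end of the observation window.  Validation enforces unique patient IDs,
referential integrity, non-empty codes, dates inside the observation
window, and no claims after death.

## Synthetic claims generator

The generator emulates a statutory-health-insurance extract with a designed
sub-population for the anticoagulation example:

| parameter | default | meaning |
| --- | --- | --- |
| `n_patients` | 10,000 | insurants |
| `drug_a_id_max` | 3,233 | IDs 1..3233 receive drug A (B01AE07), 1–10 redemptions |
| `af_id_max` | 6,148 | IDs 3234..6148 receive drug B (B01AF01); all IDs ≤ 6148 carry atrial fibrillation (I48.*, 2–5 diagnoses), C07 (1–10) and C09 (1–20) prescriptions |
| `extra_comed_range` | (2, 5) | background co-medications per patient, any ID |
| `extra_diag_range` | (1, 20) | background diagnoses per patient, any ID |
| `birth_year_range` | (1930, 1950) | uniform birth years; an elderly population |
| `baseline_hazard` | 0.0005 / day | exponential death hazard at linear predictor 0 |
| `observation_window` | 2009-01-01..2016-12-31 | claims era |

Codes are drawn from packaged synthetic vocabularies (~200 ATC, ~300
ICD-10 codes).  The vocabularies exclude the two study drugs and the I48
block, so the designed ID ranges alone determine exposure and the
atrial-fibrillation population — which is what makes the designed counts
above exact rather than approximate.  The diagnosis pool's comorbidity
blocks are sized so heavy utilizers acquire each Elixhauser group with
realistic frequency (roughly: hypertension 30 %, diabetes 20 %, solid
tumor 15 %, depression 15 %, metastatic cancer 5 %).

Death dates come from inverse-transform sampling of an exponential
proportional-hazards model, `T = -ln(U) / (λ₀ · exp(x'β))`, measured from
the patient's first study-drug prescription (background patients: the
window start).  Times running past the window end are administratively
censored.  Covariates are indicators for the two drugs, the C07/C09
classes, four Elixhauser groups (hypertension, diabetes, solid tumor,
metastatic cancer), female sex, and age coded `(age − 70)/10` at the
origin year; age at the *index* year was chosen over age at window start
because the index is where follow-up begins.

The default effect sizes are a design choice (no canonical values exist):
mortality rises with age (+0.3 per decade) and comorbidity burden (+0.2 to
+1.0), the drugs have no main effects, and the arms trade places through
symmetric interactions — drug A is protective for diabetic (∓1.8) and
older (∓0.3) patients, drug B for hypertensive (±1.8) patients and
marginally for women (±0.1).  The magnitudes are deliberately large: the
example exists to show *clearly* divergent survival curves for index
patients with opposite comorbidity profiles, and the divergence must
survive the sampling noise of precision-cohort arms of ~80 patients.  The
sign structure, not the magnitudes, is what the example's logic rests on.

The observation window extends two years before the 2011–2016 claims era
so that new users indexed early in the era can still satisfy a one-year
run-in; under the defaults the initial cohort is ~1,600 patients and each
precision cohort ~160.

Record dates are drawn uniformly over the window; any date falling after
the patient's simulated death is redrawn uniformly before it.  This keeps
per-patient record counts exactly inside their configured ranges while
honoring the no-claims-after-death invariant.  One seeded generator drives
all draws in fixed order (sexes, birth years, then per-patient blocks by
ascending ID), so a config plus seed reproduces the dataset byte for byte.

What the generator does *not* emulate: seasonality or autocorrelation in
prescription refills, code frequency distributions of a real insurer
(draws are uniform over the vocabulary), regional or provider structure,
enrollment gaps, and any confounding by indication (treatment is assigned
by ID block, independent of covariates).  Passing end-to-end tests on this
data therefore demonstrates the mechanics and determinism of the workflow,
not robustness to the messiness of real claims.

## Cohort selection

The new-user design anchors each patient's index date at their first-ever
prescription of any target ATC prefix; the prevalent-user design takes the
first prescription after the run-in period regardless of earlier history.
Inclusion requires ≥ `run_in_days` (default 365) between the patient's
earliest claim of any kind and the index, a minimum age at index (default
18, computed as index year − birth year), at least one required diagnosis
dated at or before index ("anywhere before index" rather than inside the
run-in window — the looser, more common reading), and survival to index.
Under the new-user design, a patient whose first exposure day carries two
distinct target drugs has no well-defined arm and is excluded (logged);
same-day ties within one prefix resolve to the lexicographically smallest
code.

## Similarity

Default feature set per cohort member, computed from records dated at or
before the index (baseline characterization; a full-history option
exists): age at index (continuous), sex (categorical), C07 and C09
exposure indicators, and five Elixhauser group indicators (hypertension,
diabetes, solid tumor, metastatic cancer, depression) from a minimal
editable ICD-10 prefix map — not the full 31-group algorithm, and no
weighted point score.  Treatment is intentionally *not* a similarity
variable: the index case is a treatment-naive patient for whom the arm is
the open question, and conditioning similarity on arm would collapse the
within-cohort comparison to a single arm.

Gower's dissimilarity averages range-normalized absolute differences
(continuous) and mismatch indicators (categorical/binary) over the
variables observed in both rows, with optional per-variable weights;
binary double-zeros count as matches by default, with Gower's asymmetric
coefficient available as an option.  HEOM combines the same per-variable
pieces in a Euclidean sum, scoring any missing value as the maximal
difference 1.  Continuous ranges are the reference cohort's min–max,
widened to cover an index case lying outside them so Gower stays in
[0, 1].  A zero-range variable contributes 0 with a warning.

Trimming keeps the `floor(fraction · N)` nearest patients (default 10 %),
with ties at the cutoff and all other ties broken by ascending patient ID.
Alternatively, PAM (k-medoids: greedy BUILD seeding, then steepest-descent
SWAP until no single medoid↔non-medoid exchange improves the total
within-cluster distance) partitions the cohort and the index case's
cluster — the cluster of the medoid nearest to the case, assigned post
hoc without the case participating in clustering — becomes the precision
cohort.  PAM is deterministic given the tie rules; like any single-swap
local search it can terminate in a local optimum, so on pathological
instances its cost may exceed the exhaustive-search minimum (the same
behavior as the reference R implementation).  `k` is user-chosen; no
automatic selection is provided.  Distance evaluation is partitionable
over rows and yields identical results under any partitioning.

## Scale charts

`summarize_reference` reduces the cohort to per-variable summaries: a
five-number summary with linear-interpolation ("type 7") quartiles for
continuous variables, relative category frequencies for the rest.
`draw_scale_chart` renders one horizontal track per variable — four graded
segments (min–Q1–median–Q3–max) for continuous variables, frequency-
proportional segments in descending order for categorical ones — with the
index patient's value as a red marker, clamped and annotated when outside
the reference range.  Drawing consumes only the summary profile, never the
raw matrix.

## Survival comparison

Follow-up runs from index to death (event) or to the window end
(administrative censoring — the package's documented assumption for
survivors).  The product-limit estimator processes deaths before
censorings on tied times; Greenwood's formula supplies optional confidence
bands.  The core output is graphical (one step curve per arm with at-risk
counts); the workflow additionally reports each arm's survival at the
precision cohort's median follow-up time and names the arm with the higher
estimate.  A log-rank test is available as an optional extra but is not
part of the core comparison, which is deliberately descriptive.

## Numerical conventions

- Durations are integer day counts; simulated survival times are truncated
  to whole days.
- Fraction-based selection uses floor; an empty selection is an error that
  suggests a larger fraction.
- All tie-breaks (treatment codes, distance ranks, medoids, swaps) resolve
  to the lexicographically or numerically smallest candidate.
- Problem sizes used by the test suite: the full 10,000-patient default
  population for the designed-count, cohort-verifier and end-to-end
  checks; a proportionally scaled 1,000-patient population for loop-heavy
  brute-force oracles; 100 instances with N ≤ 12 for the PAM-vs-exhaustive
  comparison; 10,000 random row pairs for metric properties and 10,000
  draws for the exponentiality check.

## Known limitations

- The comorbidity grouper is a deliberately minimal prefix map; it is an
  editable packaged file, not a validated implementation of the published
  Elixhauser algorithm.
- Age arithmetic is year-granular because births are stored as years.
- The simulator's uniform record dates make early-window index dates and
  pre-index diagnosis capture less frequent than in real data, where
  utilization precedes a new prescription more systematically.
- No treatment-episode logic: exposure is "ever prescribed at/before a
  date", with no gap or discontinuation handling.
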