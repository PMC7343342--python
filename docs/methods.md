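# Methods

This note records the analytic conventions, model assumptions, default
parameters and known limitations of the `vocburden` pipeline.

## Study design implemented

Retrospective open-cohort design over administrative claims. The index
date is the first claim with a sickle cell disease (SCD) diagnosis
(ICD-9-CM 282.41, 282.42, 282.60–282.69, any diagnosis position) inside
the identification period, 2009-07-01 through 2012-12-31 (both
configurable via `StudyWindows`). Anchored at the index date:

* **baseline window** = [index − 6 *calendar* months, index − 1 day].
  Calendar months (same day-of-month, clamped to month end) rather than
  a fixed 180 days, avoiding the silent 180/183-day ambiguity;
  configurable via `baseline_months`.
* **follow-up window** = [index, index + 364 days], a fixed year.
* Observation ends at the earliest of death, study end (2013-12-31) and
  follow-up end. Death truncates follow-up but does not remove the
  patient (`followup_end_actual` records the truncation).

All windows are closed intervals of whole calendar days; dates are
ISO-8601 in files. Diagnosis codes are stored dotless and
category-padded ("282.62" ⇌ "28262"), with both forms accepted on input,
so dotted configuration and dotless claim feeds cannot mismatch.

Eligibility cascade, in order: SCD index date exists → age ≥ 18 at index
→ continuous enrollment → no clinical-trial flag. "Continuous" means
zero uncovered days, by both medical and pharmacy benefits, over
baseline + follow-up; because claims studies commonly tolerate 30- or
45-day gaps, `allowable_gap_days` (total uncovered days tolerated,
default 0) is exposed. Eligibility is a pure per-patient function, so
results are invariant to row order and to the presence of other
patients.

## Episode construction

VOC claims carry 282.42, 282.62, 282.64 or 282.69 in any position (a
strict subset of the SCD codes; 282.60 identifies SCD but not a
crisis). Within one patient, claims sorted by (service_start,
service_end, claim_id) — the id as deterministic tie-break — are merged
greedily: a claim joins the open episode iff

    service_start − episode_running_end ≤ gap_days   (whole days),

with the episode end extending to the maximum service_end seen. Under
the default `gap_days = 3`, single-day claims on day 1 and day 4 merge;
day 1 and day 5 do not. The gap is measured end-to-start (a long
inpatient stay keeps absorbing nearby claims); a start-to-start variant
was considered and rejected because it would split claims inside a long
stay, but the parameter is exposed rather than hard-coded. The greedy
rule on sorted claims is provably identical to connected components of
the interval graph with the same gap relation, and tests verify this
against an independent union-find oracle.

Episode duration = end − start + 1 (a single-day episode has duration
1). Episodes may straddle the follow-up boundary; stratification
membership is by episode *start* date. Episode counts in follow-up are
banded 0 / 1 / 2 / 3+.

Setting assignment is a strict priority over member claims'
place-of-service categories: inpatient > ER > outpatient > office >
other, where *outpatient* covers outpatient hospital, ambulatory surgery
center, nursing facility and long-term care; *office* covers independent
clinic, federally qualified health center, state/local public health
clinic and rural health clinic; and *other* absorbs every remaining
category (lab, hospice, home, unclassified outpatient). An unmapped code
is a hard error naming the code, never a silent default.

## Comorbidity scoring

The Charlson Comorbidity Index uses the Deyo ICD-9-CM adaptation with
the original weights (1/2/3/6), shipped as editable YAML
(`data/cci_map.yaml`) because the mapping is a methodological choice,
not code. Matching is by code prefix; each condition counts once no
matter how many claims mention it; severity hierarchies score only the
severe member (diabetes with complications over diabetes,
moderate/severe over mild liver disease, metastatic tumor over
malignancy). SCD codes themselves are not in the map and never score;
whether a published analysis should exclude other SCD-driven codes
(e.g., pulmonary ranges) is a sensitivity question the configuration
file makes easy to explore. Condition flags for the baseline table
(asthma, fever, infectious disease, …) are likewise configured ICD-9
stems (`data/condition_codes.yaml`), since published tables print
condition names, not code lists.

## Cost and utilization conventions

* Costs are restated in 2013 USD by multiplying service-year amounts by
  factors derived from annual averages of the CPI medical-care component
  (BLS series CUUR0000SAM; `data/cpi_medical.yaml`, editable). Missing
  service years are hard errors.
* A claim is **SCD-related** if it carries an SCD diagnosis in any
  position, is a transfusion procedure, or (pharmacy) belongs to a
  configured SCD drug class (default: opioids, NSAIDs, hydroxyurea,
  antibiotics, acetaminophen, folic acid). By construction SCD-related
  cost ≤ all-cause cost per patient-facility; this containment is
  property-tested.
* A **visit** is one facility type per service-start day per patient
  (claim lines de-duplicated), except inpatient, where overlapping or
  abutting inpatient claim spans merge into admissions and length of
  stay is the summed inclusive days. Claims are attributed to windows by
  service-start date.
* Cost statistics cover fee-for-service enrollees only (managed-care
  amounts are not recorded in MAX-style data); utilization covers the
  whole cohort. Zero-cost patients contribute zeros to means and
  medians — except in the cost frequency distribution, which drops
  US$0 totals because a zero may mean uncaptured costs rather than no
  care. The "total" row sums inpatient, the four outpatient categories,
  long-term care and pharmacy.
* **Per-episode cost** = all medical claims (any setting, any diagnosis)
  starting inside the episode window, plus SCD-class pharmacy fills in
  the window, both CPI-adjusted. Care delivered during a crisis is
  attributed to the crisis; per-episode and annual totals are therefore
  not additive decompositions of each other and are never reconciled.

## Synthetic data generator

The generator (`vocburden.synthetic`) emulates the structure of MAX-like
claims so the whole pipeline is testable without restricted data. Per
patient: demographics from configurable marginals (67.3% female, 74%
Black, four regions, 49.8% fee-for-service, age bands 18–30/31–45/
46–64/65+ with weights 0.519/0.296/0.179/0.006); one SCD index claim on
a uniform day of the identification period; follow-up VOC episode count
K ~ NegBin(mean 2.0, dispersion 0.35), giving variance ≈ 13.4 and ~51%
zeros — the overdispersion and long right tail characteristic of claims
counts; claims per episode 1 + Poisson(1); episode setting from
(0.378, 0.362, 0.182, 0.058, 0.020) over inpatient/ER/outpatient/
office/other; per-claim costs lognormal with setting-dependent location
(μ 8.11 inpatient down to 4.11 other, σ = 1), chosen so mean costs rank
inpatient > ER > outpatient > office; background non-SCD claims at
12/patient-year and pharmacy fills at 10/patient-year over the coverage
span; 12% of patients lose coverage before the follow-up year completes;
1% carry a trial flag; 0.3% die during follow-up. All parameters live in
the versioned `data/generator_default.yaml`; the distributional forms
and scales are realistic-shape stand-ins, not calibrated estimates.

**Identifiability by construction.** Within an episode, consecutive
claim start gaps are drawn from 1..3 days; across episodes, leftover
follow-up days are distributed multinomially over gaps forced to exceed
the 3-day threshold; extra member claims draw only equal-or-lower
priority settings than the episode's assigned setting. Hence the episode
grouper recovers counts, windows and hierarchy settings *exactly* for
every patient and seed — a structural guarantee that the grouper is
correct on data satisfying its assumptions, not evidence about real
claims, where episodes genuinely blur together. Two further consequences
to keep in mind:

* Episode placement is uniform-with-rejection, not clustered in time;
  real crises cluster.
* When a patient's drawn episodes cannot fit the follow-up window with
  the required separations, trailing episodes are dropped. This
  truncation, concentrated in dropout patients with short windows,
  biases the realized mean episode count ~2% below the configured mean
  (realized ≈ 1.96 across seeds at the defaults; 2.014 at the reference
  seed 7).
* Baseline VOC episodes are only placed where they can never collide
  with index assignment — before the identification period opens and
  ending > 3 days before the index claim — so baseline VOC prevalence
  in the synthetic data (~4%) is far below real-world reports (~25%).
  A VOC claim inside the identification period would itself become the
  index, so this is a logical constraint of the design, not only of the
  generator.

Randomness flows from a single `numpy.random.default_rng` (PCG64)
stream; dates are integer day arithmetic; reruns are byte-identical
across platforms.

The 12-patient eligibility stress fixture is hand-designed, one patient
violating each rule, with hand-computed attrition (12 → 11 → 10 → 7 → 6)
shipped as fixture metadata; it doubles as the worked example for the
cost ledgers, which tests verify against hand-summed totals.

## Problem sizes and numerical choices

Study-scale checks (ground-truth recovery, conservation/containment,
qualitative cost orderings) run on 5000 patients at seed 7 — large
enough that the strict orderings across strata and settings are
overwhelmingly signal, small enough for an ordinary laptop run; the
grouper oracle comparison uses 1000 random claim sets of up to 40 claims.
Monetary amounts are rounded to cents at generation and to cents in
analytic outputs; presentation tables round percentages to one decimal.
Ties in claim ordering break on claim id; empty inputs (empty cohort,
zero episodes, no covered days) are defined outcomes, not errors.

## Limitations

* Single claim line = one record; multi-line institutional claims,
  MAX segment layouts, X12/EDI and ICD-10 are out of scope.
* The managed-care completeness problem of real MAX data (14-state
  rule) is modeled only as a plan-type flag.
* No risk adjustment, regression modeling or causal claims — the
  pipeline is descriptive, as is the design it implements.
* Synthetic magnitudes (costs, prevalences) are internally consistent
  but deliberately uncalibrated; only structural and ordinal properties
  should be read out of them.
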