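# vocburden

Claims-based analysis of the health-care burden of vaso-occlusive crisis
(VOC) in adult sickle cell disease (SCD).

VOC — the acutely painful vascular occlusion that is the hallmark
complication of SCD — drives emergency visits, hospital admissions and
much of the cost of caring for adults with the disease. This package
implements, as a tested and reusable pipeline, the standard
retrospective-claims design used to quantify that burden in Medicaid
Analytic eXtract (MAX)-style administrative data:

1. **Cohort construction.** The *index date* is the first claim carrying
   an SCD diagnosis (ICD-9-CM 282.41, 282.42, 282.60–282.69, any
   position) during the identification period (2009-07-01 to
   2012-12-31). Eligible patients are ≥18 years at index, continuously
   enrolled with medical *and* pharmacy coverage for the 6-month
   baseline and the 1-year follow-up, and not flagged as clinical-trial
   participants. An attrition table records each step.
2. **Episode construction.** VOC claims (ICD-9-CM 282.42, 282.62,
   282.64, 282.69, any position) are merged into episodes with a
   *3-day-gap rule*: sorted by service date, a claim joins the open
   episode iff `service_start − episode_end ≤ g` days (default `g = 3`);
   this is exactly the connected components of the interval graph with
   the same gap relation. Each episode receives one care setting by the
   hierarchy **inpatient > ER > outpatient > office > other** over its
   member claims' place-of-service codes.
3. **Comorbidity.** Baseline Charlson Comorbidity Index (Deyo ICD-9-CM
   adaptation, weights 1/2/3/6, severity hierarchies applied) plus
   condition, medication-class, transfusion and utilization flags.
4. **Utilization and costs.** Annual all-cause and SCD-related
   utilization and costs by facility type (costs restated in 2013 USD
   with CPI-Medical factors and restricted to fee-for-service enrollees,
   whose amounts MAX records), SCD-related summaries stratified by
   follow-up episode count (0 / 1 / 2 / 3+), per-episode costs by
   setting, and the per-stratum cost frequency distribution.

Real MAX data are access-restricted, so the package ships a seedable
synthetic claims generator that reproduces the *structure* the analysis
assumes — overdispersed (negative-binomial) episode counts, clustered
VOC claims across settings, right-skewed lognormal costs ordered
inpatient > ER > outpatient > office, enrollment churn — together with a
ground-truth episode table that the episode grouper recovers exactly, by
construction. Every stage is therefore testable end to end without any
data download.

Intended users: health-economics and outcomes researchers working with
administrative claims, and anyone needing a reference implementation of
gap-based episode-of-care grouping with hierarchical setting assignment.

## Worked example

Run the numbered analysis scripts in order (raw simulated tables land in
`scratch/data/`, summary tables in `results/`):

```bash
python analysis/01_simulate_claims.py
python analysis/02_build_cohort.py
python analysis/03_construct_episodes.py
python analysis/04_baseline_characteristics.py
python analysis/05_cost_analysis.py
```

On the default configuration (5000 patients, seed 7) this prints, among
other things:

```
eligible cohort: 4351 of 5000 (87.0%)
episodes: 10350; mean duration 3.80 days
ground-truth recovery exact: True
cohort n=4351; 67.6% female; mean CCI 0.37; 63.0% with CCI 0
annual mean total cost (FFS): all-cause $8,188, SCD-related $6,491 (79% of total)
mean SCD-related cost by episode stratum:
   0: $669  (n=2251)
   1: $3,617  (n=657)
   2: $6,386  (n=365)
  3+: $20,633  (n=1078)
```

Reading the output: 649 of 5000 simulated patients fail eligibility
(mostly enrollment churn); the grouper reconstructs every generated
episode exactly; and mean SCD-related annual cost rises steeply and
monotonically with episode frequency — the qualitative pattern the
design is built to surface — with inpatient episodes by far the most
expensive per episode (here $6,798 vs $834 for ER). Synthetic magnitudes
depend on the configured cost scales and are not calibrated to any real
population.

The same pipeline runs over your own delimited-text tables via the CLI:

```bash
voc-episodes synth --n 1000 --seed 42 --out data/       # or bring your own
voc-episodes run --config run.yaml                      # full pipeline
voc-episodes cohort --in data/ --out cohort.csv         # ... or stage by stage
```

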