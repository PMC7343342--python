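#!/usr/bin/env python
"""Baseline demographics and clinical characterization of the cohort.

Computes the demographic table (age bands, sex, race, region, plan type)
and the baseline clinical table: Charlson Comorbidity Index score/bands,
comorbid condition flags, SCD medication and transfusion use, baseline
VOC burden and baseline utilization. Writes table1_demographics.csv and
table2_baseline.csv.
"""

from pathlib import Path

import pandas as pd

from vocburden.claims_model import read_claims_tables
from vocburden.comorbidity import baseline_profiles
from vocburden.pipeline import baseline_table, demographic_table

ROOT = Path(__file__).resolve().parent.parent / "results"
DATA = Path(__file__).resolve().parent.parent / "scratch" / "data"


def main() -> None:
    paths = {k: DATA / f"{k}.csv" for k in ("patients", "medical", "pharmacy", "enrollment")}
    bundle, _ = read_claims_tables(paths)
    cohort = pd.read_csv(DATA / "cohort.csv")
    for col in cohort.columns:
        if col.endswith(("_date", "_start", "_end", "_actual")):
            cohort[col] = pd.to_datetime(cohort[col])

    profiles = baseline_profiles(bundle, cohort)
    t1 = demographic_table(cohort, bundle.patients)
    t2 = baseline_table(profiles)
    t1.to_csv(ROOT / "table1_demographics.csv", index=False)
    t2.to_csv(ROOT / "table2_baseline.csv", index=False)

    mean_cci = t2[t2["section"] == "cci"]["value"].iloc[0]
    cci0 = t2[(t2["section"] == "cci_band") & (t2["level"] == "0")]["value"].iloc[0]
    female = t1[(t1["section"] == "sex") & (t1["level"] == "female")]["value"].iloc[0]
    print(f"cohort n={len(cohort)}; {female:.1f}% female; "
          f"mean CCI {mean_cci:.2f}; {cci0:.1f}% with CCI 0")


if __name__ == "__main__":
    main()
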