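#!/usr/bin/env python
"""Apply the eligibility cascade to the simulated claims.

Index date = first SCD-coded claim in the identification period
(2009-07-01..2012-12-31); then age >= 18, continuous medical+pharmacy
enrollment over the 6-month baseline and 1-year follow-up, and no
clinical-trial flag. Writes attrition.csv (cohort rows go to scratch/data/).
"""

from pathlib import Path

from vocburden.claims_model import read_claims_tables
from vocburden.cohort import build_cohort
from vocburden.pipeline import _dates_to_str

ROOT = Path(__file__).resolve().parent.parent / "results"
DATA = Path(__file__).resolve().parent.parent / "scratch" / "data"


def main() -> None:
    paths = {k: DATA / f"{k}.csv" for k in ("patients", "medical", "pharmacy", "enrollment")}
    bundle, _ = read_claims_tables(paths)
    cohort, attrition = build_cohort(bundle)
    _dates_to_str(cohort).to_csv(DATA / "cohort.csv", index=False)
    attrition.to_csv(ROOT / "attrition.csv", index=False)
    print(attrition.to_string(index=False))
    print(f"\neligible cohort: {len(cohort)} of {len(bundle.patients)} "
          f"({100 * len(cohort) / len(bundle.patients):.1f}%)")


if __name__ == "__main__":
    main()
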