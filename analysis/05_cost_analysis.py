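#!/usr/bin/env python
"""Annual and per-episode utilization/cost analysis.

Produces the annual all-cause and SCD-related summaries by facility type
(costs over the FFS subpopulation, 2013 USD), SCD-related summaries
stratified by follow-up episode count (0/1/2/3+), per-episode costs by
care setting, and the per-stratum cost frequency distribution. Writes
table3_annual.csv, strata_summary.csv, episode_setting_costs.csv and
cost_distribution.csv.
"""

from pathlib import Path

import pandas as pd

from vocburden.claims_model import read_claims_tables
from vocburden.costs import (
    annual_summary,
    cost_frequency_distribution,
    episode_costs,
    load_cpi,
    stratified_summary,
    SCDAttributionRules,
)
from vocburden.pipeline import strata_totals

ROOT = Path(__file__).resolve().parent.parent / "results"
DATA = Path(__file__).resolve().parent.parent / "scratch" / "data"


def main() -> None:
    paths = {k: DATA / f"{k}.csv" for k in ("patients", "medical", "pharmacy", "enrollment")}
    bundle, _ = read_claims_tables(paths)
    cohort = pd.read_csv(DATA / "cohort.csv")
    for col in cohort.columns:
        if col.endswith(("_date", "_start", "_end", "_actual")):
            cohort[col] = pd.to_datetime(cohort[col])
    episodes = pd.read_csv(DATA / "episodes.csv", parse_dates=["start", "end"])
    cpi = load_cpi()
    rules = SCDAttributionRules()

    fu = cohort.set_index("patient_id")[["followup_start", "followup_end"]]
    ep = episodes.join(fu, on="patient_id")
    in_fu = ep[(ep["start"] >= ep["followup_start"]) & (ep["start"] <= ep["followup_end"])]
    counts = in_fu.groupby("patient_id").size()

    table3 = pd.concat(
        [annual_summary(cohort, bundle, cpi, scope=s) for s in ("all_cause", "scd_related")],
        ignore_index=True,
    )
    table3.to_csv(ROOT / "table3_annual.csv", index=False)

    strata = stratified_summary(cohort, bundle, counts, cpi)
    strata.to_csv(ROOT / "strata_summary.csv", index=False)

    ffs = set(cohort.loc[cohort["plan_type"] == "FFS", "patient_id"])
    per_episode, per_setting = episode_costs(
        in_fu[in_fu["patient_id"].isin(ffs)], bundle, cpi, rules=rules
    )
    per_setting.to_csv(ROOT / "episode_setting_costs.csv", index=False)

    totals = strata_totals(cohort, bundle, counts, cpi, rules)
    dist = cost_frequency_distribution(totals[totals["patient_id"].isin(ffs)])
    dist.to_csv(ROOT / "cost_distribution.csv", index=False)

    tot = table3[table3["facility"] == "total"].set_index("scope")["mean_cost"]
    print(f"annual mean total cost (FFS): all-cause ${tot['all_cause']:,.0f}, "
          f"SCD-related ${tot['scd_related']:,.0f} "
          f"({100 * tot['scd_related'] / tot['all_cause']:.0f}% of total)")
    st = strata[strata["facility"] == "total"].set_index("stratum")
    print("mean SCD-related cost by episode stratum:")
    for s in ("0", "1", "2", "3+"):
        print(f"  {s:>2}: ${st.loc[s, 'mean_cost']:,.0f}  (n={int(st.loc[s, 'n_patients'])})")
    print("mean cost per episode by setting:")
    print(per_setting.set_index("setting")[["n_episodes", "mean_cost"]].to_string())


if __name__ == "__main__":
    main()
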