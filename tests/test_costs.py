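"""Cost analytics: CPI, SCD attribution, annual/stratified/per-episode sums."""

import numpy as np
import pandas as pd
import pytest

from vocburden.claims_model import ClaimsBundle
from vocburden.cohort import build_cohort
from vocburden.costs import (
    MissingCPIYearError,
    SCDAttributionRules,
    adjust_cost,
    annual_summary,
    cost_frequency_distribution,
    episode_costs,
    is_scd_related_medical,
    is_scd_related_pharmacy,
    load_cpi,
    patient_facility_metrics,
    stratified_summary,
)

from conftest import make_medical

CPI = load_cpi()


def test_cpi_reference_year_identity_and_multiplier():
    assert adjust_cost(100.0, 2013, CPI) == pytest.approx(100.0)
    assert adjust_cost(100.0, 2011, CPI) == pytest.approx(106.22)
    with pytest.raises(MissingCPIYearError):
        adjust_cost(1.0, 1999, CPI)


def test_cpi_linearity_within_year():
    amounts = [10.0, 25.5, 0.0, 99.99]
    assert adjust_cost(sum(amounts), 2010, CPI) == pytest.approx(
        sum(adjust_cost(a, 2010, CPI) for a in amounts)
    )


def test_scd_attribution_rules():
    med = make_medical(
        [
            ("a", "p1", "2011-01-01", "2011-01-01", ("4019", "28269"), "office"),
            ("b", "p1", "2011-01-02", "2011-01-02", ("4019",), "office"),
        ]
    )
    assert list(is_scd_related_medical(med)) == [True, False]
    med.loc[1, "is_transfusion"] = True
    assert list(is_scd_related_medical(med)) == [True, True]
    rx = pd.DataFrame(
        dict(drug_class=["hydroxyurea", "other", "opioid"])
    )
    assert list(is_scd_related_pharmacy(rx)) == [True, False, True]


def _single_patient_bundle(dx):
    patients = pd.DataFrame(
        [dict(patient_id="p1", birth_date=pd.Timestamp("1980-01-01"), sex="female",
              race="black", region="south", plan_type="FFS", death_date=pd.NaT,
              clinical_trial_flag=False)]
    )
    medical = make_medical(
        [("c1", "p1", "2013-02-01", "2013-02-03", dx, "inpatient")]
    )
    medical["paid_amount"] = 100.0
    pharmacy = pd.DataFrame(
        columns=["claim_id", "patient_id", "fill_date", "drug_class",
                 "paid_amount", "service_year"]
    )
    enrollment = pd.DataFrame(
        [dict(patient_id="p1", span_start=pd.Timestamp("2012-01-01"),
              span_end=pd.Timestamp("2013-12-31"), medical_coverage=True,
              pharmacy_coverage=True)]
    )
    return ClaimsBundle(patients, medical, pharmacy, enrollment)


def _cohort_frame():
    return pd.DataFrame(
        [dict(patient_id="p1", index_date=pd.Timestamp("2013-01-15"),
              followup_start=pd.Timestamp("2013-01-15"),
              followup_end=pd.Timestamp("2014-01-13"), plan_type="FFS")]
    )


def test_single_patient_identity():
    bundle = _single_patient_bundle(("28262",))
    cohort = _cohort_frame()
    for scope in ("all_cause", "scd_related"):
        summary = annual_summary(cohort, bundle, {2013: 1.0, 2014: 1.0}, scope=scope)
        ip = summary[summary["facility"] == "inpatient"].iloc[0]
        assert ip["pct_with_visit"] == 100.0
        assert ip["mean_cost"] == pytest.approx(100.0)
        assert ip["median_cost"] == pytest.approx(100.0)
        assert ip["mean_los"] == pytest.approx(3.0)


def test_scope_split_for_non_scd_claim():
    bundle = _single_patient_bundle(("4019",))
    cohort = _cohort_frame()
    cpi = {2013: 1.0, 2014: 1.0}
    ac = annual_summary(cohort, bundle, cpi, scope="all_cause")
    scd = annual_summary(cohort, bundle, cpi, scope="scd_related")
    assert ac[ac["facility"] == "inpatient"]["mean_cost"].iloc[0] == pytest.approx(100.0)
    assert scd[scd["facility"] == "inpatient"]["mean_cost"].iloc[0] == pytest.approx(0.0)


def test_empty_cohort_marks_zero_population(stress):
    bundle, _ = stress
    empty = _cohort_frame().iloc[0:0]
    summary = annual_summary(empty, bundle, CPI)
    assert (summary["n_utilization"] == 0).all()
    assert summary["mean_cost"].isna().all()


# ---------------------------------------------------------------------------
# Hand-summed ledgers on the stress fixture (CPI 2011=1.0622, 2012=1.0246)


@pytest.fixture(scope="module")
def stress_cohort(stress):
    bundle, _ = stress
    cohort, _ = build_cohort(bundle)
    return bundle, cohort


def test_stress_fixture_total_costs_match_hand_ledger(stress_cohort):
    bundle, cohort = stress_cohort
    summary = annual_summary(cohort, bundle, CPI, scope="all_cause")
    total = summary[summary["facility"] == "total"].iloc[0]
    # per-FFS-patient all-cause follow-up totals, adjusted to 2013 USD:
    # SF01 5650*1.0622=6001.43; SF02 400*1.0622=424.88;
    # SF10 1030*1.0622=1094.07; SF11 100*1.0622+250*1.0246=362.37;
    # SF12 100*1.0622=106.22
    expected = [6001.43, 424.88, 1094.066, 362.37, 106.22]
    assert total["n_costing"] == 5  # SF09 is managed care
    assert total["mean_cost"] == pytest.approx(np.mean(expected), abs=0.01)
    assert total["median_cost"] == pytest.approx(424.88, abs=0.01)


def test_stress_fixture_scd_related_excludes_non_scd_claim(stress_cohort):
    bundle, cohort = stress_cohort
    summary = annual_summary(cohort, bundle, CPI, scope="scd_related")
    total = summary[summary["facility"] == "total"].iloc[0]
    # SF02's 300 office claim (dx 789.00) drops out of the SCD scope
    expected = [6001.43, 106.22, 1094.066, 362.37, 106.22]
    assert total["mean_cost"] == pytest.approx(np.mean(expected), abs=0.01)


def test_stress_fixture_inpatient_row(stress_cohort):
    bundle, cohort = stress_cohort
    summary = annual_summary(cohort, bundle, CPI, scope="all_cause")
    ip = summary[summary["facility"] == "inpatient"].iloc[0]
    assert ip["pct_with_visit"] == pytest.approx(100.0 / 6)  # SF01 of 6
    assert ip["mean_cost"] == pytest.approx(5000 * 1.0622 / 5, abs=0.01)
    assert ip["median_cost"] == 0.0


def test_containment_scd_within_all_cause(small_synth):
    bundle, _ = small_synth
    cohort, _ = build_cohort(bundle)
    ac = patient_facility_metrics(cohort, bundle, CPI, scope="all_cause")
    scd = patient_facility_metrics(cohort, bundle, CPI, scope="scd_related")
    key = ["patient_id", "facility"]
    merged = ac.merge(scd, on=key, suffixes=("_ac", "_scd"))
    assert (merged["cost_adj_scd"] <= merged["cost_adj_ac"] + 1e-9).all()
    assert ((merged["visits_scd"] > 0) <= (merged["visits_ac"] > 0)).all()


def test_total_row_equals_component_sum(small_synth):
    bundle, _ = small_synth
    cohort, _ = build_cohort(bundle)
    from vocburden.costs import TOTAL_COST_FACILITIES

    metrics = patient_facility_metrics(cohort, bundle, CPI, scope="all_cause")
    ffs = set(cohort.loc[cohort["plan_type"] == "FFS", "patient_id"])
    comp = metrics[
        metrics["patient_id"].isin(ffs)
        & metrics["facility"].isin(TOTAL_COST_FACILITIES)
    ]
    per_patient = comp.groupby("patient_id")["cost_adj"].sum()
    summary = annual_summary(cohort, bundle, CPI, scope="all_cause")
    total = summary[summary["facility"] == "total"].iloc[0]
    assert total["mean_cost"] == pytest.approx(per_patient.mean())
    assert total["median_cost"] == pytest.approx(per_patient.median())


def test_strata_partition_cohort(small_synth):
    bundle, truth = small_synth
    cohort, _ = build_cohort(bundle)
    fu = truth[truth["phase"] == "followup"].groupby("patient_id").size()
    summary = stratified_summary(cohort, bundle, fu, CPI)
    sizes = summary.drop_duplicates("stratum").set_index("stratum")["n_patients"]
    assert sizes.sum() == len(cohort)


# ---------------------------------------------------------------------------
# Per-episode costs


def _episode_frame(pid, start, end, setting="er"):
    return pd.DataFrame(
        [dict(episode_id=f"{pid}-E1", patient_id=pid, start=pd.Timestamp(start),
              end=pd.Timestamp(end), duration_days=(pd.Timestamp(end) - pd.Timestamp(start)).days + 1,
              setting=setting, n_claims=1)]
    )


def test_episode_cost_contents(stress):
    bundle, _ = stress
    # SF01's merged inpatient episode spans 2011-07-01..07-04
    eps = _episode_frame("SF01", "2011-07-01", "2011-07-04", setting="inpatient")
    per_episode, summary = episode_costs(eps, bundle, CPI)
    # member inpatient claim 5000 + ER claim 400, both 2011
    assert per_episode["medical_cost"].iloc[0] == pytest.approx(5400 * 1.0622, abs=0.01)
    assert per_episode["scd_pharmacy_cost"].iloc[0] == 0.0
    assert per_episode["total"].iloc[0] == pytest.approx(5400 * 1.0622, abs=0.01)
    row = summary[summary["setting"] == "inpatient"].iloc[0]
    assert row["n_episodes"] == 1 and row["mean_duration_days"] == 4


def test_non_scd_medical_inside_window_included_pharmacy_filtered(stress):
    bundle, _ = stress
    bundle = bundle.copy()
    # add one non-SCD medical claim and two fills inside SF01's episode window
    extra_med = make_medical(
        [("X1", "SF01", "2011-07-02", "2011-07-02", ("4019",), "lab")]
    )
    extra_med["paid_amount"] = 77.0
    bundle.medical = pd.concat([bundle.medical, extra_med], ignore_index=True)
    fills = pd.DataFrame(
        [
            dict(claim_id="RX1", patient_id="SF01", fill_date=pd.Timestamp("2011-07-02"),
                 drug_class="opioid", paid_amount=30.0, service_year=2011),
            dict(claim_id="RX2", patient_id="SF01", fill_date=pd.Timestamp("2011-07-02"),
                 drug_class="other", paid_amount=999.0, service_year=2011),
        ]
    )
    bundle.pharmacy = pd.concat([bundle.pharmacy, fills], ignore_index=True)
    eps = _episode_frame("SF01", "2011-07-01", "2011-07-04", setting="inpatient")
    per_episode, _ = episode_costs(eps, bundle, CPI)
    assert per_episode["medical_cost"].iloc[0] == pytest.approx(
        (5400 + 77) * 1.0622, abs=0.01
    )
    # only the SCD-class fill counts
    assert per_episode["scd_pharmacy_cost"].iloc[0] == pytest.approx(30 * 1.0622, abs=0.01)


def test_claim_attribution_is_a_partition_across_disjoint_episodes(small_synth):
    bundle, _ = small_synth
    from vocburden.episodes import build_episode_table

    table = build_episode_table(bundle.medical, gap_days=3)
    # episode windows within a patient never overlap post-merge
    for _, grp in table.groupby("patient_id"):
        grp = grp.sort_values("start")
        assert (grp["start"].shift(-1) > grp["end"]).iloc[:-1].all()


# ---------------------------------------------------------------------------
# Cost frequency distribution


def test_distribution_basics():
    totals = pd.DataFrame(
        dict(patient_id=["a", "b", "c", "d"], stratum=["1"] * 4,
             total=[10.0, 20.0, 30.0, 0.0])
    )
    dist = cost_frequency_distribution(totals, bin_width=100.0)
    assert dist["n_patients"].sum() == 3      # the zero-total patient drops
    assert dist["stratum_max"].iloc[0] == 30.0
    assert dist["stratum_n"].iloc[0] == 3
    empty = cost_frequency_distribution(totals[totals["total"] == 0])
    assert empty.empty


def test_distribution_matches_numpy_histogram():
    rng = np.random.default_rng(0)
    vals = rng.lognormal(8, 1, 500)
    totals = pd.DataFrame(
        dict(patient_id=[f"p{i}" for i in range(500)], stratum=["3+"] * 500, total=vals)
    )
    width = 5000.0
    dist = cost_frequency_distribution(totals, bin_width=width)
    edges = np.arange(0, vals.max() + 2 * width, width)
    expected, _ = np.histogram(vals, bins=edges)
    got = np.zeros(len(edges) - 1, dtype=int)
    for row in dist.itertuples(index=False):
        got[int(row.bin_low // width)] = row.n_patients
    assert (got == expected).all()
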