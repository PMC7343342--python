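"""Cohort eligibility: index date, age, continuous enrollment, exclusions.

The study design is a retrospective claims cohort: the index date is the
first claim carrying a sickle cell disease (SCD) diagnosis in any position
during the identification period; eligible adults must then show
continuous enrollment with both medical and pharmacy coverage for the
6-month baseline before the index date and a full year of follow-up after
it, and must not be flagged as clinical-trial participants.

Conventions:

* "6-month baseline" means six *calendar* months back from the index date
  (same day-of-month, clamped at month end), not a fixed 180 days; the
  baseline window is [index - 6 months, index - 1 day].
* The follow-up window is the fixed year [index, index + 364 days].
* "Continuous" enrollment tolerates ``allowable_gap_days`` total uncovered
  days over baseline+follow-up; the default 0 is strict, but claims
  studies commonly tolerate 30- or 45-day gaps, so it is a parameter.
* Follow-up observation ends at the earliest of death, study end and
  index + 364 days; death truncates follow-up but does not remove the
  patient.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .claims_model import ClaimsBundle, SCD_DX_CODES, normalize_enrollment

__all__ = ["StudyWindows", "find_index_date", "has_continuous_enrollment", "build_cohort"]


@dataclasses.dataclass(frozen=True)
class StudyWindows:
    """Calendar anchors of the study design."""

    id_period_start: pd.Timestamp = pd.Timestamp("2009-07-01")
    id_period_end: pd.Timestamp = pd.Timestamp("2012-12-31")
    baseline_months: int = 6
    followup_days: int = 365
    study_end: pd.Timestamp = pd.Timestamp("2013-12-31")

    def __post_init__(self) -> None:
        if self.baseline_months <= 0 or self.followup_days <= 0:
            raise ValueError("baseline_months and followup_days must be positive")
        if self.id_period_end < self.id_period_start:
            raise ValueError("identification period is empty")

    def baseline_window(self, index_date: pd.Timestamp) -> tuple[pd.Timestamp, pd.Timestamp]:
        start = index_date - pd.DateOffset(months=self.baseline_months)
        return pd.Timestamp(start), index_date - pd.Timedelta(days=1)

    def followup_window(self, index_date: pd.Timestamp) -> tuple[pd.Timestamp, pd.Timestamp]:
        return index_date, index_date + pd.Timedelta(days=self.followup_days - 1)


def find_index_date(
    medical: pd.DataFrame, windows: StudyWindows
) -> pd.Timestamp | None:
    """Earliest SCD-coded claim date in the identification period, or None.

    ``medical`` must hold a single patient's claims; an SCD code in *any*
    diagnosis position qualifies.
    """
    if medical.empty:
        return None
    mask = [
        bool(SCD_DX_CODES.intersection(codes)) for codes in medical["dx_codes"]
    ]
    dates = medical.loc[mask, "service_start"]
    dates = dates[(dates >= windows.id_period_start) & (dates <= windows.id_period_end)]
    if dates.empty:
        return None
    return dates.min()


def _covered_days(
    spans: pd.DataFrame, lo: pd.Timestamp, hi: pd.Timestamp
) -> int:
    """Days of [lo, hi] covered by normalized, non-overlapping spans."""
    total = 0
    for start, end in zip(spans["span_start"], spans["span_end"]):
        s, e = max(start, lo), min(end, hi)
        if s <= e:
            total += int((e - s).days) + 1
    return total


def has_continuous_enrollment(
    spans: pd.DataFrame,
    index_date: pd.Timestamp,
    windows: StudyWindows,
    *,
    allowable_gap_days: int = 0,
) -> bool:
    """True iff baseline+follow-up is covered with both benefit flags.

    Coverage is assessed over the closed window
    [index - baseline_months, index + followup_days - 1] using only spans
    with both medical and pharmacy coverage; at most
    ``allowable_gap_days`` total uncovered days are tolerated.
    """
    lo, _ = windows.baseline_window(index_date)
    _, hi = windows.followup_window(index_date)
    both = spans[spans["medical_coverage"] & spans["pharmacy_coverage"]]
    both = normalize_enrollment(both)
    window_days = int((hi - lo).days) + 1
    return window_days - _covered_days(both, lo, hi) <= allowable_gap_days


_ATTRITION_LABELS = (
    "Patients in source data",
    "SCD diagnosis during identification period (index date assigned)",
    "Aged >=18 years at index date",
    "Continuous medical+pharmacy enrollment over baseline and follow-up",
    "Not enrolled in a clinical trial",
)


def build_cohort(
    bundle: ClaimsBundle,
    windows: StudyWindows | None = None,
    *,
    allowable_gap_days: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply the eligibility cascade and return (cohort, attrition).

    Criteria are applied in order: SCD index date exists -> age >= 18 at
    index -> continuous enrollment -> no clinical-trial flag.  The
    attrition table records patients remaining after each step; its final
    count equals the cohort size.  Eligibility is a pure per-patient
    function, so input row order never matters.

    Cohort columns: patient_id, index_date, baseline_start, baseline_end,
    followup_start, followup_end, followup_end_actual, age_at_index,
    plan_type.
    """
    windows = windows or StudyWindows()
    patients = bundle.patients.sort_values("patient_id").reset_index(drop=True)
    enrollment = normalize_enrollment(bundle.enrollment)
    medical_by_pid = {
        pid: grp for pid, grp in bundle.medical.groupby("patient_id", sort=False)
    }
    spans_by_pid = {
        pid: grp for pid, grp in enrollment.groupby("patient_id", sort=False)
    }
    empty_medical = bundle.medical.iloc[0:0]
    empty_spans = enrollment.iloc[0:0]

    counts = [len(patients)]
    # step 1: index date
    index_dates = {}
    for pid in patients["patient_id"]:
        idx = find_index_date(medical_by_pid.get(pid, empty_medical), windows)
        if idx is not None:
            index_dates[pid] = idx
    step1 = patients[patients["patient_id"].isin(index_dates)].copy()
    counts.append(len(step1))

    # step 2: age >= 18 at index
    step1["index_date"] = step1["patient_id"].map(index_dates)
    ages = [
        _age_at(idx, born)
        for idx, born in zip(step1["index_date"], step1["birth_date"])
    ]
    step1["age_at_index"] = ages
    step2 = step1[step1["age_at_index"] >= 18].copy()
    counts.append(len(step2))

    # step 3: continuous enrollment
    keep = [
        has_continuous_enrollment(
            spans_by_pid.get(pid, empty_spans),
            idx,
            windows,
            allowable_gap_days=allowable_gap_days,
        )
        for pid, idx in zip(step2["patient_id"], step2["index_date"])
    ]
    step3 = step2[np.asarray(keep, dtype=bool)].copy()
    counts.append(len(step3))

    # step 4: clinical-trial exclusion
    cohort = step3[~step3["clinical_trial_flag"]].copy()
    counts.append(len(cohort))

    baseline = [windows.baseline_window(d) for d in cohort["index_date"]]
    followup = [windows.followup_window(d) for d in cohort["index_date"]]
    cohort["baseline_start"] = [b[0] for b in baseline]
    cohort["baseline_end"] = [b[1] for b in baseline]
    cohort["followup_start"] = [f[0] for f in followup]
    cohort["followup_end"] = [f[1] for f in followup]
    ends = []
    for fu_end, death in zip(cohort["followup_end"], cohort["death_date"]):
        end = min(fu_end, windows.study_end)
        if pd.notna(death):
            end = min(end, death)
        ends.append(end)
    cohort["followup_end_actual"] = ends
    cohort = cohort[
        [
            "patient_id",
            "index_date",
            "baseline_start",
            "baseline_end",
            "followup_start",
            "followup_end",
            "followup_end_actual",
            "age_at_index",
            "plan_type",
        ]
    ].reset_index(drop=True)

    attrition = pd.DataFrame(
        {"criterion": _ATTRITION_LABELS, "patients_remaining": counts}
    )
    return cohort, attrition


def _age_at(when: pd.Timestamp, birth: pd.Timestamp) -> int:
    years = when.year - birth.year
    if (when.month, when.day) < (birth.month, birth.day):
        years -= 1
    return years
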