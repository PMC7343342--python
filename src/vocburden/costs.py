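"""Utilization and cost analytics: CPI adjustment, SCD attribution,
annual facility-type summaries, episode-count strata and per-episode costs.

Costs are restated in 2013 US dollars with multipliers derived from the
medical-care component of the Consumer Price Index (shipped as an
editable data file).  A claim is SCD-related if it carries a sickle cell
diagnosis in any position, is a transfusion procedure, or (for pharmacy)
belongs to a configured SCD treatment drug class.

Utilization conventions (claim-line vs visit granularity is not a
property of the input data, so it is fixed here):

* a "visit" is one facility type per service-start day per patient,
  de-duplicated, except inpatient, where distinct admissions are counted
  by merging overlapping/abutting inpatient claim date spans and length
  of stay is the summed inclusive span days;
* claims are attributed to analysis windows by service-start date;
* cost summaries include zero-cost patients (many published medians are
  US$0 for exactly this reason), except the cost frequency distribution,
  which drops zero-total patients whose costs may simply be uncaptured.

Cost amounts are only recorded for fee-for-service (FFS) enrollees in
MAX-style data, so cost statistics default to the FFS subpopulation while
utilization covers the full cohort.
"""

from __future__ import annotations

import dataclasses
from importlib import resources
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .claims_model import ClaimsBundle, FACILITY_TYPES, SCD_DX_CODES
from .episodes import STRATA, pos_to_facility

__all__ = [
    "load_cpi",
    "adjust_cost",
    "SCDAttributionRules",
    "is_scd_related_medical",
    "is_scd_related_pharmacy",
    "patient_facility_metrics",
    "annual_summary",
    "stratified_summary",
    "episode_costs",
    "cost_frequency_distribution",
    "TOTAL_COST_FACILITIES",
]

#: Facility types whose costs enter the "total" row
#: (inpatient + all outpatient categories + long-term care + pharmacy).
TOTAL_COST_FACILITIES = (
    "inpatient",
    "outpatient_hospital",
    "outpatient_er",
    "outpatient_office",
    "outpatient_other",
    "long_term_care",
    "pharmacy",
)

DEFAULT_SCD_DRUG_CLASSES = frozenset(
    {"opioid", "nsaid", "hydroxyurea", "antibiotic", "acetaminophen", "folic_acid"}
)


class MissingCPIYearError(KeyError):
    pass


def load_cpi(path: str | Path | None = None) -> dict[int, float]:
    """Load service-year -> multiplier-to-reference-year factors."""
    source = (
        Path(path)
        if path
        else resources.files("vocburden.data").joinpath("cpi_medical.yaml")
    )
    raw = yaml.safe_load(source.read_text())
    factors = {int(y): float(m) for y, m in raw["factors"].items()}
    ref = int(raw["reference_year"])
    if abs(factors.get(ref, 0.0) - 1.0) > 1e-9:
        raise ValueError("reference-year multiplier must be 1.0")
    if any(m <= 0 for m in factors.values()):
        raise ValueError("CPI multipliers must be positive")
    return factors


def adjust_cost(amount: float, service_year: int, cpi: Mapping[int, float]) -> float:
    """Restate ``amount`` (service-year USD) in reference-year USD."""
    try:
        return amount * cpi[service_year]
    except KeyError:
        raise MissingCPIYearError(
            f"no CPI multiplier for service year {service_year}"
        ) from None


def _adjust_series(amounts: pd.Series, years: pd.Series, cpi: Mapping[int, float]) -> pd.Series:
    missing = sorted(set(years) - set(cpi))
    if missing:
        raise MissingCPIYearError(f"no CPI multiplier for service year(s) {missing}")
    return amounts.astype(float) * years.map(cpi).astype(float)


@dataclasses.dataclass(frozen=True)
class SCDAttributionRules:
    """What makes a claim SCD-related."""

    scd_dx_codes: frozenset[str] = SCD_DX_CODES
    scd_drug_classes: frozenset[str] = DEFAULT_SCD_DRUG_CLASSES
    transfusion_is_scd: bool = True

    def __post_init__(self) -> None:
        if not self.scd_dx_codes:
            raise ValueError("scd_dx_codes must be non-empty")


def is_scd_related_medical(
    medical: pd.DataFrame, rules: SCDAttributionRules | None = None
) -> pd.Series:
    rules = rules or SCDAttributionRules()
    dx_hit = pd.Series(
        [bool(rules.scd_dx_codes.intersection(c)) for c in medical["dx_codes"]],
        index=medical.index,
        dtype=bool,
    )
    if rules.transfusion_is_scd:
        dx_hit |= medical["is_transfusion"].astype(bool)
    return dx_hit


def is_scd_related_pharmacy(
    pharmacy: pd.DataFrame, rules: SCDAttributionRules | None = None
) -> pd.Series:
    rules = rules or SCDAttributionRules()
    return pharmacy["drug_class"].isin(rules.scd_drug_classes)


# ---------------------------------------------------------------------------
# Per-patient annual metrics

def _merge_spans(starts: list, ends: list) -> list[tuple]:
    order = sorted(range(len(starts)), key=lambda i: (starts[i], ends[i]))
    merged: list[list] = []
    one = pd.Timedelta(days=1)
    for i in order:
        if merged and starts[i] <= merged[-1][1] + one:
            merged[-1][1] = max(merged[-1][1], ends[i])
        else:
            merged.append([starts[i], ends[i]])
    return [tuple(m) for m in merged]


def patient_facility_metrics(
    cohort: pd.DataFrame,
    bundle: ClaimsBundle,
    cpi: Mapping[int, float],
    *,
    scope: str = "all_cause",
    rules: SCDAttributionRules | None = None,
) -> pd.DataFrame:
    """Per (patient, facility) follow-up-year visits, LOS and adjusted cost.

    Every cohort member contributes a row for every facility type (zeros
    included), which keeps downstream means/medians honest about
    non-users.  ``scope`` is "all_cause" or "scd_related".
    """
    if scope not in ("all_cause", "scd_related"):
        raise ValueError(f"unknown scope {scope!r}")
    rules = rules or SCDAttributionRules()
    windows = cohort.set_index("patient_id")[["followup_start", "followup_end"]]

    med = bundle.medical[bundle.medical["patient_id"].isin(windows.index)].copy()
    if not med.empty:
        med = med.join(windows, on="patient_id")
        med = med[
            (med["service_start"] >= med["followup_start"])
            & (med["service_start"] <= med["followup_end"])
        ].copy()
    if not med.empty:
        if scope == "scd_related":
            med = med[is_scd_related_medical(med, rules)].copy()
    if not med.empty:
        med["facility"] = med["pos_code"].map(pos_to_facility)
        med["cost_adj"] = _adjust_series(med["paid_amount"], med["service_year"], cpi)

    rx = bundle.pharmacy[bundle.pharmacy["patient_id"].isin(windows.index)].copy()
    if not rx.empty:
        rx = rx.join(windows, on="patient_id")
        rx = rx[
            (rx["fill_date"] >= rx["followup_start"])
            & (rx["fill_date"] <= rx["followup_end"])
        ].copy()
    if not rx.empty and scope == "scd_related":
        rx = rx[is_scd_related_pharmacy(rx, rules)].copy()
    if not rx.empty:
        rx["cost_adj"] = _adjust_series(rx["paid_amount"], rx["service_year"], cpi)

    index = pd.MultiIndex.from_product(
        [cohort["patient_id"], FACILITY_TYPES], names=["patient_id", "facility"]
    )
    out = pd.DataFrame(
        {"visits": 0, "los_days": 0, "cost_adj": 0.0}, index=index
    )

    if not med.empty:
        costs = med.groupby(["patient_id", "facility"])["cost_adj"].sum()
        out.loc[costs.index, "cost_adj"] = costs

        non_ip = med[med["facility"] != "inpatient"]
        if not non_ip.empty:
            visits = (
                non_ip.drop_duplicates(["patient_id", "facility", "service_start"])
                .groupby(["patient_id", "facility"])
                .size()
            )
            out.loc[visits.index, "visits"] = visits

        ip = med[med["facility"] == "inpatient"]
        for pid, grp in ip.groupby("patient_id"):
            stays = _merge_spans(list(grp["service_start"]), list(grp["service_end"]))
            los = sum(int((e - s).days) + 1 for s, e in stays)
            out.loc[(pid, "inpatient"), "visits"] = len(stays)
            out.loc[(pid, "inpatient"), "los_days"] = los

    if not rx.empty:
        fills = (
            rx.drop_duplicates(["patient_id", "fill_date"]).groupby("patient_id").size()
        )
        rx_cost = rx.groupby("patient_id")["cost_adj"].sum()
        for pid, n in fills.items():
            out.loc[(pid, "pharmacy"), "visits"] = n
        for pid, c in rx_cost.items():
            out.loc[(pid, "pharmacy"), "cost_adj"] = c

    return out.reset_index()


def _facility_rows(
    metrics: pd.DataFrame, cost_metrics: pd.DataFrame, n_util: int, n_cost: int
) -> pd.DataFrame:
    rows = []
    for facility in FACILITY_TYPES:
        m = metrics[metrics["facility"] == facility]
        c = cost_metrics[cost_metrics["facility"] == facility]
        row = dict(
            facility=facility,
            pct_with_visit=100.0 * (m["visits"] > 0).sum() / n_util if n_util else np.nan,
            mean_visits=m["visits"].mean() if n_util else np.nan,
            sd_visits=m["visits"].std(ddof=1) if n_util > 1 else np.nan,
            mean_cost=c["cost_adj"].mean() if n_cost else np.nan,
            median_cost=c["cost_adj"].median() if n_cost else np.nan,
            sd_cost=c["cost_adj"].std(ddof=1) if n_cost > 1 else np.nan,
        )
        if facility == "inpatient":
            row["mean_los"] = m["los_days"].mean() if n_util else np.nan
            row["sd_los"] = m["los_days"].std(ddof=1) if n_util > 1 else np.nan
        else:
            row["mean_los"] = np.nan
            row["sd_los"] = np.nan
        rows.append(row)
    # total cost row over the facilities that enter the published total
    tot = (
        cost_metrics[cost_metrics["facility"].isin(TOTAL_COST_FACILITIES)]
        .groupby("patient_id")["cost_adj"]
        .sum()
    )
    if n_cost:
        tot = tot.reindex(cost_metrics["patient_id"].unique(), fill_value=0.0)
    rows.append(
        dict(
            facility="total",
            pct_with_visit=np.nan,
            mean_visits=np.nan,
            sd_visits=np.nan,
            mean_cost=tot.mean() if n_cost else np.nan,
            median_cost=tot.median() if n_cost else np.nan,
            sd_cost=tot.std(ddof=1) if n_cost > 1 else np.nan,
            mean_los=np.nan,
            sd_los=np.nan,
        )
    )
    return pd.DataFrame(rows)


def annual_summary(
    cohort: pd.DataFrame,
    bundle: ClaimsBundle,
    cpi: Mapping[int, float],
    *,
    scope: str = "all_cause",
    costing_population: str = "FFS_only",
    rules: SCDAttributionRules | None = None,
) -> pd.DataFrame:
    """Follow-up-year utilization and costs by facility type, plus total.

    Utilization covers the whole cohort; cost statistics cover the
    ``costing_population`` ("FFS_only" by default, since managed-care
    amounts are not recorded) with zero-cost members contributing zeros.
    An empty cohort yields an all-NaN table carrying n_utilization = 0.
    """
    if costing_population not in ("FFS_only", "all"):
        raise ValueError(f"unknown costing_population {costing_population!r}")
    metrics = patient_facility_metrics(cohort, bundle, cpi, scope=scope, rules=rules)
    if costing_population == "FFS_only":
        cost_cohort = cohort[cohort["plan_type"] == "FFS"]
    else:
        cost_cohort = cohort
    cost_metrics = metrics[metrics["patient_id"].isin(cost_cohort["patient_id"])]
    out = _facility_rows(metrics, cost_metrics, len(cohort), len(cost_cohort))
    out.insert(0, "scope", scope)
    out["n_utilization"] = len(cohort)
    out["n_costing"] = len(cost_cohort)
    return out


def stratified_summary(
    cohort: pd.DataFrame,
    bundle: ClaimsBundle,
    episode_counts: pd.Series,
    cpi: Mapping[int, float],
    *,
    rules: SCDAttributionRules | None = None,
) -> pd.DataFrame:
    """SCD-related utilization/costs per episode-count stratum (0/1/2/3+).

    ``episode_counts`` maps patient_id -> follow-up episode count; cohort
    members absent from it count zero episodes.  Strata partition the
    cohort, so per-stratum n sums to the cohort size.
    """
    counts = (
        episode_counts.reindex(cohort["patient_id"]).fillna(0).astype(int)
    )
    strata = counts.map(lambda c: str(c) if c < 3 else "3+")
    strata.index = cohort["patient_id"]
    frames = []
    for stratum in STRATA:
        members = strata.index[strata == stratum]
        sub = cohort[cohort["patient_id"].isin(members)]
        summary = annual_summary(
            sub, bundle, cpi, scope="scd_related", rules=rules
        )
        summary.insert(0, "stratum", stratum)
        summary["n_patients"] = len(sub)
        frames.append(summary)
    return pd.concat(frames, ignore_index=True)


def episode_costs(
    episodes: pd.DataFrame,
    bundle: ClaimsBundle,
    cpi: Mapping[int, float],
    *,
    rules: SCDAttributionRules | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Cost of each VOC episode and the per-setting mean/SD table.

    Per episode: ``medical_cost`` sums *all* medical claims (any setting,
    any diagnosis) whose service start falls inside the episode window —
    care during a crisis is attributed to the crisis — plus
    ``scd_pharmacy_cost``, SCD-class fills in-window.  The caller is
    responsible for passing episodes of the costing (FFS) population
    only.  The summary table has one row per setting plus "all".
    """
    rules = rules or SCDAttributionRules()
    med_by_pid = dict(tuple(bundle.medical.groupby("patient_id", sort=False)))
    rx = bundle.pharmacy
    rx_scd = rx[is_scd_related_pharmacy(rx, rules)] if not rx.empty else rx
    rx_by_pid = dict(tuple(rx_scd.groupby("patient_id", sort=False)))
    empty_med = bundle.medical.iloc[0:0]
    empty_rx = bundle.pharmacy.iloc[0:0]

    rows = []
    for ep in episodes.itertuples(index=False):
        med = med_by_pid.get(ep.patient_id, empty_med)
        in_win = med[
            (med["service_start"] >= ep.start) & (med["service_start"] <= ep.end)
        ]
        med_cost = float(
            _adjust_series(in_win["paid_amount"], in_win["service_year"], cpi).sum()
        )
        fills = rx_by_pid.get(ep.patient_id, empty_rx)
        fills = fills[(fills["fill_date"] >= ep.start) & (fills["fill_date"] <= ep.end)]
        rx_cost = float(
            _adjust_series(fills["paid_amount"], fills["service_year"], cpi).sum()
        )
        rows.append(
            dict(
                episode_id=ep.episode_id,
                patient_id=ep.patient_id,
                setting=ep.setting,
                medical_cost=med_cost,
                scd_pharmacy_cost=rx_cost,
                total=med_cost + rx_cost,
            )
        )
    per_episode = pd.DataFrame(
        rows,
        columns=[
            "episode_id",
            "patient_id",
            "setting",
            "medical_cost",
            "scd_pharmacy_cost",
            "total",
        ],
    )
    summary_rows = []
    groups = [("all", per_episode)] + [
        (s, per_episode[per_episode["setting"] == s])
        for s in ("inpatient", "er", "outpatient", "office", "other")
    ]
    for name, grp in groups:
        summary_rows.append(
            dict(
                setting=name,
                n_episodes=len(grp),
                mean_cost=grp["total"].mean() if len(grp) else np.nan,
                sd_cost=grp["total"].std(ddof=1) if len(grp) > 1 else np.nan,
                mean_duration_days=np.nan,
            )
        )
    summary = pd.DataFrame(summary_rows)
    if len(per_episode) and "duration_days" in episodes.columns:
        dur = episodes.set_index("episode_id")["duration_days"]
        per_set = per_episode.join(dur, on="episode_id")
        for i, (name, _) in enumerate(groups):
            sel = per_set if name == "all" else per_set[per_set["setting"] == name]
            if len(sel):
                summary.loc[i, "mean_duration_days"] = sel["duration_days"].mean()
    return per_episode, summary


def cost_frequency_distribution(
    totals: pd.DataFrame, *, bin_width: float = 10_000.0
) -> pd.DataFrame:
    """Binned distribution of per-patient totals per stratum, zeros dropped.

    ``totals`` needs columns patient_id, stratum, total.  Patients with a
    US$0 total are excluded (their costs may simply be uncaptured).
    Returns one row per (stratum, bin) with the count, plus per-stratum n
    and max columns.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    nz = totals[totals["total"] > 0]
    rows = []
    for stratum in STRATA:
        grp = nz[nz["stratum"] == stratum]
        if grp.empty:
            continue
        idx = np.floor(grp["total"] / bin_width).astype(int)
        counts = idx.value_counts().sort_index()
        for b, n in counts.items():
            rows.append(
                dict(
                    stratum=stratum,
                    bin_low=b * bin_width,
                    bin_high=(b + 1) * bin_width,
                    n_patients=int(n),
                    stratum_n=len(grp),
                    stratum_max=float(grp["total"].max()),
                )
            )
    return pd.DataFrame(
        rows,
        columns=[
            "stratum",
            "bin_low",
            "bin_high",
            "n_patients",
            "stratum_n",
            "stratum_max",
        ],
    )
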