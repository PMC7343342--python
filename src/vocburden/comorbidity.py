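"""Baseline clinical characterization: Charlson index and condition flags.

The Charlson Comorbidity Index (CCI) is a weighted count of comorbid
condition categories.  This module ships the Deyo ICD-9-CM adaptation
with the original Charlson weights (1/2/3/6) as an editable YAML data
file; scoring is prefix matching of dotless diagnosis codes against each
condition's stems, each condition counting at most once regardless of how
many claims or diagnosis positions mention it.  Severity hierarchies
(uncomplicated vs complicated diabetes, mild vs moderate/severe liver
disease, malignancy vs metastatic tumor) score only the severe form when
both appear.

Baseline profiles aggregate, over each cohort member's baseline window:
the CCI score and band (0 / 1 / 2-3 / 4+), named comorbid-condition
flags, medication-class flags from pharmacy fills, a transfusion flag,
baseline VOC episode count and whether any baseline episode required an
inpatient stay, and per-facility any-visit utilization flags.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
import yaml

from .claims_model import ClaimsBundle, DRUG_CLASSES, FACILITY_TYPES
from .episodes import (
    SettingHierarchy,
    classify_setting,
    identify_voc_claims,
    merge_into_episodes,
    pos_to_facility,
)

__all__ = [
    "load_cci_map",
    "load_condition_map",
    "cci_score",
    "cci_band",
    "condition_flags",
    "baseline_profiles",
    "CCI_BANDS",
]

CCI_BANDS = ("0", "1", "2-3", "4+")


def _expand(spec: Mapping) -> tuple[str, ...]:
    """Expand a {prefixes, ranges} stanza into a flat prefix tuple."""
    prefixes = [str(p) for p in spec.get("prefixes", [])]
    for lo, hi in spec.get("ranges", []):
        lo, hi = str(lo), str(hi)
        if len(lo) != len(hi):
            raise ValueError(f"range endpoints {lo!r}..{hi!r} differ in width")
        width = len(lo)
        prefixes.extend(str(v).zfill(width) for v in range(int(lo), int(hi) + 1))
    if not prefixes:
        raise ValueError("condition stanza defines no prefixes")
    return tuple(prefixes)


def _packaged(name: str) -> Path:
    return resources.files("vocburden.data").joinpath(name)  # type: ignore[return-value]


def load_cci_map(path: str | Path | None = None) -> dict:
    """Load the CCI mapping: condition -> (prefixes, weight), + hierarchies."""
    source = Path(path) if path else _packaged("cci_map.yaml")
    raw = yaml.safe_load(source.read_text())
    conditions = {
        name: (_expand(spec), int(spec["weight"]))
        for name, spec in raw["conditions"].items()
    }
    for name, (_, weight) in conditions.items():
        if weight not in (1, 2, 3, 6):
            raise ValueError(f"condition {name!r} has weight {weight} outside {{1,2,3,6}}")
    return {
        "conditions": conditions,
        "hierarchies": [tuple(pair) for pair in raw.get("hierarchies", [])],
    }


def load_condition_map(path: str | Path | None = None) -> dict[str, tuple[str, ...]]:
    """Load the comorbid-condition flag stems: condition -> prefixes."""
    source = Path(path) if path else _packaged("condition_codes.yaml")
    raw = yaml.safe_load(source.read_text())
    return {name: _expand(spec) for name, spec in raw["conditions"].items()}


def _matches_any(code: str, prefixes: tuple[str, ...]) -> bool:
    return any(code.startswith(p) for p in prefixes)


def present_conditions(
    dx_codes: Iterable[str], cci_map: Mapping
) -> set[str]:
    """Conditions present in a diagnosis-code collection, hierarchies applied."""
    codes = set(dx_codes)
    present = {
        name
        for name, (prefixes, _) in cci_map["conditions"].items()
        if any(_matches_any(c, prefixes) for c in codes)
    }
    for mild, severe in cci_map["hierarchies"]:
        if mild in present and severe in present:
            present.discard(mild)
    return present


def cci_band(score: int) -> str:
    if score <= 0:
        return "0"
    if score == 1:
        return "1"
    if score <= 3:
        return "2-3"
    return "4+"


def cci_score(
    baseline_claims: pd.DataFrame, cci_map: Mapping | None = None
) -> tuple[int, str]:
    """Score the CCI over a (pre-windowed) claim set.

    Each condition counts once however many claims mention it; the score
    is invariant to claim order and duplication and non-decreasing under
    added diagnoses.  Returns ``(score, band)``.
    """
    cci_map = cci_map or load_cci_map()
    all_dx = [c for codes in baseline_claims.get("dx_codes", ()) for c in codes]
    present = present_conditions(all_dx, cci_map)
    score = sum(cci_map["conditions"][name][1] for name in present)
    return score, cci_band(score)


def condition_flags(
    dx_codes: Iterable[str], condition_map: Mapping[str, tuple[str, ...]]
) -> dict[str, bool]:
    codes = set(dx_codes)
    return {
        name: any(_matches_any(c, prefixes) for c in codes)
        for name, prefixes in condition_map.items()
    }


def baseline_profiles(
    bundle: ClaimsBundle,
    cohort: pd.DataFrame,
    *,
    cci_map: Mapping | None = None,
    condition_map: Mapping[str, tuple[str, ...]] | None = None,
    gap_days: int = 3,
    hierarchy: SettingHierarchy | None = None,
) -> pd.DataFrame:
    """One row of baseline characteristics per cohort member.

    All flags are computed strictly over the patient's baseline window;
    baseline VOC episodes use the same gap-merge rule as the follow-up
    analysis.
    """
    cci_map = cci_map or load_cci_map()
    condition_map = condition_map or load_condition_map()
    hierarchy = hierarchy or SettingHierarchy()
    med_by_pid = dict(tuple(bundle.medical.groupby("patient_id", sort=False)))
    rx_by_pid = dict(tuple(bundle.pharmacy.groupby("patient_id", sort=False)))
    empty_med = bundle.medical.iloc[0:0]
    empty_rx = bundle.pharmacy.iloc[0:0]
    pos_by_id = dict(zip(bundle.medical["claim_id"], bundle.medical["pos_code"]))

    rows: list[dict] = []
    for rec in cohort.itertuples(index=False):
        med = med_by_pid.get(rec.patient_id, empty_med)
        med = med[
            (med["service_start"] >= rec.baseline_start)
            & (med["service_start"] <= rec.baseline_end)
        ]
        rx = rx_by_pid.get(rec.patient_id, empty_rx)
        rx = rx[
            (rx["fill_date"] >= rec.baseline_start)
            & (rx["fill_date"] <= rec.baseline_end)
        ]
        score, band = cci_score(med, cci_map)
        all_dx = [c for codes in med["dx_codes"] for c in codes]
        flags = condition_flags(all_dx, condition_map)

        voc = identify_voc_claims(med)
        episodes = merge_into_episodes(voc, gap_days=gap_days) if not voc.empty else []
        inpatient_voc = any(
            classify_setting(ep, pos_by_id, hierarchy) == "inpatient"
            for ep in episodes
        )
        filled = set(rx["drug_class"])
        used_facilities = {pos_to_facility(p) for p in med["pos_code"]}
        if len(rx):
            used_facilities.add("pharmacy")

        row = dict(
            patient_id=rec.patient_id,
            cci_score=score,
            cci_band=band,
            baseline_voc_episode_count=len(episodes),
            baseline_voc_inpatient_flag=inpatient_voc,
            transfusion_flag=bool(med["is_transfusion"].any()),
        )
        row.update({f"cond_{k}": v for k, v in flags.items()})
        row.update({f"med_{dc}": dc in filled for dc in DRUG_CLASSES})
        row.update({f"util_{f}": f in used_facilities for f in FACILITY_TYPES})
        rows.append(row)
    if not rows:
        cols = (
            ["patient_id", "cci_score", "cci_band", "baseline_voc_episode_count",
             "baseline_voc_inpatient_flag", "transfusion_flag"]
            + [f"cond_{k}" for k in condition_map]
            + [f"med_{dc}" for dc in DRUG_CLASSES]
            + [f"util_{f}" for f in FACILITY_TYPES]
        )
        return pd.DataFrame(columns=cols)
    return pd.DataFrame(rows)
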