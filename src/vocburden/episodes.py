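"""Vaso-occlusive crisis (VOC) episode construction.

A VOC episode is a maximal cluster of VOC-coded claims in which each claim
starts at most ``gap_days`` days after the running end of the cluster.
Because one crisis is often treated in several settings over a few days
(an ER visit rolling into an admission, say), discrete claims within a
3-day gap are combined into a single episode; the gap is configurable.

Gap semantics: claims are sorted by (service_start, service_end, claim_id)
and a claim joins the open episode iff

    service_start - episode_running_end <= gap_days   (whole days)

so with the default gap of 3 a single-day claim on day 1 and one on day 4
merge, while day 1 and day 5 do not.  The episode end extends to the
maximum service_end seen.  This start-to-running-end rule is equivalent to
connected components of the interval graph with the same gap relation.

Each episode is assigned one care setting by a strict hierarchy over its
member claims' place-of-service categories:

    inpatient > ER > outpatient > office > other

where "outpatient" covers outpatient hospital, ambulatory surgery center,
nursing facility and long-term care, and "office" covers independent
clinic, federally qualified health center, state/local public health
clinic and rural health clinic.  Anything unenumerated falls to "other".
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "VOC_DX_CODES",
    "SETTINGS",
    "SettingHierarchy",
    "Episode",
    "identify_voc_claims",
    "merge_into_episodes",
    "build_episode_table",
    "classify_setting",
    "count_and_stratify",
    "STRATA",
    "pos_to_facility",
    "POS_TO_FACILITY",
]

#: ICD-9-CM codes identifying a vaso-occlusive crisis in any diagnosis
#: position (282.42, 282.62, 282.64, 282.69); a strict subset of the
#: sickle cell disease code set.
VOC_DX_CODES: frozenset[str] = frozenset({"28242", "28262", "28264", "28269"})

#: Episode settings from highest to lowest classification priority.
SETTINGS = ("inpatient", "er", "outpatient", "office", "other")

#: Episode-count strata for the follow-up year.
STRATA = ("0", "1", "2", "3+")

_DEFAULT_POS_TO_SETTING: dict[str, str] = {
    "inpatient": "inpatient",
    "outpatient_er": "er",
    "outpatient_hospital": "outpatient",
    "ambulatory_surgery_center": "outpatient",
    "nursing_facility": "outpatient",
    "long_term_care": "outpatient",
    "independent_clinic": "office",
    "fqhc": "office",
    "public_health_clinic": "office",
    "rural_health_clinic": "office",
    "office": "office",
    "lab": "other",
    "hospice": "other",
    "home": "other",
    "outpatient_other": "other",
}

#: Place-of-service category -> facility type used in annual
#: utilization/cost tables (distinct from the 5-level episode setting).
POS_TO_FACILITY: dict[str, str] = {
    "inpatient": "inpatient",
    "outpatient_hospital": "outpatient_hospital",
    "outpatient_er": "outpatient_er",
    "office": "outpatient_office",
    "independent_clinic": "outpatient_office",
    "fqhc": "outpatient_office",
    "public_health_clinic": "outpatient_office",
    "rural_health_clinic": "outpatient_office",
    "ambulatory_surgery_center": "ambulatory_surgery_center",
    "lab": "lab",
    "hospice": "hospice",
    "nursing_facility": "long_term_care",
    "long_term_care": "long_term_care",
    "home": "outpatient_other",
    "outpatient_other": "outpatient_other",
}


def pos_to_facility(pos_code: str) -> str:
    try:
        return POS_TO_FACILITY[pos_code]
    except KeyError:
        raise KeyError(f"unmapped place-of-service code {pos_code!r}") from None


@dataclasses.dataclass(frozen=True)
class SettingHierarchy:
    """Priority-ordered settings plus the place-of-service mapping."""

    priority: tuple[str, ...] = SETTINGS
    pos_to_setting: Mapping[str, str] = dataclasses.field(
        default_factory=lambda: dict(_DEFAULT_POS_TO_SETTING)
    )

    def setting_of(self, pos_code: str) -> str:
        try:
            return self.pos_to_setting[pos_code]
        except KeyError:
            raise KeyError(
                f"unmapped place-of-service code {pos_code!r}"
            ) from None

    def highest(self, settings: Iterable[str]) -> str:
        present = set(settings)
        for s in self.priority:
            if s in present:
                return s
        raise ValueError("no settings supplied")


@dataclasses.dataclass
class Episode:
    episode_id: str
    patient_id: str
    start: pd.Timestamp
    end: pd.Timestamp
    member_claim_ids: tuple[str, ...]
    setting: str | None = None

    @property
    def duration_days(self) -> int:
        return int((self.end - self.start).days) + 1

    @property
    def n_claims(self) -> int:
        return len(self.member_claim_ids)


def identify_voc_claims(
    medical: pd.DataFrame, code_set: frozenset[str] | set[str] = VOC_DX_CODES
) -> pd.DataFrame:
    """Claims carrying a VOC code in any diagnosis position, order preserved."""
    if not code_set:
        raise ValueError("VOC code set must be non-empty")
    if medical.empty:
        return medical.copy()
    code_set = frozenset(code_set)
    mask = [bool(code_set.intersection(codes)) for codes in medical["dx_codes"]]
    return medical.loc[mask].copy()


def merge_into_episodes(
    voc_claims: pd.DataFrame, gap_days: int = 3
) -> list[Episode]:
    """Merge one patient's VOC claims into episodes with the gap rule.

    Claims are processed in (service_start, service_end, claim_id) order
    for reproducible tie-breaking; a claim joins the open episode iff its
    start is within ``gap_days`` days of the episode's running end.
    """
    if gap_days < 0:
        raise ValueError("gap_days must be >= 0")
    if voc_claims.empty:
        return []
    patients = voc_claims["patient_id"].unique()
    if len(patients) != 1:
        raise ValueError(
            f"merge_into_episodes expects one patient's claims, got {len(patients)}"
        )
    pid = patients[0]
    ordered = voc_claims.sort_values(
        ["service_start", "service_end", "claim_id"], kind="stable"
    )
    episodes: list[Episode] = []
    gap = pd.Timedelta(days=gap_days)
    cur_start = cur_end = None
    cur_members: list[str] = []

    def close() -> None:
        episodes.append(
            Episode(
                episode_id=f"{pid}-E{len(episodes) + 1}",
                patient_id=pid,
                start=cur_start,
                end=cur_end,
                member_claim_ids=tuple(cur_members),
            )
        )

    for cid, start, end in zip(
        ordered["claim_id"], ordered["service_start"], ordered["service_end"]
    ):
        if cur_start is None:
            cur_start, cur_end, cur_members = start, end, [cid]
        elif start - cur_end <= gap:
            cur_end = max(cur_end, end)
            cur_members.append(cid)
        else:
            close()
            cur_start, cur_end, cur_members = start, end, [cid]
    close()
    return episodes


def classify_setting(
    episode: Episode,
    claims_by_id: Mapping[str, str],
    hierarchy: SettingHierarchy | None = None,
) -> str:
    """Assign the highest-priority setting among member claims.

    ``claims_by_id`` maps claim_id -> place-of-service category code.
    """
    hierarchy = hierarchy or SettingHierarchy()
    settings = [hierarchy.setting_of(claims_by_id[cid]) for cid in episode.member_claim_ids]
    return hierarchy.highest(settings)


def build_episode_table(
    medical: pd.DataFrame,
    *,
    gap_days: int = 3,
    code_set: frozenset[str] = VOC_DX_CODES,
    hierarchy: SettingHierarchy | None = None,
) -> pd.DataFrame:
    """Identify VOC claims for every patient and emit the episode table.

    Columns: patient_id, episode_id, start, end, duration_days, setting,
    n_claims, member_claim_ids (tuple).  Episodes are in chronological
    order within patient; patients sorted by id.
    """
    hierarchy = hierarchy or SettingHierarchy()
    voc = identify_voc_claims(medical, code_set)
    rows: list[dict] = []
    if not voc.empty:
        pos_by_id = dict(zip(medical["claim_id"], medical["pos_code"]))
        for pid, grp in voc.groupby("patient_id", sort=True):
            for ep in merge_into_episodes(grp, gap_days=gap_days):
                ep.setting = classify_setting(ep, pos_by_id, hierarchy)
                rows.append(
                    dict(
                        patient_id=pid,
                        episode_id=ep.episode_id,
                        start=ep.start,
                        end=ep.end,
                        duration_days=ep.duration_days,
                        setting=ep.setting,
                        n_claims=ep.n_claims,
                        member_claim_ids=ep.member_claim_ids,
                    )
                )
    return pd.DataFrame(
        rows,
        columns=[
            "patient_id",
            "episode_id",
            "start",
            "end",
            "duration_days",
            "setting",
            "n_claims",
            "member_claim_ids",
        ],
    )


def count_and_stratify(
    episode_starts: Sequence[pd.Timestamp],
    window: tuple[pd.Timestamp, pd.Timestamp],
) -> tuple[int, str]:
    """Count episodes starting inside the closed ``window`` and band them.

    Returns ``(count, stratum)`` with strata "0", "1", "2", "3+".
    Membership is by episode *start* date, so an episode that begins on
    the last follow-up day counts even if it runs past the window.
    """
    lo, hi = window
    count = sum(1 for s in episode_starts if lo <= s <= hi)
    stratum = str(count) if count < 3 else "3+"
    return count, stratum
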