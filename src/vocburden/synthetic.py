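"""Seedable synthetic Medicaid-style claims generator.

The generator emits the four input tables plus a ground-truth episode
table, with the statistical structure the downstream analysis assumes:

* demographics drawn from configurable marginals (two-thirds female,
  predominantly Black enrollees, four census regions, roughly half
  fee-for-service);
* one sickle-cell index claim per patient on a random day of the
  identification period, with annual vaso-occlusive crisis (VOC) episode
  counts drawn negative-binomial (claims data are strongly overdispersed,
  with a long right tail of high-frequency patients);
* each VOC episode realized as one or more VOC-coded claims whose
  consecutive start-date gaps never exceed the within-episode maximum
  (default 3 days), while distinct episodes are separated by strictly
  larger gaps — so the gap-merge episode grouper recovers the generated
  episodes, windows and hierarchy-assigned settings exactly, by
  construction;
* right-skewed lognormal claim costs with setting-dependent scale, so
  mean costs rank inpatient > ER > outpatient > office;
* background (non-SCD) medical claims, pharmacy fills, enrollment churn
  (a configurable fraction of patients lose coverage before the followup
  year completes), clinical-trial flags and rare deaths.

Episode placement is intentionally identifiability-first rather than
realistic: inter-episode spacing is drawn by distributing the leftover
follow-up days uniformly at random among gaps that are forced to exceed
the merge threshold.  All randomness flows from one
``numpy.random.default_rng`` (PCG64) stream fixed by ``seed``; dates use
integer day arithmetic, so output is reproducible across platforms.

``generate_eligibility_stress_fixture`` returns a small hand-designed
bundle with one patient violating each eligibility rule, used to
hand-verify the cohort selection cascade.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, Field, field_validator, model_validator

from .claims_model import (
    ClaimsBundle,
    DRUG_CLASSES,
    ENROLLMENT_COLUMNS,
    MEDICAL_COLUMNS,
    PATIENT_COLUMNS,
    PHARMACY_COLUMNS,
)
from .cohort import StudyWindows

__all__ = [
    "GeneratorConfig",
    "generate_dataset",
    "generate_eligibility_stress_fixture",
    "GROUND_TRUTH_COLUMNS",
]

GROUND_TRUTH_COLUMNS = (
    "patient_id",
    "episode_seq",
    "phase",
    "start",
    "end",
    "setting",
    "n_claims",
)

_SETTING_ORDER = ("inpatient", "er", "outpatient", "office", "other")

# representative place-of-service codes per episode setting; extra member
# claims draw only from equal-or-lower-priority settings so the hierarchy
# classification of the episode stays identifiable
_SETTING_POS = {
    "inpatient": ("inpatient",),
    "er": ("outpatient_er",),
    "outpatient": (
        "outpatient_hospital",
        "ambulatory_surgery_center",
        "nursing_facility",
        "long_term_care",
    ),
    "office": ("independent_clinic", "fqhc", "public_health_clinic", "rural_health_clinic"),
    "other": ("home", "outpatient_other"),
}

_VOC_CODES = ("28242", "28262", "28264", "28269")

# non-SCD diagnosis pool for background claims, weighted toward the
# baseline comorbidity flags the analysis reports
_BACKGROUND_DX = (
    "0389",    # infectious
    "0340",    # infectious (strep)
    "49390",   # asthma
    "4659",    # URI
    "78060",   # fever
    "5640",    # constipation
    "3382",    # chronic pain
    "2750",    # iron overload
    "7334",    # avascular necrosis
    "34590",   # seizures
    "2189",    # neoplasm (benign)
    "5173",    # acute chest syndrome
    "4019",    # hypertension (no flag)
    "78900",   # abdominal pain (no flag)
    "V700",    # routine exam (no flag)
)
_BACKGROUND_DX_WEIGHTS = (
    0.10, 0.05, 0.08, 0.06, 0.07, 0.04, 0.04, 0.03, 0.03, 0.03,
    0.04, 0.02, 0.13, 0.15, 0.13,
)

_BACKGROUND_POS = (
    "outpatient_hospital",
    "office",
    "independent_clinic",
    "lab",
    "outpatient_er",
    "outpatient_other",
    "home",
)
_BACKGROUND_POS_WEIGHTS = (0.30, 0.20, 0.08, 0.15, 0.12, 0.10, 0.05)

_AGE_BANDS = {"18-30": (18, 30), "31-45": (31, 45), "46-64": (46, 64), "65+": (65, 75)}


def _check_probs(name: str, probs: dict[str, float]) -> None:
    total = sum(probs.values())
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"{name} must sum to 1 (got {total!r})")
    if any(p < 0 for p in probs.values()):
        raise ValueError(f"{name} must be non-negative")


class GeneratorConfig(BaseModel):
    """All knobs of the synthetic generator, with study-shaped defaults."""

    n_patients: int = Field(ge=0, default=1000)
    seed: int = 0

    prop_female: float = 0.673
    race_probs: dict[str, float] = {
        "white": 0.063, "black": 0.740, "hispanic": 0.101,
        "other": 0.029, "unknown": 0.067,
    }
    region_probs: dict[str, float] = {
        "northeast": 0.446, "south": 0.266, "west": 0.189, "north_central": 0.099,
    }
    plan_probs: dict[str, float] = {"FFS": 0.498, "managed_care": 0.502}
    age_band_probs: dict[str, float] = {
        "18-30": 0.519, "31-45": 0.296, "46-64": 0.179, "65+": 0.006,
    }

    episode_rate_mean: float = Field(gt=0, default=2.0)
    episode_dispersion: float = Field(gt=0, default=0.35)
    claims_per_episode_mean: float = Field(ge=1.0, default=2.0)
    gap_within_episode_max_days: int = Field(ge=1, default=3)
    setting_probs: dict[str, float] = {
        "inpatient": 0.378, "er": 0.362, "outpatient": 0.182,
        "office": 0.058, "other": 0.020,
    }
    inpatient_stay_mean_days: float = Field(gt=0, default=4.5)

    # lognormal (mu, sigma) of per-claim cost in reference-year USD
    cost_lognormal_params: dict[str, tuple[float, float]] = {
        "inpatient": (8.11, 1.0),
        "er": (5.75, 1.0),
        "outpatient": (5.33, 1.0),
        "office": (4.51, 1.0),
        "other": (4.11, 1.0),
        "background": (4.60, 1.0),
        "pharmacy": (3.70, 0.8),
    }

    background_claim_rate: float = Field(ge=0, default=12.0)  # per patient-year
    pharmacy_fill_rate: float = Field(ge=0, default=10.0)  # per patient-year
    drug_class_probs: dict[str, float] = {
        "antibiotic": 0.20, "acetaminophen": 0.20, "folic_acid": 0.13,
        "opioid": 0.13, "nsaid": 0.12, "hydroxyurea": 0.05, "other": 0.17,
    }
    transfusion_prob: float = Field(ge=0, le=1, default=0.03)

    baseline_voc_prob: float = Field(ge=0, le=1, default=0.25)
    enrollment_dropout_prob: float = Field(ge=0, le=1, default=0.12)
    clinical_trial_prob: float = Field(ge=0, le=1, default=0.01)
    death_prob: float = Field(ge=0, le=1, default=0.003)

    cpi_factors: dict[int, float] = {
        2009: 1.1318, 2010: 1.0945, 2011: 1.0622, 2012: 1.0246, 2013: 1.0,
    }

    @model_validator(mode="after")
    def _validate_probs(self) -> "GeneratorConfig":
        _check_probs("race_probs", self.race_probs)
        _check_probs("region_probs", self.region_probs)
        _check_probs("plan_probs", self.plan_probs)
        _check_probs("age_band_probs", self.age_band_probs)
        _check_probs("setting_probs", self.setting_probs)
        _check_probs("drug_class_probs", self.drug_class_probs)
        if not 0 <= self.prop_female <= 1:
            raise ValueError("prop_female must be a probability")
        unknown = set(self.drug_class_probs) - set(DRUG_CLASSES)
        if unknown:
            raise ValueError(f"unknown drug classes {sorted(unknown)}")
        if set(self.setting_probs) != set(_SETTING_ORDER):
            raise ValueError("setting_probs must cover exactly the five settings")
        return self

    @classmethod
    def from_yaml(cls, path: str | Path | None = None, **overrides) -> "GeneratorConfig":
        """Load the shipped (or a custom) config file, with overrides."""
        source = (
            Path(path)
            if path
            else resources.files("vocburden.data").joinpath("generator_default.yaml")
        )
        raw = yaml.safe_load(source.read_text()) or {}
        raw.pop("version", None)
        raw.update(overrides)
        return cls(**raw)


def _choice(rng: np.random.Generator, items, probs) -> str:
    return items[rng.choice(len(items), p=np.asarray(probs) / np.sum(probs))]


def _lognormal_cost(rng: np.random.Generator, params: tuple[float, float]) -> float:
    mu, sigma = params
    return float(np.round(rng.lognormal(mu, sigma), 2))


def _nominal(amount_ref: float, year: int, cpi: dict[int, float]) -> float:
    """Deflate a reference-year amount to service-year dollars."""
    return round(amount_ref / cpi[year], 2)


class _Emitter:
    """Accumulates table rows during generation."""

    def __init__(self) -> None:
        self.patients: list[dict] = []
        self.medical: list[dict] = []
        self.pharmacy: list[dict] = []
        self.enrollment: list[dict] = []
        self.truth: list[dict] = []
        self._claim_no = 0

    def next_claim_id(self, prefix: str) -> str:
        self._claim_no += 1
        return f"{prefix}{self._claim_no:08d}"


def _place_episodes(
    rng: np.random.Generator,
    durations: list[int],
    window_days: int,
    min_gap: int,
) -> list[int] | None:
    """Start offsets for episodes of given durations inside [0, window_days).

    Consecutive episodes are separated end-to-start by at least
    ``min_gap + 1`` days; leftover slack is spread multinomially.
    Returns None when nothing fits.
    """
    k = len(durations)
    if k == 0:
        return []
    required = sum(durations) + (min_gap + 1) * (k - 1)
    if required > window_days:
        return None
    slack = window_days - required
    extra = rng.multinomial(slack, [1.0 / (k + 1)] * (k + 1)) if slack else [0] * (k + 1)
    offsets = []
    cursor = int(extra[0])
    for j, d in enumerate(durations):
        offsets.append(cursor)
        cursor += d + (min_gap + 1) + int(extra[j + 1])
    return offsets


def generate_dataset(
    config: GeneratorConfig, windows: Optional[StudyWindows] = None
) -> tuple[ClaimsBundle, pd.DataFrame]:
    """Generate a full synthetic claims bundle plus the ground-truth table.

    Deterministic given ``config`` (including its seed).  Every generated
    VOC episode is realized as >=1 VOC-coded claim with intra-episode
    start gaps <= the configured maximum and inter-episode separation
    strictly greater, so the episode grouper recovers the ground truth
    exactly; background claims never carry sickle cell codes.
    """
    windows = windows or StudyWindows()
    rng = np.random.default_rng(config.seed)
    em = _Emitter()
    id_days = int((windows.id_period_end - windows.id_period_start).days)
    gap_max = config.gap_within_episode_max_days
    races = list(config.race_probs)
    regions = list(config.region_probs)
    plans = list(config.plan_probs)
    bands = list(config.age_band_probs)
    settings = list(config.setting_probs)
    drug_classes = list(config.drug_class_probs)
    nb_p = config.episode_dispersion / (config.episode_dispersion + config.episode_rate_mean)

    for i in range(config.n_patients):
        pid = f"P{i:05d}"
        index_date = windows.id_period_start + pd.Timedelta(
            days=int(rng.integers(0, id_days + 1))
        )
        sex = "female" if rng.random() < config.prop_female else "male"
        race = _choice(rng, races, [config.race_probs[r] for r in races])
        region = _choice(rng, regions, [config.region_probs[r] for r in regions])
        plan = _choice(rng, plans, [config.plan_probs[p] for p in plans])
        band = _choice(rng, bands, [config.age_band_probs[b] for b in bands])
        lo, hi = _AGE_BANDS[band]
        age = int(rng.integers(lo, hi + 1))
        birth = index_date - pd.DateOffset(years=age) - pd.Timedelta(
            days=int(rng.integers(0, 330))
        )
        trial = bool(rng.random() < config.clinical_trial_prob)
        death = None
        if rng.random() < config.death_prob:
            death = index_date + pd.Timedelta(days=int(rng.integers(200, 364)))

        baseline_start = pd.Timestamp(index_date - pd.DateOffset(months=windows.baseline_months))
        dropout = rng.random() < config.enrollment_dropout_prob
        if dropout:
            coverage_end = index_date + pd.Timedelta(days=int(rng.integers(60, 330)))
        else:
            coverage_end = index_date + pd.Timedelta(
                days=windows.followup_days - 1 + int(rng.integers(0, 180))
            )
        # the data window closes at study end; no claims or coverage beyond it
        coverage_end = min(coverage_end, windows.study_end)
        coverage_start = baseline_start - pd.Timedelta(days=int(rng.integers(0, 180)))
        # ... and opens 6 months before the identification period
        data_start = pd.Timestamp(
            windows.id_period_start - pd.DateOffset(months=windows.baseline_months)
        )
        coverage_start = max(coverage_start, data_start)
        em.enrollment.append(
            dict(
                patient_id=pid,
                span_start=coverage_start,
                span_end=coverage_end,
                medical_coverage=True,
                pharmacy_coverage=True,
            )
        )
        em.patients.append(
            dict(
                patient_id=pid,
                birth_date=birth,
                sex=sex,
                race=race,
                region=region,
                plan_type=plan,
                death_date=death,
                clinical_trial_flag=trial,
            )
        )

        # sickle cell index claim (non-VOC SCD code) on the index date
        year = int(index_date.year)
        em.medical.append(
            dict(
                claim_id=em.next_claim_id("M"),
                patient_id=pid,
                service_start=index_date,
                service_end=index_date,
                dx_codes=("28260",),
                pos_code="outpatient_hospital",
                is_transfusion=False,
                paid_amount=_nominal(
                    _lognormal_cost(rng, config.cost_lognormal_params["background"]),
                    year,
                    config.cpi_factors,
                ),
                service_year=year,
            )
        )

        # baseline VOC episodes, confined to dates that can never collide
        # with the index assignment (before the identification period) nor
        # merge into follow-up episodes (end <= index - gap - 1)
        if rng.random() < config.baseline_voc_prob:
            region_end = min(
                windows.id_period_start - pd.Timedelta(days=1),
                index_date - pd.Timedelta(days=gap_max + 1),
            )
            region_days = int((region_end - baseline_start).days) + 1
            if region_days >= 15:
                n_base = int(rng.integers(1, 3))
                claims_n = [
                    1 + int(rng.poisson(config.claims_per_episode_mean - 1.0))
                    for _ in range(n_base)
                ]
                base_settings = [
                    _choice(rng, settings, [config.setting_probs[s] for s in settings])
                    for _ in range(n_base)
                ]
                stays = [
                    1 + int(rng.poisson(config.inpatient_stay_mean_days - 1))
                    if s == "inpatient"
                    else 1
                    for s in base_settings
                ]
                durations = [
                    max(stay, 1 + gap_max * (m - 1))
                    for stay, m in zip(stays, claims_n)
                ]
                offs = _place_episodes(rng, durations, region_days, gap_max)
                while offs is None and claims_n:
                    claims_n.pop()
                    base_settings.pop()
                    stays.pop()
                    durations.pop()
                    offs = _place_episodes(rng, durations, region_days, gap_max)
                for off, m, setting, stay in zip(
                    offs or [], claims_n, base_settings, stays
                ):
                    start = baseline_start + pd.Timedelta(days=off)
                    end = _generate_episode_claims_fixed_stay(
                        rng, config, pid, start, setting, m, stay, em
                    )
                    em.truth.append(
                        dict(
                            patient_id=pid,
                            episode_seq=0,
                            phase="baseline",
                            start=start,
                            end=end,
                            setting=setting,
                            n_claims=m,
                        )
                    )

        # follow-up VOC episodes in [index, min(index+364, coverage_end)]
        fu_end = min(
            index_date + pd.Timedelta(days=windows.followup_days - 1), coverage_end
        )
        fu_days = int((fu_end - index_date).days) + 1
        k = int(rng.negative_binomial(config.episode_dispersion, nb_p))
        claims_n = [
            1 + int(rng.poisson(config.claims_per_episode_mean - 1.0)) for _ in range(k)
        ]
        ep_settings = [
            _choice(rng, settings, [config.setting_probs[s] for s in settings])
            for _ in range(k)
        ]
        # conservative duration bound per episode: first-claim stay plus
        # maximal start gaps; actual realized end may be earlier
        max_durs = []
        stay_lens = []
        for m, s in zip(claims_n, ep_settings):
            stay = (
                1 + int(rng.poisson(config.inpatient_stay_mean_days - 1))
                if s == "inpatient"
                else 1
            )
            stay_lens.append(stay)
            max_durs.append(max(stay, 1 + gap_max * (m - 1)))
        offs = _place_episodes(rng, max_durs, fu_days, gap_max)
        while offs is None and claims_n:
            claims_n.pop()
            ep_settings.pop()
            max_durs.pop()
            stay_lens.pop()
            offs = _place_episodes(rng, max_durs, fu_days, gap_max)
        for off, m, setting, stay in zip(offs or [], claims_n, ep_settings, stay_lens):
            start = index_date + pd.Timedelta(days=off)
            end = _generate_episode_claims_fixed_stay(
                rng, config, pid, start, setting, m, stay, em
            )
            em.truth.append(
                dict(
                    patient_id=pid,
                    episode_seq=0,
                    phase="followup",
                    start=start,
                    end=end,
                    setting=setting,
                    n_claims=m,
                )
            )

        # background medical claims over the coverage span, never SCD-coded
        span_days = int((coverage_end - coverage_start).days) + 1
        n_bg = int(rng.poisson(config.background_claim_rate * span_days / 365.0))
        bg_offsets = sorted(int(o) for o in rng.integers(0, span_days, n_bg))
        for off in bg_offsets:
            svc = coverage_start + pd.Timedelta(days=off)
            dx = _BACKGROUND_DX[
                int(rng.choice(len(_BACKGROUND_DX), p=_BACKGROUND_DX_WEIGHTS))
            ]
            pos = _BACKGROUND_POS[
                int(rng.choice(len(_BACKGROUND_POS), p=_BACKGROUND_POS_WEIGHTS))
            ]
            year = int(svc.year)
            em.medical.append(
                dict(
                    claim_id=em.next_claim_id("M"),
                    patient_id=pid,
                    service_start=svc,
                    service_end=svc,
                    dx_codes=(dx,),
                    pos_code=pos,
                    is_transfusion=bool(rng.random() < config.transfusion_prob),
                    paid_amount=_nominal(
                        _lognormal_cost(rng, config.cost_lognormal_params["background"]),
                        year,
                        config.cpi_factors,
                    ),
                    service_year=year,
                )
            )

        # pharmacy fills
        n_rx = int(rng.poisson(config.pharmacy_fill_rate * span_days / 365.0))
        rx_offsets = sorted(int(o) for o in rng.integers(0, span_days, n_rx))
        for off in rx_offsets:
            fill = coverage_start + pd.Timedelta(days=off)
            year = int(fill.year)
            em.pharmacy.append(
                dict(
                    claim_id=em.next_claim_id("R"),
                    patient_id=pid,
                    fill_date=fill,
                    drug_class=_choice(
                        rng, drug_classes, [config.drug_class_probs[d] for d in drug_classes]
                    ),
                    paid_amount=_nominal(
                        _lognormal_cost(rng, config.cost_lognormal_params["pharmacy"]),
                        year,
                        config.cpi_factors,
                    ),
                    service_year=year,
                )
            )

    bundle = ClaimsBundle(
        patients=_frame(em.patients, PATIENT_COLUMNS),
        medical=_frame(em.medical, MEDICAL_COLUMNS),
        pharmacy=_frame(em.pharmacy, PHARMACY_COLUMNS),
        enrollment=_frame(em.enrollment, ENROLLMENT_COLUMNS),
    )
    truth = _frame(em.truth, GROUND_TRUTH_COLUMNS)
    if not truth.empty:
        truth = truth.sort_values(["patient_id", "start"]).reset_index(drop=True)
        truth["episode_seq"] = truth.groupby("patient_id").cumcount() + 1
    return bundle, truth


def _generate_episode_claims_fixed_stay(
    rng: np.random.Generator,
    config: GeneratorConfig,
    pid: str,
    start: pd.Timestamp,
    setting: str,
    n_claims: int,
    stay_days: int,
    em: _Emitter,
) -> pd.Timestamp:
    """Like :func:`_generate_episode_claims` but with a pre-drawn first-claim
    stay length, so placement bounds computed before realization hold."""
    gap_max = config.gap_within_episode_max_days
    offsets = [0]
    for _ in range(n_claims - 1):
        offsets.append(offsets[-1] + int(rng.integers(1, gap_max + 1)))
    prio = _SETTING_ORDER.index(setting)
    end_offset = 0
    for j, off in enumerate(offsets):
        pos_setting = (
            setting
            if j == 0
            else _SETTING_ORDER[int(rng.integers(prio, len(_SETTING_ORDER)))]
        )
        pos = _SETTING_POS[pos_setting][int(rng.integers(len(_SETTING_POS[pos_setting])))]
        length = stay_days if j == 0 and setting == "inpatient" else 1
        svc_start = start + pd.Timedelta(days=off)
        svc_end = svc_start + pd.Timedelta(days=length - 1)
        end_offset = max(end_offset, off + length - 1)
        year = int(svc_start.year)
        dx = [_VOC_CODES[int(rng.integers(len(_VOC_CODES)))]]
        if rng.random() < 0.3:
            dx.append(_BACKGROUND_DX[int(rng.integers(len(_BACKGROUND_DX)))])
        cost_ref = _lognormal_cost(rng, config.cost_lognormal_params[pos_setting])
        em.medical.append(
            dict(
                claim_id=em.next_claim_id("M"),
                patient_id=pid,
                service_start=svc_start,
                service_end=svc_end,
                dx_codes=tuple(dx),
                pos_code=pos,
                is_transfusion=False,
                paid_amount=_nominal(cost_ref, year, config.cpi_factors),
                service_year=year,
            )
        )
    return start + pd.Timedelta(days=end_offset)


def _frame(rows: list[dict], columns: tuple[str, ...]) -> pd.DataFrame:
    df = pd.DataFrame(rows, columns=list(columns))
    for col in df.columns:
        if col.endswith("_date") or col in ("service_start", "service_end",
                                            "span_start", "span_end", "fill_date",
                                            "start", "end"):
            df[col] = pd.to_datetime(df[col])
    return df


# ---------------------------------------------------------------------------
# Eligibility stress fixture


def _patient(pid, birth, *, sex="female", race="black", region="south",
             plan="FFS", death=None, trial=False) -> dict:
    return dict(
        patient_id=pid, birth_date=pd.Timestamp(birth), sex=sex, race=race,
        region=region, plan_type=plan,
        death_date=pd.Timestamp(death) if death else None,
        clinical_trial_flag=trial,
    )


def _med(cid, pid, start, end=None, dx=("28260",), pos="outpatient_hospital",
         transfusion=False, paid=100.0, year=None) -> dict:
    start = pd.Timestamp(start)
    end = pd.Timestamp(end) if end else start
    return dict(
        claim_id=cid, patient_id=pid, service_start=start, service_end=end,
        dx_codes=tuple(dx), pos_code=pos, is_transfusion=transfusion,
        paid_amount=float(paid), service_year=year or int(start.year),
    )


def _rx(cid, pid, fill, drug_class="opioid", paid=40.0) -> dict:
    fill = pd.Timestamp(fill)
    return dict(
        claim_id=cid, patient_id=pid, fill_date=fill, drug_class=drug_class,
        paid_amount=float(paid), service_year=int(fill.year),
    )


def _span(pid, start, end, med=True, pharm=True) -> dict:
    return dict(
        patient_id=pid, span_start=pd.Timestamp(start), span_end=pd.Timestamp(end),
        medical_coverage=med, pharmacy_coverage=pharm,
    )


def generate_eligibility_stress_fixture() -> tuple[ClaimsBundle, dict]:
    """A 12-patient hand-designed bundle exercising every eligibility rule.

    Six patients are eligible; each of the other six violates exactly one
    criterion (no SCD claim in the identification period, age under 18,
    a baseline enrollment gap, a follow-up enrollment gap, missing
    pharmacy coverage, clinical-trial flag).  Expected attrition counts
    and the eligible id set ship in the returned metadata dict.
    """
    patients, medical, pharmacy, enrollment = [], [], [], []

    def full_span(pid):
        enrollment.append(_span(pid, "2010-11-01", "2012-07-31"))

    # SF01 eligible FFS; 2 follow-up episodes (first merges ER into an
    # inpatient stay); baseline hydroxyurea, transfusion, asthma claim.
    patients.append(_patient("SF01", "1980-01-01"))
    full_span("SF01")
    medical += [
        _med("SF01-IDX", "SF01", "2011-06-15"),
        _med("SF01-V1", "SF01", "2011-07-01", "2011-07-03", dx=("28262",),
             pos="inpatient", paid=5000.0),
        _med("SF01-V2", "SF01", "2011-07-04", dx=("28262",), pos="outpatient_er",
             paid=400.0),
        _med("SF01-V3", "SF01", "2011-09-01", dx=("28269",), pos="independent_clinic",
             paid=150.0),
        _med("SF01-B1", "SF01", "2011-01-15", dx=("49390",), pos="office", paid=80.0),
        _med("SF01-B2", "SF01", "2011-03-01", dx=("V582",), pos="outpatient_hospital",
             transfusion=True, paid=600.0),
    ]
    pharmacy.append(_rx("SF01-R1", "SF01", "2011-02-01", drug_class="hydroxyurea"))

    # SF02 eligible FFS; zero episodes; one non-SCD follow-up claim.
    patients.append(_patient("SF02", "1975-05-20", sex="male"))
    full_span("SF02")
    medical += [
        _med("SF02-IDX", "SF02", "2011-06-15"),
        _med("SF02-B1", "SF02", "2011-08-10", dx=("78900",), pos="office", paid=300.0),
    ]

    # SF03 fails age: 16 at index.
    patients.append(_patient("SF03", "1995-01-01"))
    full_span("SF03")
    medical.append(_med("SF03-IDX", "SF03", "2011-06-15"))

    # SF04 fails index: only SCD claim predates the identification period.
    patients.append(_patient("SF04", "1980-01-01"))
    full_span("SF04")
    medical += [
        _med("SF04-OLD", "SF04", "2009-06-15"),
        _med("SF04-B1", "SF04", "2011-08-01", dx=("78900",), pos="office"),
    ]

    # SF05 fails enrollment: baseline gap (coverage starts after baseline).
    patients.append(_patient("SF05", "1980-01-01"))
    enrollment.append(_span("SF05", "2011-01-15", "2012-07-31"))
    medical.append(_med("SF05-IDX", "SF05", "2011-06-15"))

    # SF06 fails enrollment: coverage ends before follow-up completes.
    patients.append(_patient("SF06", "1980-01-01"))
    enrollment.append(_span("SF06", "2010-11-01", "2012-03-31"))
    medical.append(_med("SF06-IDX", "SF06", "2011-06-15"))

    # SF07 fails the clinical-trial exclusion.
    patients.append(_patient("SF07", "1980-01-01", trial=True))
    full_span("SF07")
    medical.append(_med("SF07-IDX", "SF07", "2011-06-15"))

    # SF08 fails enrollment: medical-only coverage in baseline.
    patients.append(_patient("SF08", "1980-01-01"))
    enrollment += [
        _span("SF08", "2010-11-01", "2011-06-14", med=True, pharm=False),
        _span("SF08", "2011-06-15", "2012-07-31"),
    ]
    medical.append(_med("SF08-IDX", "SF08", "2011-06-15"))

    # SF09 eligible managed care; 1 ER episode (costs excluded from FFS
    # costing but utilization counted).
    patients.append(_patient("SF09", "1982-03-03", plan="managed_care"))
    full_span("SF09")
    medical += [
        _med("SF09-IDX", "SF09", "2011-06-15"),
        _med("SF09-V1", "SF09", "2011-10-01", dx=("28262",), pos="outpatient_er",
             paid=350.0),
    ]

    # SF10 eligible FFS; 3 well-separated single-claim ER episodes (3+).
    patients.append(_patient("SF10", "1970-07-07"))
    full_span("SF10")
    medical += [
        _med("SF10-IDX", "SF10", "2011-06-15"),
        _med("SF10-V1", "SF10", "2011-08-01", dx=("28264",), pos="outpatient_er", paid=300.0),
        _med("SF10-V2", "SF10", "2011-08-10", dx=("28264",), pos="outpatient_er", paid=310.0),
        _med("SF10-V3", "SF10", "2011-08-20", dx=("28264",), pos="outpatient_er", paid=320.0),
    ]

    # SF11 eligible FFS; episode starting just inside the follow-up window
    # and extending past it (still counted, by start-date membership).
    patients.append(_patient("SF11", "1985-09-09"))
    enrollment.append(_span("SF11", "2010-11-01", "2012-08-31"))
    medical += [
        _med("SF11-IDX", "SF11", "2011-06-15"),
        _med("SF11-V1", "SF11", "2012-06-12", dx=("28262",), pos="outpatient_hospital",
             paid=250.0),
        _med("SF11-V2", "SF11", "2012-06-15", dx=("28262",), pos="outpatient_hospital",
             paid=260.0),
    ]

    # SF12 eligible FFS; 65+ age band, zero episodes.
    patients.append(_patient("SF12", "1945-05-01", sex="male"))
    full_span("SF12")
    medical.append(_med("SF12-IDX", "SF12", "2011-06-15"))

    bundle = ClaimsBundle(
        patients=_frame(patients, PATIENT_COLUMNS),
        medical=_frame(medical, MEDICAL_COLUMNS),
        pharmacy=_frame(pharmacy, PHARMACY_COLUMNS),
        enrollment=_frame(enrollment, ENROLLMENT_COLUMNS),
    )
    metadata = {
        "n_patients": 12,
        "eligible_ids": ["SF01", "SF02", "SF09", "SF10", "SF11", "SF12"],
        "attrition_counts": [12, 11, 10, 7, 6],
        "failing": {
            "no_index": ["SF04"],
            "age": ["SF03"],
            "enrollment": ["SF05", "SF06", "SF08"],
            "trial": ["SF07"],
        },
        "index_date": "2011-06-15",
        "followup_episode_counts": {
            "SF01": 2, "SF02": 0, "SF09": 1, "SF10": 3, "SF11": 1, "SF12": 0,
        },
    }
    return bundle, metadata
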