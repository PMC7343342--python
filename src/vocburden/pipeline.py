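"""End-to-end pipeline orchestration and report rendering.

``run_pipeline`` executes read (or synthesize) -> cohort -> baseline ->
episodes -> analytics and writes tidy CSV reports plus a machine-readable
JSON run log.  The log serializes the full configuration verbatim with a
SHA-256 config hash, per-stage cohort counts and output-file digests, so
a rerun under the same configuration is byte-identical and auditable.

Report shapes follow the conventions of published claims studies:
demographics with fixed age bands (18-30 / 31-45 / 46-64 / 65+),
baseline clinical characteristics, annual all-cause and SCD-related
utilization/costs by facility type, episode-count strata, per-episode
costs by setting, and the per-stratum cost frequency distribution.
Percentages are reported to one decimal and costs to whole dollars in
the presentation tables; analytic outputs keep cent precision.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path
from typing import Optional

import pandas as pd
from pydantic import BaseModel, Field

from . import __version__
from .claims_model import ClaimsBundle, read_claims_tables, write_bundle
from .cohort import StudyWindows, build_cohort
from .comorbidity import baseline_profiles, load_cci_map, load_condition_map
from .costs import (
    SCDAttributionRules,
    annual_summary,
    cost_frequency_distribution,
    episode_costs,
    load_cpi,
    stratified_summary,
)
from .episodes import STRATA, build_episode_table
from .synthetic import GeneratorConfig, generate_dataset

__all__ = ["RunConfig", "run_pipeline", "PipelineError"]


class PipelineError(RuntimeError):
    """An error in a named pipeline stage."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[stage {stage}] {message}")
        self.stage = stage


class RunConfig(BaseModel):
    """Everything that determines one pipeline run."""

    input_dir: Optional[str] = None  # read tables from here, or ...
    synthetic: Optional[GeneratorConfig] = None  # ... generate them
    out_dir: str = "results"

    id_period_start: str = "2009-07-01"
    id_period_end: str = "2012-12-31"
    baseline_months: int = 6
    followup_days: int = 365
    study_end: str = "2013-12-31"

    gap_days: int = Field(ge=0, default=3)
    allowable_enrollment_gap_days: int = Field(ge=0, default=0)
    costing_population: str = "FFS_only"
    cost_bin_width: float = Field(gt=0, default=10_000.0)

    cci_map_file: Optional[str] = None
    condition_codes_file: Optional[str] = None
    cpi_file: Optional[str] = None

    def study_windows(self) -> StudyWindows:
        return StudyWindows(
            id_period_start=pd.Timestamp(self.id_period_start),
            id_period_end=pd.Timestamp(self.id_period_end),
            baseline_months=self.baseline_months,
            followup_days=self.followup_days,
            study_end=pd.Timestamp(self.study_end),
        )

    def config_hash(self) -> str:
        payload = json.dumps(self.model_dump(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()


def _pct(n: int, d: int) -> float:
    return round(100.0 * n / d, 1) if d else float("nan")


def demographic_table(cohort: pd.DataFrame, patients: pd.DataFrame) -> pd.DataFrame:
    """Demographics of the eligible cohort (counts and percentages)."""
    merged = cohort.merge(patients, on="patient_id", suffixes=("", "_p"))
    n = len(merged)
    rows = [dict(section="overall", level="n_patients", n=n, value=float(n))]
    rows.append(
        dict(
            section="age_years",
            level="mean_sd",
            n=n,
            value=round(merged["age_at_index"].mean(), 2) if n else float("nan"),
            sd=round(merged["age_at_index"].std(ddof=1), 2) if n > 1 else float("nan"),
        )
    )
    bands = pd.cut(
        merged["age_at_index"],
        bins=[17, 30, 45, 64, 200],
        labels=["18-30", "31-45", "46-64", "65+"],
    )
    for label in ["18-30", "31-45", "46-64", "65+"]:
        c = int((bands == label).sum())
        rows.append(dict(section="age_group", level=label, n=c, value=_pct(c, n)))
    for col, section in [("sex", "sex"), ("race", "race"), ("region", "region"),
                         ("plan_type", "plan_type")]:
        for level, c in merged[col].value_counts().sort_index().items():
            rows.append(dict(section=section, level=level, n=int(c), value=_pct(int(c), n)))
    return pd.DataFrame(rows, columns=["section", "level", "n", "value", "sd"])


def baseline_table(profiles: pd.DataFrame) -> pd.DataFrame:
    """Baseline clinical characteristics (the Table-2 shape)."""
    n = len(profiles)
    rows = [
        dict(
            section="cci",
            level="mean_sd",
            n=n,
            value=round(profiles["cci_score"].mean(), 2) if n else float("nan"),
            sd=round(profiles["cci_score"].std(ddof=1), 2) if n > 1 else float("nan"),
        )
    ]
    for band in ["0", "1", "2-3", "4+"]:
        c = int((profiles["cci_band"] == band).sum())
        rows.append(dict(section="cci_band", level=band, n=c, value=_pct(c, n)))
    c = int((profiles["baseline_voc_episode_count"] > 0).sum())
    rows.append(dict(section="baseline_voc", level="any_episode", n=c, value=_pct(c, n)))
    c = int(profiles["baseline_voc_inpatient_flag"].sum())
    rows.append(dict(section="baseline_voc", level="inpatient_episode", n=c, value=_pct(c, n)))
    rows.append(
        dict(
            section="baseline_voc",
            level="mean_episodes",
            n=n,
            value=round(profiles["baseline_voc_episode_count"].mean(), 2)
            if n
            else float("nan"),
            sd=round(profiles["baseline_voc_episode_count"].std(ddof=1), 2)
            if n > 1
            else float("nan"),
        )
    )
    for col in profiles.columns:
        for prefix, section in [("cond_", "comorbidity"), ("med_", "medication"),
                                ("util_", "baseline_utilization")]:
            if col.startswith(prefix):
                c = int(profiles[col].sum())
                rows.append(
                    dict(section=section, level=col[len(prefix):], n=c, value=_pct(c, n))
                )
    c = int(profiles["transfusion_flag"].sum()) if n else 0
    rows.append(dict(section="management", level="blood_transfusion", n=c, value=_pct(c, n)))
    return pd.DataFrame(rows, columns=["section", "level", "n", "value", "sd"])


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis; returns the report bundle in memory.

    Writes all report CSVs plus ``run_log.json`` under ``config.out_dir``.
    Every output row set is deterministic given the configuration; any
    stage failure raises :class:`PipelineError` naming the stage.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    windows = config.study_windows()

    # ---- read / synthesize
    truth = None
    try:
        if config.synthetic is not None:
            bundle, truth = generate_dataset(config.synthetic, windows)
        elif config.input_dir:
            paths = {
                k: Path(config.input_dir) / f"{k}.csv"
                for k in ("patients", "medical", "pharmacy", "enrollment")
            }
            bundle, _ = read_claims_tables(paths)
        else:
            raise ValueError("config must set input_dir or synthetic")
    except Exception as exc:
        raise PipelineError("claims_model", str(exc)) from exc

    # ---- cohort
    try:
        cohort, attrition = build_cohort(
            bundle, windows, allowable_gap_days=config.allowable_enrollment_gap_days
        )
    except Exception as exc:
        raise PipelineError("cohort_builder", str(exc)) from exc

    # ---- baseline characterization
    try:
        cci_map = load_cci_map(config.cci_map_file)
        condition_map = load_condition_map(config.condition_codes_file)
        profiles = baseline_profiles(
            bundle, cohort, cci_map=cci_map, condition_map=condition_map,
            gap_days=config.gap_days,
        )
    except Exception as exc:
        raise PipelineError("comorbidity", str(exc)) from exc

    # ---- episodes
    try:
        episodes = build_episode_table(
            bundle.medical[bundle.medical["patient_id"].isin(cohort["patient_id"])],
            gap_days=config.gap_days,
        )
        fu = cohort.set_index("patient_id")[["followup_start", "followup_end"]]
        if not episodes.empty:
            ep = episodes.join(fu, on="patient_id")
            in_fu = ep[(ep["start"] >= ep["followup_start"]) & (ep["start"] <= ep["followup_end"])]
            episode_counts = in_fu.groupby("patient_id").size()
            fu_episodes = in_fu.drop(columns=["followup_start", "followup_end"])
        else:
            episode_counts = pd.Series(dtype=int)
            fu_episodes = episodes
    except Exception as exc:
        raise PipelineError("episode_builder", str(exc)) from exc

    # ---- analytics
    try:
        cpi = load_cpi(config.cpi_file)
        rules = SCDAttributionRules()
        table3 = pd.concat(
            [
                annual_summary(
                    cohort, bundle, cpi, scope=s,
                    costing_population=config.costing_population, rules=rules,
                )
                for s in ("all_cause", "scd_related")
            ],
            ignore_index=True,
        )
        strata = stratified_summary(cohort, bundle, episode_counts, cpi, rules=rules)
        ffs_ids = set(cohort.loc[cohort["plan_type"] == "FFS", "patient_id"])
        ffs_episodes = fu_episodes[fu_episodes["patient_id"].isin(ffs_ids)]
        per_episode, per_setting = episode_costs(ffs_episodes, bundle, cpi, rules=rules)

        totals = strata_totals(cohort, bundle, episode_counts, cpi, rules)
        distribution = cost_frequency_distribution(
            totals[totals["patient_id"].isin(ffs_ids)],
            bin_width=config.cost_bin_width,
        )
    except Exception as exc:
        raise PipelineError("cost_analytics", str(exc)) from exc

    # ---- render
    table1 = demographic_table(cohort, bundle.patients)
    table2 = baseline_table(profiles)
    outputs = {
        "attrition": attrition,
        "cohort": _dates_to_str(cohort),
        "baseline_profiles": profiles,
        "table1_demographics": table1,
        "table2_baseline": table2,
        "table3_annual_hcru_costs": _round(table3),
        "strata_summary": _round(strata),
        "episode_costs": _round(per_episode),
        "episode_setting_costs": _round(per_setting),
        "cost_distribution": _round(distribution),
        "episodes": _dates_to_str(
            fu_episodes.drop(columns=["member_claim_ids"], errors="ignore")
        ),
    }
    if truth is not None:
        outputs["ground_truth"] = _dates_to_str(truth)

    cfg_hash = config.config_hash()
    file_hashes = {}
    for name, df in outputs.items():
        path = out_dir / f"{name}.csv"
        with open(path, "w", newline="") as fh:
            fh.write(f"# config_hash={cfg_hash}\n")
            df.to_csv(fh, index=False, float_format="%.4f")
        file_hashes[name] = hashlib.sha256(path.read_bytes()).hexdigest()

    strat_counts = (
        episode_counts.reindex(cohort["patient_id"]).fillna(0).astype(int)
        .map(lambda c: str(c) if c < 3 else "3+")
        .value_counts()
        .reindex(STRATA, fill_value=0)
    )
    log = {
        "package_version": __version__,
        "config": json.loads(json.dumps(config.model_dump(), default=str)),
        "config_hash": cfg_hash,
        "stage_counts": {
            "patients_in": int(len(bundle.patients)),
            "medical_claims_in": int(len(bundle.medical)),
            "cohort_size": int(len(cohort)),
            "followup_episodes": int(len(fu_episodes)),
            "strata_sizes": {k: int(v) for k, v in strat_counts.items()},
        },
        "notes": {
            "death_handling": "death truncates follow-up observation; the patient is retained",
        },
        "output_hashes": file_hashes,
    }
    with open(out_dir / "run_log.json", "w") as fh:
        json.dump(log, fh, indent=2, sort_keys=True)

    outputs["run_log"] = log
    outputs["episode_counts"] = episode_counts
    outputs["bundle"] = bundle
    return outputs


def strata_totals(cohort, bundle, episode_counts, cpi, rules) -> pd.DataFrame:
    """Per-patient SCD-related total cost with episode-count stratum."""
    from .costs import TOTAL_COST_FACILITIES, patient_facility_metrics

    metrics = patient_facility_metrics(
        cohort, bundle, cpi, scope="scd_related", rules=rules
    )
    totals = (
        metrics[metrics["facility"].isin(TOTAL_COST_FACILITIES)]
        .groupby("patient_id")["cost_adj"]
        .sum()
        .rename("total")
        .reset_index()
    )
    counts = episode_counts.reindex(totals["patient_id"]).fillna(0).astype(int)
    totals["stratum"] = counts.map(lambda c: str(c) if c < 3 else "3+").values
    return totals


def _round(df: pd.DataFrame) -> pd.DataFrame:
    out = df.copy()
    for col in out.columns:
        if out[col].dtype.kind == "f":
            out[col] = out[col].round(2)
    return out


def _dates_to_str(df: pd.DataFrame) -> pd.DataFrame:
    out = df.copy()
    for col in out.columns:
        if out[col].dtype.kind == "M":
            out[col] = out[col].dt.strftime("%Y-%m-%d")
    return out
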