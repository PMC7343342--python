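"""Core claim-level data model and delimited-text I/O.

The pipeline operates on four tabular inputs shaped after the CMS Medicaid
Analytic eXtract (MAX) research files:

* ``patients`` — one row per enrollee with demographics, plan type, an
  optional death date and a clinical-trial participation flag;
* ``medical`` — one row per billed medical service line, carrying service
  dates, an ordered list of ICD-9-CM diagnosis codes, a place-of-service
  category, a transfusion procedure flag and the paid amount in
  service-year dollars;
* ``pharmacy`` — one row per prescription fill with a coarse drug class;
* ``enrollment`` — coverage spans with medical/pharmacy benefit flags.

Collections are plain :class:`pandas.DataFrame` objects with fixed column
names and dtypes; the dataclass :class:`ClaimsBundle` carries the four
tables together.  Files are UTF-8 delimited text (comma by default) with a
mandatory header row; dates are ISO-8601 and diagnosis code lists are
``;``-joined.  All date windows in this package are closed intervals of
whole calendar days.

Diagnosis codes are stored *without* decimal points, zero-padded to the
three-character ICD-9 category ("282.62" -> "28262", "1.9" -> "0019");
:func:`normalize_icd9` accepts either form so that dotted configuration
files and dotless claim feeds cannot silently mismatch.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "ClaimsBundle",
    "RowError",
    "ClaimsSchemaError",
    "normalize_icd9",
    "SCD_DX_CODES",
    "read_claims_tables",
    "read_table",
    "write_bundle",
    "normalize_enrollment",
    "PATIENT_COLUMNS",
    "MEDICAL_COLUMNS",
    "PHARMACY_COLUMNS",
    "ENROLLMENT_COLUMNS",
]

# ---------------------------------------------------------------------------
# Schemas

PATIENT_COLUMNS = (
    "patient_id",
    "birth_date",
    "sex",
    "race",
    "region",
    "plan_type",
    "death_date",
    "clinical_trial_flag",
)
MEDICAL_COLUMNS = (
    "claim_id",
    "patient_id",
    "service_start",
    "service_end",
    "dx_codes",
    "pos_code",
    "is_transfusion",
    "paid_amount",
    "service_year",
)
PHARMACY_COLUMNS = (
    "claim_id",
    "patient_id",
    "fill_date",
    "drug_class",
    "paid_amount",
    "service_year",
)
ENROLLMENT_COLUMNS = (
    "patient_id",
    "span_start",
    "span_end",
    "medical_coverage",
    "pharmacy_coverage",
)

SEXES = ("male", "female")
RACES = ("white", "black", "hispanic", "other", "unknown")
REGIONS = ("northeast", "south", "west", "north_central")
PLAN_TYPES = ("FFS", "managed_care")
DRUG_CLASSES = (
    "antibiotic",
    "acetaminophen",
    "folic_acid",
    "opioid",
    "nsaid",
    "hydroxyurea",
    "other",
)

#: Facility types reported in annual utilization/cost tables.
FACILITY_TYPES = (
    "inpatient",
    "outpatient_hospital",
    "outpatient_er",
    "outpatient_office",
    "outpatient_other",
    "ambulatory_surgery_center",
    "lab",
    "hospice",
    "long_term_care",
    "pharmacy",
)


def normalize_icd9(code: str) -> str:
    """Return ``code`` in dotless, category-padded ICD-9-CM form.

    ``"282.62" -> "28262"``, ``"1.9" -> "0019"``, ``"V43.4" -> "V434"``.
    Already-dotless codes pass through (numeric categories are padded to
    three characters).
    """
    code = str(code).strip().upper()
    if not code:
        raise ValueError("empty diagnosis code")
    if "." in code:
        head, _, tail = code.partition(".")
    else:
        head, tail = code, ""
    if head[0].isdigit():
        head = head.zfill(3)
    elif head[0] in "VE" and "." not in code:
        # dotless V/E codes pass through untouched
        return head + tail
    return head + tail


#: ICD-9-CM codes identifying sickle cell disease in any diagnosis position
#: (282.41, 282.42, 282.60-282.69).
SCD_DX_CODES: frozenset[str] = frozenset(
    {"28241", "28242"} | {f"2826{i}" for i in range(10)}
)


class ClaimsSchemaError(ValueError):
    """A required column is missing or a table is structurally unreadable."""


@dataclasses.dataclass(frozen=True)
class RowError:
    """A rejected input row, with enough context to locate it in the file."""

    table: str
    row: int  # 0-based data-row index (header excluded)
    message: str


@dataclasses.dataclass
class ClaimsBundle:
    """The four claim tables for one analysis run."""

    patients: pd.DataFrame
    medical: pd.DataFrame
    pharmacy: pd.DataFrame
    enrollment: pd.DataFrame

    def copy(self) -> "ClaimsBundle":
        return ClaimsBundle(
            self.patients.copy(),
            self.medical.copy(),
            self.pharmacy.copy(),
            self.enrollment.copy(),
        )


# ---------------------------------------------------------------------------
# Parsing helpers

_DATE_COLUMNS = {
    "patients": ["birth_date", "death_date"],
    "medical": ["service_start", "service_end"],
    "pharmacy": ["fill_date"],
    "enrollment": ["span_start", "span_end"],
}
_BOOL_COLUMNS = {
    "patients": ["clinical_trial_flag"],
    "medical": ["is_transfusion"],
    "pharmacy": [],
    "enrollment": ["medical_coverage", "pharmacy_coverage"],
}
_REQUIRED = {
    "patients": PATIENT_COLUMNS,
    "medical": MEDICAL_COLUMNS,
    "pharmacy": PHARMACY_COLUMNS,
    "enrollment": ENROLLMENT_COLUMNS,
}
_OPTIONAL_DATES = {"death_date"}

_TRUTHY = {"true", "1", "yes", "t"}
_FALSY = {"false", "0", "no", "f", ""}


def _parse_bool(series: pd.Series) -> pd.Series:
    lowered = series.astype(str).str.strip().str.lower()
    bad = ~lowered.isin(_TRUTHY | _FALSY)
    out = lowered.isin(_TRUTHY)
    out[bad] = pd.NA
    return out


def _split_dx(value: str) -> tuple[str, ...]:
    parts = [p for p in str(value).split(";") if p.strip()]
    return tuple(normalize_icd9(p) for p in parts)


def read_table(
    path: str | Path,
    table: str,
    *,
    delimiter: str = ",",
    strict: bool = True,
    schema_map: Mapping[str, str] | None = None,
) -> tuple[pd.DataFrame, list[RowError]]:
    """Read one claims table, enforcing the schema and row invariants.

    ``schema_map`` renames custom input headers to canonical names before
    validation.  In ``strict`` mode any invalid row raises; otherwise
    offending rows are dropped and reported in the returned error list.
    """
    if table not in _REQUIRED:
        raise ValueError(f"unknown table kind {table!r}")
    df = pd.read_csv(path, sep=delimiter, dtype=str, keep_default_na=False)
    if schema_map:
        df = df.rename(columns=dict(schema_map))
    missing = [c for c in _REQUIRED[table] if c not in df.columns]
    if missing:
        raise ClaimsSchemaError(
            f"{table} table at {path} is missing required column(s): "
            + ", ".join(missing)
        )
    df = df.loc[:, list(_REQUIRED[table])].reset_index(drop=True)
    errors: list[RowError] = []
    bad_mask = pd.Series(False, index=df.index)

    def flag(mask: pd.Series, message: str) -> None:
        nonlocal bad_mask
        for idx in df.index[mask & ~bad_mask]:
            errors.append(RowError(table, int(idx), message))
        bad_mask |= mask

    for col in _DATE_COLUMNS[table]:
        parsed = pd.to_datetime(
            df[col].replace("", pd.NA), format="%Y-%m-%d", errors="coerce"
        )
        optional = col in _OPTIONAL_DATES
        invalid = parsed.isna() & (df[col] != "" if optional else True)
        flag(invalid, f"unparseable date in column {col!r}")
        df[col] = parsed

    for col in _BOOL_COLUMNS[table]:
        parsed = _parse_bool(df[col])
        flag(parsed.isna(), f"unparseable boolean in column {col!r}")
        df[col] = parsed.fillna(False).astype(bool)

    if "paid_amount" in df.columns:
        amounts = pd.to_numeric(df["paid_amount"], errors="coerce")
        flag(amounts.isna(), "unparseable paid_amount")
        flag(amounts < 0, "negative paid_amount")
        df["paid_amount"] = amounts.astype(float)
    if "service_year" in df.columns:
        years = pd.to_numeric(df["service_year"], errors="coerce")
        flag(years.isna(), "unparseable service_year")
        df["service_year"] = years.fillna(-1).astype(int)

    if table == "medical":
        df["dx_codes"] = df["dx_codes"].map(
            lambda v: _split_dx(v) if str(v).strip() else ()
        )
        flag(df["dx_codes"].map(len) == 0, "dx_codes must be non-empty")
        flag(
            df["service_end"] < df["service_start"],
            "service_end earlier than service_start",
        )
    if table == "enrollment":
        flag(df["span_end"] < df["span_start"], "span_end earlier than span_start")
    if table == "patients":
        has_death = df["death_date"].notna()
        flag(
            has_death & (df["death_date"] < df["birth_date"]),
            "death_date earlier than birth_date",
        )
        dupes = df["patient_id"].duplicated(keep=False)
        flag(dupes, "duplicate patient_id")

    if errors and strict:
        first = errors[0]
        raise ValueError(
            f"{len(errors)} invalid row(s) in {table} table; first: "
            f"row {first.row}: {first.message}"
        )
    df = df.loc[~bad_mask].reset_index(drop=True)
    return df, errors


def read_claims_tables(
    paths: Mapping[str, str | Path],
    *,
    delimiter: str = ",",
    strict: bool = True,
    schema_map: Mapping[str, Mapping[str, str]] | None = None,
) -> tuple[ClaimsBundle, list[RowError]]:
    """Read the four input tables named in ``paths``.

    ``paths`` maps table kind ("patients", "medical", "pharmacy",
    "enrollment") to a file path.  Returns the bundle plus the combined
    row-level error report (empty in strict mode, by construction).
    """
    tables: dict[str, pd.DataFrame] = {}
    errors: list[RowError] = []
    for kind in ("patients", "medical", "pharmacy", "enrollment"):
        df, errs = read_table(
            paths[kind],
            kind,
            delimiter=delimiter,
            strict=strict,
            schema_map=(schema_map or {}).get(kind),
        )
        tables[kind] = df
        errors.extend(errs)
    return ClaimsBundle(**tables), errors


def _format_table(df: pd.DataFrame, table: str) -> pd.DataFrame:
    out = df.copy()
    for col in _DATE_COLUMNS[table]:
        out[col] = out[col].map(
            lambda d: "" if pd.isna(d) else pd.Timestamp(d).strftime("%Y-%m-%d")
        )
    for col in _BOOL_COLUMNS[table]:
        out[col] = out[col].map(lambda b: "true" if b else "false")
    if table == "medical":
        out["dx_codes"] = out["dx_codes"].map(";".join)
    if "paid_amount" in out.columns:
        out["paid_amount"] = out["paid_amount"].map(lambda v: f"{v:.2f}")
    return out


def write_bundle(
    bundle: ClaimsBundle, out_dir: str | Path, *, delimiter: str = ","
) -> dict[str, Path]:
    """Write the four tables as delimited text under ``out_dir``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for kind in ("patients", "medical", "pharmacy", "enrollment"):
        df = getattr(bundle, kind)
        path = out_dir / f"{kind}.csv"
        _format_table(df, kind).to_csv(path, sep=delimiter, index=False)
        paths[kind] = path
    return paths


# ---------------------------------------------------------------------------
# Enrollment normalization

def normalize_enrollment(spans: pd.DataFrame) -> pd.DataFrame:
    """Merge overlapping/abutting spans with identical coverage flags.

    Spans that overlap or abut (next start <= current end + 1 day) within
    one (patient, medical_coverage, pharmacy_coverage) group are collapsed
    into a single span.  The covered-day set per patient/flag combination
    is preserved exactly; the result is sorted and idempotent under
    re-application.
    """
    if spans.empty:
        return spans.copy().reset_index(drop=True)
    spans = spans.sort_values(
        ["patient_id", "medical_coverage", "pharmacy_coverage", "span_start", "span_end"]
    )
    rows: list[dict] = []
    one_day = pd.Timedelta(days=1)
    for (pid, med, pharm), grp in spans.groupby(
        ["patient_id", "medical_coverage", "pharmacy_coverage"], sort=True
    ):
        cur_start = cur_end = None
        for start, end in zip(grp["span_start"], grp["span_end"]):
            if cur_start is None:
                cur_start, cur_end = start, end
            elif start <= cur_end + one_day:
                cur_end = max(cur_end, end)
            else:
                rows.append(
                    dict(
                        patient_id=pid,
                        span_start=cur_start,
                        span_end=cur_end,
                        medical_coverage=med,
                        pharmacy_coverage=pharm,
                    )
                )
                cur_start, cur_end = start, end
        rows.append(
            dict(
                patient_id=pid,
                span_start=cur_start,
                span_end=cur_end,
                medical_coverage=med,
                pharmacy_coverage=pharm,
            )
        )
    out = pd.DataFrame(rows, columns=list(ENROLLMENT_COLUMNS))
    return out.sort_values(["patient_id", "span_start"]).reset_index(drop=True)


def dx_any_in(dx_codes: Sequence[Iterable[str]], code_set: frozenset[str] | set[str]) -> pd.Series:
    """Vectorized membership test: does any diagnosis fall in ``code_set``?"""
    code_set = frozenset(code_set)
    return pd.Series(
        [bool(code_set.intersection(codes)) for codes in dx_codes],
        index=getattr(dx_codes, "index", None),
        dtype=bool,
    )
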