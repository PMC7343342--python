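"""I/O round-trips, row validation and enrollment-span normalization."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vocburden.claims_model import (
    ClaimsSchemaError,
    normalize_enrollment,
    normalize_icd9,
    read_claims_tables,
    read_table,
    write_bundle,
)


@pytest.mark.parametrize(
    "raw,expected",
    [
        ("282.62", "28262"),
        ("28262", "28262"),
        ("1.9", "0019"),
        ("V43.4", "V434"),
        ("E812", "E812"),
        (" 493.90 ", "49390"),
    ],
)
def test_icd9_normalization_accepts_dotted_and_dotless(raw, expected):
    assert normalize_icd9(raw) == expected


def test_round_trip_preserves_all_tables(small_synth, tmp_path):
    bundle, _ = small_synth
    paths = write_bundle(bundle, tmp_path)
    back, errors = read_claims_tables(paths)
    assert errors == []
    for kind in ("patients", "medical", "pharmacy", "enrollment"):
        pd.testing.assert_frame_equal(getattr(back, kind), getattr(bundle, kind))


def test_empty_file_with_header_yields_empty_collection(tmp_path):
    path = tmp_path / "medical.csv"
    path.write_text(
        "claim_id,patient_id,service_start,service_end,dx_codes,pos_code,"
        "is_transfusion,paid_amount,service_year\n"
    )
    df, errors = read_table(path, "medical")
    assert df.empty and errors == []


def test_missing_column_is_a_hard_error_naming_it(tmp_path):
    path = tmp_path / "pharmacy.csv"
    path.write_text("claim_id,patient_id,fill_date,paid_amount,service_year\nr1,p1,2011-01-01,5,2011\n")
    with pytest.raises(ClaimsSchemaError, match="drug_class"):
        read_table(path, "pharmacy")


_MED_HEADER = (
    "claim_id,patient_id,service_start,service_end,dx_codes,pos_code,"
    "is_transfusion,paid_amount,service_year\n"
)


def test_inverted_service_dates_rejected_with_invariant_message(tmp_path):
    path = tmp_path / "medical.csv"
    path.write_text(
        _MED_HEADER + "c1,p1,2011-05-10,2011-05-01,282.62,inpatient,false,10,2011\n"
    )
    df, errors = read_table(path, "medical", strict=False)
    assert df.empty
    assert len(errors) == 1 and "service_end" in errors[0].message
    with pytest.raises(ValueError, match="service_end"):
        read_table(path, "medical", strict=True)


def test_mixed_rows_parse_with_dx_order_preserved(tmp_path):
    (tmp_path / "patients.csv").write_text(
        "patient_id,birth_date,sex,race,region,plan_type,death_date,clinical_trial_flag\n"
        "p1,1980-01-01,female,black,south,FFS,,false\n"
    )
    (tmp_path / "medical.csv").write_text(
        _MED_HEADER
        + "c1,p1,2011-05-01,2011-05-01,282.62;780.60,inpatient,false,10,2011\n"
        + "c2,p1,2011-06-01,2011-06-01,401.9,office,false,20,2011\n"
    )
    (tmp_path / "pharmacy.csv").write_text(
        "claim_id,patient_id,fill_date,drug_class,paid_amount,service_year\n"
        "r1,p1,2011-05-03,opioid,5,2011\n"
    )
    (tmp_path / "enrollment.csv").write_text(
        "patient_id,span_start,span_end,medical_coverage,pharmacy_coverage\n"
        "p1,2011-01-01,2012-01-01,true,true\n"
    )
    bundle, errors = read_claims_tables(
        {k: tmp_path / f"{k}.csv" for k in ("patients", "medical", "pharmacy", "enrollment")}
    )
    assert errors == []
    assert len(bundle.medical) == 2 and len(bundle.pharmacy) == 1
    assert tuple(bundle.medical["dx_codes"]) == (("28262", "78060"), ("4019",))


def test_negative_cost_rejected(tmp_path):
    path = tmp_path / "medical.csv"
    path.write_text(
        _MED_HEADER + "c1,p1,2011-05-01,2011-05-02,282.62,inpatient,false,-3,2011\n"
    )
    _, errors = read_table(path, "medical", strict=False)
    assert any("negative" in e.message for e in errors)


# ---------------------------------------------------------------------------
# Enrollment normalization


def _spans(rows):
    return pd.DataFrame(
        [
            dict(
                patient_id=p,
                span_start=pd.Timestamp(s),
                span_end=pd.Timestamp(e),
                medical_coverage=m,
                pharmacy_coverage=ph,
            )
            for p, s, e, m, ph in rows
        ],
        columns=["patient_id", "span_start", "span_end", "medical_coverage", "pharmacy_coverage"],
    )


def test_normalize_empty_is_empty():
    out = normalize_enrollment(_spans([]))
    assert out.empty


def test_abutting_spans_with_same_flags_merge():
    out = normalize_enrollment(
        _spans(
            [
                ("p1", "2011-01-01", "2011-03-31", True, True),
                ("p1", "2011-04-01", "2011-06-30", True, True),
            ]
        )
    )
    assert len(out) == 1
    assert out.loc[0, "span_start"] == pd.Timestamp("2011-01-01")
    assert out.loc[0, "span_end"] == pd.Timestamp("2011-06-30")


def test_different_flags_do_not_merge():
    out = normalize_enrollment(
        _spans(
            [
                ("p1", "2011-01-01", "2011-03-31", True, False),
                ("p1", "2011-04-01", "2011-06-30", True, True),
            ]
        )
    )
    assert len(out) == 2


def _day_set(df):
    days = set()
    for r in df.itertuples(index=False):
        cur = r.span_start
        while cur <= r.span_end:
            days.add((r.patient_id, r.medical_coverage, r.pharmacy_coverage, cur))
            cur += pd.Timedelta(days=1)
    return days


@settings(max_examples=40, deadline=None, derandomize=True)
@given(
    st.lists(
        st.tuples(
            st.integers(0, 300),
            st.integers(0, 40),
            st.booleans(),
        ),
        min_size=0,
        max_size=50,
    )
)
def test_normalization_preserves_covered_days_and_is_idempotent(raw):
    base = pd.Timestamp("2011-01-01")
    spans = _spans(
        [
            ("p1", base + pd.Timedelta(days=o), base + pd.Timedelta(days=o + ln), True, flag)
            for o, ln, flag in raw
        ]
    )
    out = normalize_enrollment(spans)
    assert _day_set(out) == _day_set(spans)
    pd.testing.assert_frame_equal(normalize_enrollment(out), out)
    # merged spans within a flag group are separated by > 1 day
    for _, grp in out.groupby(["patient_id", "medical_coverage", "pharmacy_coverage"]):
        starts = list(grp["span_start"])
        ends = list(grp["span_end"])
        for nxt, prev_end in zip(starts[1:], ends[:-1]):
            assert (nxt - prev_end).days > 1
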