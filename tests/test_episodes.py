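"""Episode grouping: gap-merge semantics, hierarchy, strata, oracle checks."""

import numpy as np
import pandas as pd
import pytest

from vocburden.episodes import (
    SettingHierarchy,
    VOC_DX_CODES,
    build_episode_table,
    classify_setting,
    count_and_stratify,
    identify_voc_claims,
    merge_into_episodes,
)

from conftest import make_medical


def _claims(intervals, pid="p1", dx=("28262",), pos="outpatient_er"):
    return make_medical(
        [
            (f"c{i}", pid, s, e, dx, pos)
            for i, (s, e) in enumerate(intervals)
        ]
    )


# ---------------------------------------------------------------------------
# VOC claim identification


def test_scd_but_not_voc_code_excluded():
    claims = _claims([("2011-01-01", "2011-01-01")], dx=("28260",))
    assert identify_voc_claims(claims).empty


def test_voc_code_in_any_position_included():
    claims = _claims([("2011-01-01", "2011-01-01")], dx=("4019", "78060", "28262"))
    assert len(identify_voc_claims(claims)) == 1


def test_empty_input_empty_output():
    claims = _claims([])
    assert identify_voc_claims(claims).empty


# ---------------------------------------------------------------------------
# Gap merging


@pytest.mark.parametrize(
    "intervals,gap,expected_n",
    [
        # single-day claims on day 1 and day 4: separation 3 -> merge
        ([("2011-01-01", "2011-01-01"), ("2011-01-04", "2011-01-04")], 3, 1),
        # day 1 and day 5: separation 4 -> two episodes
        ([("2011-01-01", "2011-01-01"), ("2011-01-05", "2011-01-05")], 3, 2),
        # overlapping intervals always merge
        ([("2011-01-01", "2011-01-10"), ("2011-01-02", "2011-01-02")], 3, 1),
        ([("2011-01-01", "2011-01-01")], 0, 1),
    ],
)
def test_gap_rule_examples(intervals, gap, expected_n):
    eps = merge_into_episodes(_claims(intervals), gap_days=gap)
    assert len(eps) == expected_n


def test_overlapping_inpatient_er_episode_window():
    claims = make_medical(
        [
            ("a", "p1", "2011-01-01", "2011-01-10", ("28262",), "inpatient"),
            ("b", "p1", "2011-01-02", "2011-01-02", ("28262",), "outpatient_er"),
        ]
    )
    (ep,) = merge_into_episodes(claims, gap_days=3)
    assert ep.start == pd.Timestamp("2011-01-01")
    assert ep.end == pd.Timestamp("2011-01-10")
    assert ep.duration_days == 10


def test_mixed_patients_hard_error():
    claims = pd.concat([_claims([("2011-01-01", "2011-01-01")], pid="p1"),
                        _claims([("2011-01-02", "2011-01-02")], pid="p2")])
    with pytest.raises(ValueError, match="one patient"):
        merge_into_episodes(claims)


# ---------------------------------------------------------------------------
# Brute-force oracle (union-find over the interval-gap graph)


def brute_force_episodes(intervals, gap):
    """Connected components where intervals i,j link iff their day gap <= gap."""
    n = len(intervals)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        si, ei = intervals[i]
        for j in range(i + 1, n):
            sj, ej = intervals[j]
            if max((sj - ei), (si - ej)) <= gap:
                parent[find(i)] = find(j)
    comps = {}
    for i in range(n):
        comps.setdefault(find(i), []).append(i)
    out = []
    for members in comps.values():
        out.append(
            (
                min(intervals[i][0] for i in members),
                max(intervals[i][1] for i in members),
                frozenset(members),
            )
        )
    return sorted(out)


def random_claim_sets(n_sets, rng, max_claims=40, max_len=30, day_range=120):
    for _ in range(n_sets):
        n = int(rng.integers(1, max_claims + 1))
        starts = rng.integers(0, day_range, n)
        lengths = rng.integers(0, max_len, n)
        yield [(int(s), int(s + l)) for s, l in zip(starts, lengths)]


def _as_claims(intervals):
    base = pd.Timestamp("2011-01-01")
    return _claims(
        [
            (base + pd.Timedelta(days=s), base + pd.Timedelta(days=e))
            for s, e in intervals
        ]
    )


def _merged_as_tuples(claims, gap):
    base = pd.Timestamp("2011-01-01")
    out = []
    for ep in merge_into_episodes(claims, gap_days=gap):
        members = frozenset(int(cid[1:]) for cid in ep.member_claim_ids)
        out.append(((ep.start - base).days, (ep.end - base).days, members))
    return sorted(out)


def test_merge_matches_oracle_on_random_sets():
    rng = np.random.default_rng(42)
    for intervals in random_claim_sets(200, rng):
        claims = _as_claims(intervals)
        assert _merged_as_tuples(claims, 3) == brute_force_episodes(intervals, 3)


def test_partition_and_separation_properties():
    rng = np.random.default_rng(11)
    for intervals in random_claim_sets(100, rng):
        claims = _as_claims(intervals)
        eps = merge_into_episodes(claims, gap_days=3)
        members = [cid for ep in eps for cid in ep.member_claim_ids]
        assert sorted(members) == sorted(claims["claim_id"])  # exactly once
        for prev, nxt in zip(eps, eps[1:]):
            assert (nxt.start - prev.end).days > 3


def test_episode_count_monotone_in_gap():
    rng = np.random.default_rng(5)
    for intervals in random_claim_sets(50, rng):
        claims = _as_claims(intervals)
        counts = [len(merge_into_episodes(claims, gap_days=g)) for g in range(11)]
        assert all(a >= b for a, b in zip(counts, counts[1:]))
        assert len(merge_into_episodes(claims, gap_days=10_000)) == 1


# ---------------------------------------------------------------------------
# Setting hierarchy


def test_inpatient_outranks_er():
    claims = make_medical(
        [
            ("a", "p1", "2011-01-01", "2011-01-01", ("28262",), "outpatient_er"),
            ("b", "p1", "2011-01-02", "2011-01-03", ("28262",), "inpatient"),
        ]
    )
    (ep,) = merge_into_episodes(claims)
    pos = dict(zip(claims["claim_id"], claims["pos_code"]))
    assert classify_setting(ep, pos) == "inpatient"


def test_single_office_claim_is_office():
    claims = _claims([("2011-01-01", "2011-01-01")], pos="independent_clinic")
    (ep,) = merge_into_episodes(claims)
    assert classify_setting(ep, {"c0": "independent_clinic"}) == "office"


def test_long_term_care_counts_as_outpatient():
    claims = make_medical(
        [
            ("a", "p1", "2011-01-01", "2011-01-01", ("28262",), "long_term_care"),
            ("b", "p1", "2011-01-02", "2011-01-02", ("28262",), "independent_clinic"),
        ]
    )
    (ep,) = merge_into_episodes(claims)
    pos = dict(zip(claims["claim_id"], claims["pos_code"]))
    assert classify_setting(ep, pos) == "outpatient"


def test_unmapped_pos_code_is_a_hard_error_naming_it():
    claims = _claims([("2011-01-01", "2011-01-01")], pos="spaceship")
    (ep,) = merge_into_episodes(claims)
    with pytest.raises(KeyError, match="spaceship"):
        classify_setting(ep, {"c0": "spaceship"})


# ---------------------------------------------------------------------------
# Counting and stratification


def test_stratification_bands():
    win = (pd.Timestamp("2011-01-01"), pd.Timestamp("2011-12-31"))
    days = [pd.Timestamp("2011-03-01") + pd.Timedelta(days=20 * i) for i in range(5)]
    assert count_and_stratify([], win) == (0, "0")
    assert count_and_stratify(days[:1], win) == (1, "1")
    assert count_and_stratify(days[:2], win) == (2, "2")
    assert count_and_stratify(days, win) == (5, "3+")
    # start after window end is not counted
    assert count_and_stratify([pd.Timestamp("2012-01-01")], win) == (0, "0")
    # start on the last window day counts
    assert count_and_stratify([pd.Timestamp("2011-12-31")], win) == (1, "1")


def test_episode_table_orders_and_ids(small_synth):
    bundle, _ = small_synth
    table = build_episode_table(bundle.medical, gap_days=3)
    # chronological within patient, VOC-coded members only
    for _, grp in table.groupby("patient_id"):
        assert grp["start"].is_monotonic_increasing
    voc_ids = set(identify_voc_claims(bundle.medical)["claim_id"])
    members = [cid for t in table["member_claim_ids"] for cid in t]
    assert set(members) <= voc_ids and len(members) == len(set(members))
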