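"""Shared fixtures: hand-built stress bundle and a small synthetic dataset."""

import pandas as pd
import pytest

from vocburden.synthetic import (
    GeneratorConfig,
    generate_dataset,
    generate_eligibility_stress_fixture,
)


@pytest.fixture(scope="session")
def stress():
    """(bundle, metadata) for the 12-patient eligibility stress fixture."""
    return generate_eligibility_stress_fixture()


@pytest.fixture(scope="session")
def small_synth():
    """(bundle, ground_truth) for a small seeded synthetic dataset."""
    return generate_dataset(GeneratorConfig(n_patients=150, seed=3))


def make_medical(rows):
    """Build a medical-claims frame from (claim_id, pid, start, end, dx, pos) rows."""
    recs = []
    for cid, pid, start, end, dx, pos in rows:
        recs.append(
            dict(
                claim_id=cid,
                patient_id=pid,
                service_start=pd.Timestamp(start),
                service_end=pd.Timestamp(end),
                dx_codes=tuple(dx),
                pos_code=pos,
                is_transfusion=False,
                paid_amount=0.0,
                service_year=pd.Timestamp(start).year,
            )
        )
    return pd.DataFrame(recs)
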