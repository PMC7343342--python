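#!/usr/bin/env python
"""Simulate the study's claims data.

Generates the default 5000-patient synthetic Medicaid-style dataset
(seed 7): patient demographics, medical claims with VOC episodes realized
as gap-separated claim clusters, pharmacy fills and enrollment spans,
plus the ground-truth episode table. The raw tables are bulky working
data, so they land under scratch/data/; downstream steps summarize them
into results/.
"""

from pathlib import Path

from vocburden.claims_model import write_bundle
from vocburden.pipeline import _dates_to_str
from vocburden.synthetic import GeneratorConfig, generate_dataset

OUT = Path(__file__).resolve().parent.parent / "scratch" / "data"


def main() -> None:
    config = GeneratorConfig.from_yaml(n_patients=5000, seed=7)
    bundle, truth = generate_dataset(config)
    write_bundle(bundle, OUT)
    _dates_to_str(truth).to_csv(OUT / "ground_truth.csv", index=False)
    fu = truth[truth["phase"] == "followup"]
    print(f"patients:          {len(bundle.patients)}")
    print(f"medical claims:    {len(bundle.medical)}")
    print(f"pharmacy fills:    {len(bundle.pharmacy)}")
    print(f"true VOC episodes: {len(truth)} ({len(fu)} in follow-up)")
    print(f"wrote tables to {OUT}")


if __name__ == "__main__":
    main()
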