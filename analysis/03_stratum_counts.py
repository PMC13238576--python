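#!/usr/bin/env python
"""Aggregate the simulated ED line list to zero-filled stratum-day counts.

Parses the line list, assigns each presentation an exposure region (residents
keep their SA2; visitors and unknown addresses take the hospital's region),
derives condition groups and age bands, then joins counts with the heatwave
exposure level, public holidays and PM2.5 for both index variants.
"""

import json
from pathlib import Path

import pandas as pd

from ntheat import outcomes, pipeline

ROOT = Path(__file__).resolve().parents[1]
FIXTURE_DIR = ROOT / "scratch" / "fixtures" / "tiny"
RESULTS = ROOT / "results"


def main() -> None:
    if not (FIXTURE_DIR / "manifest.json").exists():
        from ntheat import synthetic

        synthetic.make_fixture("tiny", seed=7, out_dir=FIXTURE_DIR)
    summary = pipeline.run_pipeline(FIXTURE_DIR, ROOT / "scratch" / "pipeline_tiny")
    records, _ = outcomes.parse_ed_records(FIXTURE_DIR / "ed.csv")
    records = outcomes.derive_demographics(records)

    RESULTS.mkdir(exist_ok=True)
    group_counts = records["condition_group"].value_counts().rename_axis("group")
    group_counts.to_csv(RESULTS / "condition_group_counts.csv")
    sd = pd.read_csv(ROOT / "scratch" / "pipeline_tiny" / "stratum_days_T.csv")
    print(f"parsed {len(records)} presentations; "
          f"{summary['parse']['rejected']} rejected by reason")
    print(f"stratum-days (variant T): {len(sd)} rows, "
          f"{sd['count'].sum()} events conserved")
    print("top condition groups:")
    print(group_counts.head(5).to_string())


if __name__ == "__main__":
    main()
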