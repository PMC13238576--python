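#!/usr/bin/env python
"""Generate the synthetic input data sets used by the downstream analyses.

Writes the 'tiny' fixture (2 regions, 2 analysis years, baseline 5
presentations/day) under scratch/fixtures/tiny and echoes its manifest to
results/.  The 'powered' configuration (40 regions x 4 years, baseline
20/day, true severe/extreme RR 1.06, low-intensity RR 1.015) is used
in-memory by the parameter-recovery analysis and is only summarized here.
"""

import json
from pathlib import Path

from ntheat import synthetic

ROOT = Path(__file__).resolve().parents[1]
FIXTURE_DIR = ROOT / "scratch" / "fixtures" / "tiny"
SEED = 7


def main() -> None:
    manifest = synthetic.make_fixture("tiny", seed=SEED, out_dir=FIXTURE_DIR)
    (ROOT / "results").mkdir(exist_ok=True)
    (ROOT / "results" / "tiny_fixture_manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True)
    )
    print(f"tiny fixture written to {FIXTURE_DIR}")
    print(f"  regions: {manifest['weather_config']['n_regions']}, "
          f"analysis years: {manifest['analysis_years']}")
    print(f"  true RRs: low {manifest['true_rr_low']}, "
          f"severe/extreme {manifest['true_rr_severe_extreme']}")
    powered = synthetic.FIXTURES["powered"]
    print("powered configuration (used in-memory by 04): "
          f"{powered.weather.n_regions} regions, years {powered.analysis_years}, "
          f"baseline {powered.ed.baseline_rate}/day")


if __name__ == "__main__":
    main()
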