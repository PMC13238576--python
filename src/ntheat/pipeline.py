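"""End-to-end driver: fixture files in, calendars, fits and report tables out.

Reads the standard input file set (climate.csv, ed.csv, pm25.csv,
holidays.csv, weights.csv, manifest.json), builds both heatwave calendars
(temperature-only and heat-index variants), aggregates stratum-day counts and
fits the conditional quasi-Poisson model per variant, then writes the
descriptive surfaces.  All outputs are plain CSV/JSON with no timestamps, so
a rerun with identical inputs is byte-identical.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import pandas as pd

from . import casecrossover, climate, ehf, outcomes, reporting


def run_pipeline(input_dir, out_dir, use_pm25: bool = True) -> dict:
    """Run every stage on a fixture directory; returns a small result summary."""
    inp, out = Path(input_dir), Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = json.loads((inp / "manifest.json").read_text())
    ref0, ref1 = manifest["reference_years"]
    an0, an1 = manifest["analysis_years"]

    series = climate.read_region_daily_csv(inp / "climate.csv")
    regions = sorted(series)
    hospital_region = {f"H:{r}": r for r in regions}

    calendars: dict[str, pd.DataFrame] = {}
    thresholds = []
    for variant in ("T", "TH"):
        params = ehf.EHFParams(variant=variant, ref_start=ref0, ref_end=ref1)
        cal, thr = ehf.build_calendars(series, params)
        cal = cal[(cal["date"].dt.year >= an0) & (cal["date"].dt.year <= an1)]
        calendars[variant] = cal.reset_index(drop=True)
        thresholds.extend(asdict(t) for t in thr)
    (out / "thresholds.json").write_text(json.dumps(thresholds, indent=2, sort_keys=True))
    for variant, cal in calendars.items():
        cal.assign(date=cal["date"].dt.strftime("%Y-%m-%d")).to_csv(
            out / f"calendar_{variant}.csv", index=False, float_format="%.6f"
        )

    records, parse_report = outcomes.parse_ed_records(inp / "ed.csv")
    records, assign_report = outcomes.assign_exposure_region(
        records, hospital_region, set(regions)
    )
    records = outcomes.derive_demographics(records)
    holidays = pd.read_csv(inp / "holidays.csv")
    pm25 = pd.read_csv(inp / "pm25.csv")

    summary: dict = {"parse": parse_report, "assign": assign_report, "fits": {}}
    for variant, cal in calendars.items():
        stratum_days, agg_report = outcomes.aggregate_counts(records, cal, holidays, pm25)
        stratum_days.assign(date=stratum_days["date"].dt.strftime("%Y-%m-%d")).to_csv(
            out / f"stratum_days_{variant}.csv", index=False, float_format="%.6f"
        )
        fit = casecrossover.fit_stratum_days(stratum_days, use_pm25=use_pm25)
        (out / f"fit_{variant}.json").write_text(
            json.dumps(fit.to_dict(), indent=2, sort_keys=True)
        )
        casecrossover.summarize_rr(fit).to_csv(
            out / f"rate_ratios_{variant}.csv", index=False, float_format="%.6f"
        )
        summary["fits"][variant] = fit.to_dict() | {"aggregate": agg_report}

    ct = reporting.crosstab_indexes(calendars["T"], calendars["TH"])
    crosstab = ct.to_frame()
    crosstab.insert(0, "row", crosstab.index)
    crosstab.to_csv(out / "index_crosstab.csv", index=False)
    (out / "index_crosstab.json").write_text(
        json.dumps(
            {
                "both": ct.both, "t_only": ct.t_only, "th_only": ct.th_only,
                "neither": ct.neither, "t_only_pct": ct.t_only_pct,
                "th_only_pct": ct.th_only_pct,
            },
            indent=2, sort_keys=True,
        )
    )
    summary["crosstab"] = {"t_only_pct": ct.t_only_pct, "th_only_pct": ct.th_only_pct}
    return summary
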