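# ntheat

Heatwave exposure and emergency-department (ED) demand in the Northern
Territory of Australia: an Excess Heat Factor (EHF) engine with and without
humidity, and a space-time-stratified case-crossover analysis of daily
presentation counts. The package is written for environmental
epidemiologists who need the full pipeline — climate ingestion, heatwave
classification, outcome aggregation, conditional quasi-Poisson regression
and descriptive reporting — runnable end-to-end on synthetic data, because
the NT health and climate inputs themselves are available only by request.

## The model

**Exposure.** For a daily driver x (mean temperature for variant T; an
apparent-temperature heat index combining temperature and relative humidity
for variant TH) the EHF at day i is

    EHI_sig(i)  = mean(x[i..i+2]) − T95
    EHI_accl(i) = mean(x[i..i+2]) − mean(x[i−30..i−1])
    EHF(i)      = EHI_sig(i) × max(1, EHI_accl(i))      [°C²]

where T95 is the climatological 95th percentile of the driver over a fixed
reference period (default 1960–2011). Positive EHF marks a heatwave day;
severity is low (EHF < EHF85), severe (EHF ≥ EHF85) or extreme
(EHF ≥ 3·EHF85), with EHF85 the 85th percentile of positive reference-period
EHF. Severe and extreme are combined for analysis.

**Outcome model.** Daily counts y within a stratum s = (region, year, month,
day-of-week) follow a conditional (quasi-)Poisson model,

    count ~ HeatwaveSeverity + PublicHoliday + PM2.5,  eliminate stratum

fitted by maximizing the stratum-conditioned likelihood (Newton iterations),
with a Pearson dispersion factor scaling the covariance. Results are rate
ratios RR = exp(β) with 95% Wald intervals; percent change is (RR − 1)×100.

## Worked example

Generate the bundled two-region synthetic fixture and run the full pipeline:

```python
from ntheat import synthetic, pipeline

synthetic.make_fixture("tiny", seed=7, out_dir="scratch/fixtures/tiny")
summary = pipeline.run_pipeline("scratch/fixtures/tiny", "scratch/pipeline_tiny")

fit = summary["fits"]["T"]
for term, rr, lo, hi in zip(fit["terms"], fit["rr"], fit["ci_low"], fit["ci_high"]):
    print(f"{term:18s} RR {rr:.3f} (95% CI {lo:.3f}-{hi:.3f})")
```

prints

```
hw_low             RR 1.198 (95% CI 1.065-1.348)
hw_severe_extreme  RR 1.267 (95% CI 0.998-1.608)
holiday            RR 1.115 (95% CI 0.913-1.361)
pm25               RR 0.999 (95% CI 0.993-1.006)
```

Read: on this two-region, two-year fixture, presentations on low-intensity
heatwave days are estimated 19.8% above comparable non-heatwave days in the
same stratum, and 26.7% above on severe/extreme days — wide intervals, as
expected at this scale (the generating rate ratios are 1.015 and 1.06; the
40-region "powered" configuration recovers them with near-nominal coverage,
see `results/parameter_recovery.json` after running the analysis scripts).

The numbered drivers under `analysis/` run the same stages as a narrative
sequence — `01_simulate_fixtures.py` through `05_descriptive_report.py` —
writing their tables under `results/`.

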