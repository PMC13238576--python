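{
  "description": "Published summary tabulations for the Northern Territory heatwave surveillance record, 68 SA2 regions, 2001-2023: heatwave location-day counts by index variant and severity, the two-index agreement cross-tabulation, and selected emergency-department presentation counts.",
  "n_regions": 68,
  "start_year": 2001,
  "end_year": 2023,
  "crosstab_location_days": {
    "both": 13187,
    "t_only": 17580,
    "th_only": 12996,
    "neither": 527437
  },
  "heatwave_days": {
    "T": {"total": 30767, "severe": 5454, "extreme": 200},
    "TH": {"total": 26183, "severe": 3256, "extreme": 572, "october_march": 25523}
  },
  "ed_presentations": {
    "low_T_total": 151129,
    "low_T_aboriginal": 72931
  },
  "nhulunbuy_heatwave_days_T": {"low": 523, "severe": 90, "extreme": 12}
}
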