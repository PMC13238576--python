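"""Emergency-department line-list parsing, grouping and stratum-day aggregation.

Each presentation record carries a date, hospital, residential region, basic
demographics and an ICD-10-AM shortlist diagnosis code.  This module derives
the analysis groupings (condition group, age band, socioeconomic band,
residency class), assigns every presentation an exposure region (residential
SA2 for NT residents; the hospital's SA2 for visitors and unknown addresses),
and aggregates to zero-filled region-day counts joined with heatwave exposure
level, public-holiday flag and PM2.5.

Stratum keys for the case-crossover design are (region, year, month,
ISO day-of-week).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
import yaml

log = logging.getLogger(__name__)

ICD_CODE_RE = re.compile(r"^[A-Z][0-9]{2}(\.[0-9A-Z]{1,4})?$")

UNCLASSIFIED = "other_unclassified"

ED_COLUMNS = [
    "date",
    "hospital_id",
    "region_id",
    "residency_hint",
    "age_years",
    "sex",
    "indigenous_status",
    "icd_code",
]

AGE_BAND_EDGES = [(0, 4, "<5"), (5, 18, "5-18"), (19, 49, "19-49"), (50, 64, "50-64")]
AGE_BAND_TOP = "65+"
UNKNOWN = "unknown"

#: Socioeconomic (IRSD decile) banding presets.  ``deciles`` gives the closed
#: decile range per band.  Two published groupings circulate for the same NT
#: analysis; both are provided and the choice is an explicit argument.
IRSD_SCHEMES = {
    "methods": {
        "most_disadvantaged": (1, 3),
        "moderate": (4, 7),
        "most_advantaged": (8, 10),
    },
    "table": {
        "most_disadvantaged": (1, 3),
        "moderate": (4, 6),
        "most_advantaged": (7, 10),
    },
}


# ---------------------------------------------------------------------------
# Condition-group map
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class _Entry:
    kind: str  # stem | stem_range | exact | decimal_range
    start: str
    end: str

    def matches(self, code: str) -> bool:
        stem = code[:3]
        if self.kind == "stem":
            return stem == self.start
        if self.kind == "stem_range":
            return self.start <= stem <= self.end and stem[0] == self.start[0]
        if self.kind == "exact":
            return code == self.start
        # decimal range, same stem: numeric comparison of the suffix
        if stem != self.start[:3] or "." not in code:
            return False
        lo = float("0" + self.start[3:])
        hi = float("0" + self.end[3:])
        try:
            val = float("0." + code.split(".", 1)[1])
        except ValueError:
            return False
        return lo <= val <= hi


def _compile_entry(spec: str) -> _Entry:
    if "-" in spec:
        start, end = spec.split("-")
        if "." in start or "." in end:
            if start[:3] != end[:3]:
                raise ValueError(f"decimal range must share a stem: {spec}")
            return _Entry("decimal_range", start, end)
        if not start <= end or start[0] != end[0]:
            raise ValueError(f"malformed code range: {spec}")
        return _Entry("stem_range", start, end)
    if "." in spec:
        return _Entry("exact", spec, spec)
    return _Entry("stem", spec, spec)


class ConditionGroupMap:
    """Ordered ICD-10-AM shortlist code ranges; first matching group wins."""

    def __init__(self, groups: list[dict]):
        self.groups = [
            (g["name"], g.get("label", g["name"]), [_compile_entry(str(c)) for c in g["codes"]])
            for g in groups
        ]
        self._malformed = 0

    @property
    def names(self) -> list[str]:
        return [name for name, _, _ in self.groups]

    def map_code(self, code) -> str:
        """Group name for one ICD code; malformed or unlisted codes map to other/unclassified."""
        if code is None or (isinstance(code, float) and np.isnan(code)):
            return UNCLASSIFIED
        code = str(code).strip().upper()
        if not ICD_CODE_RE.match(code):
            self._malformed += 1
            log.debug("malformed ICD code %r -> %s", code, UNCLASSIFIED)
            return UNCLASSIFIED
        for name, _, entries in self.groups:
            if any(e.matches(code) for e in entries):
                return name
        return UNCLASSIFIED

    def map_codes(self, codes: pd.Series) -> pd.Series:
        uniq = codes.astype("object").drop_duplicates()
        lookup = {c: self.map_code(c) for c in uniq}
        return codes.map(lookup).fillna(UNCLASSIFIED)


def load_condition_groups() -> ConditionGroupMap:
    """The shortlist condition-group map shipped with the package."""
    text = resources.files("ntheat.data").joinpath("condition_groups.yaml").read_text()
    return ConditionGroupMap(yaml.safe_load(text))


# ---------------------------------------------------------------------------
# Line-list parsing
# ---------------------------------------------------------------------------

_SEX_MAP = {"m": "male", "male": "male", "f": "female", "female": "female"}
_INDIG_MAP = {
    "aboriginal": "aboriginal",
    "a": "aboriginal",
    "non-aboriginal": "non_aboriginal",
    "non_aboriginal": "non_aboriginal",
    "n": "non_aboriginal",
}


def parse_ed_records(path_or_df) -> tuple[pd.DataFrame, dict]:
    """Parse the ED line list; invalid rows are rejected and counted by reason.

    Unknown categorical values are preserved as ``unknown``, never dropped.
    Returns (records, report) where report counts rows read, kept and
    rejected per reason.
    """
    if isinstance(path_or_df, pd.DataFrame):
        df = path_or_df.copy()
    else:
        df = pd.read_csv(path_or_df, dtype=str)
    missing = [c for c in ED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"ED line list is missing mandatory column(s) {missing}")
    report = {"n_read": len(df), "rejected": {}}

    dates = pd.to_datetime(df["date"], format="%Y-%m-%d", errors="coerce")
    bad_date = dates.isna()
    if bad_date.any():
        report["rejected"]["bad_date"] = int(bad_date.sum())
    df = df.loc[~bad_date].copy()
    df["date"] = dates[~bad_date]

    age = pd.to_numeric(df["age_years"], errors="coerce")
    age[age < 0] = np.nan
    df["age_years"] = age

    sex = df["sex"].astype(str).str.strip().str.lower()
    df["sex"] = sex.map(_SEX_MAP).fillna(UNKNOWN)
    ind = df["indigenous_status"].astype(str).str.strip().str.lower()
    df["indigenous_status"] = ind.map(_INDIG_MAP).fillna(UNKNOWN)
    df["icd_code"] = df["icd_code"].astype(str).str.strip().str.upper().replace(
        {"": None, "NAN": None, "NONE": None}
    )
    report["n_kept"] = len(df)
    return df.reset_index(drop=True), report


def assign_exposure_region(
    records: pd.DataFrame,
    hospital_region: dict[str, str],
    known_regions: set[str],
) -> tuple[pd.DataFrame, dict]:
    """Attach exposure_region and residency class to each record.

    NT residential regions keep their own region; visitors (non-NT address)
    and unknown/missing addresses take the SA2 of the hospital attended.
    Records at hospitals absent from the registry are rejected and counted.
    """
    df = records.copy()
    hosp_region = df["hospital_id"].map(hospital_region)
    unknown_hosp = hosp_region.isna()
    report = {"rejected_unknown_hospital": int(unknown_hosp.sum())}
    df = df.loc[~unknown_hosp].copy()
    hosp_region = hosp_region[~unknown_hosp]

    region = df["region_id"].astype("object").where(df["region_id"].notna(), None)
    hint = (
        df["residency_hint"].astype(str).str.strip().str.lower().replace("nan", "")
        if "residency_hint" in df
        else pd.Series("", index=df.index)
    )
    in_registry = region.map(lambda r: r in known_regions if r is not None else False)
    is_visitor = hint.isin(("non_nt", "visitor", "interstate", "overseas"))
    resident = in_registry & ~is_visitor

    df["residency"] = np.where(resident, "resident", np.where(is_visitor, "visitor", UNKNOWN))
    df["exposure_region"] = np.where(resident, region, hosp_region)
    return df.reset_index(drop=True), report


def derive_demographics(
    records: pd.DataFrame,
    irsd_decile_by_region: dict[str, int] | None = None,
    irsd_scheme: str = "methods",
    condition_map: ConditionGroupMap | None = None,
) -> pd.DataFrame:
    """Attach age_band, irsd_band and condition_group labels (raw fields untouched)."""
    df = records.copy()
    age = df["age_years"]
    band = pd.Series(UNKNOWN, index=df.index, dtype=object)
    for lo, hi, label in AGE_BAND_EDGES:
        band[(age >= lo) & (age <= hi)] = label
    band[age >= 65] = AGE_BAND_TOP
    df["age_band"] = band

    if irsd_decile_by_region is not None:
        scheme = IRSD_SCHEMES[irsd_scheme]
        decile = df["region_id"].map(irsd_decile_by_region)
        irsd = pd.Series(UNKNOWN, index=df.index, dtype=object)
        for name, (lo, hi) in scheme.items():
            irsd[(decile >= lo) & (decile <= hi)] = name
        df["irsd_band"] = irsd
    if condition_map is None:
        condition_map = load_condition_groups()
    df["condition_group"] = condition_map.map_codes(df["icd_code"])
    return df


# ---------------------------------------------------------------------------
# Stratum-day aggregation
# ---------------------------------------------------------------------------

def _holiday_flags(holidays: pd.DataFrame | None, regions, dates) -> pd.DataFrame:
    """Long (region_id, date, holiday) frame from a scoped holiday calendar."""
    grid = pd.MultiIndex.from_product([regions, dates], names=["region_id", "date"])
    flags = pd.Series(False, index=grid, name="holiday")
    if holidays is not None and len(holidays):
        h = holidays.copy()
        h["date"] = pd.to_datetime(h["date"])
        for _, row in h.iterrows():
            if str(row.get("scope", "all")) in ("all", "territory", "territory-wide"):
                for r in regions:
                    if (r, row["date"]) in flags.index:
                        flags.loc[(r, row["date"])] = True
            elif (row["scope"], row["date"]) in flags.index:
                flags.loc[(row["scope"], row["date"])] = True
    return flags.reset_index()


def aggregate_counts(
    records: pd.DataFrame,
    calendar: pd.DataFrame,
    holidays: pd.DataFrame | None = None,
    pm25: pd.DataFrame | None = None,
    record_filter: pd.Series | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Zero-filled stratum-day counts for one outcome subset.

    ``calendar`` is the long severity calendar (region_id, date,
    exposure_level) defining the analysis span; a row is produced for every
    region-date it contains, with the count of filtered records, the exposure
    level, the public-holiday flag and PM2.5 (NaN where missing).  Records
    dated outside the calendar span are excluded and counted.

    Returns (stratum_days, report).
    """
    if record_filter is not None:
        records = records.loc[record_filter]
    cal = calendar[["region_id", "date", "exposure_level"]].copy()
    cal["date"] = pd.to_datetime(cal["date"])
    span_keys = pd.MultiIndex.from_frame(cal[["region_id", "date"]])

    rec_keys = pd.MultiIndex.from_arrays(
        [records["exposure_region"], pd.to_datetime(records["date"])]
    )
    inside = rec_keys.isin(span_keys)
    n_outside = int((~inside).sum())
    counts = (
        pd.Series(1, index=rec_keys[inside])
        .groupby(level=[0, 1])
        .sum()
        .reindex(span_keys, fill_value=0)
    )
    out = cal.copy()
    out["count"] = counts.to_numpy()

    regions = sorted(out["region_id"].unique())
    dates = pd.DatetimeIndex(sorted(out["date"].unique()))
    flags = _holiday_flags(holidays, regions, dates)
    out = out.merge(flags, on=["region_id", "date"], how="left")
    out["holiday"] = out["holiday"].fillna(False).astype(bool)

    if pm25 is not None and len(pm25):
        p = pm25.copy()
        p["date"] = pd.to_datetime(p["date"])
        out = out.merge(
            p[["region_id", "date", "pm25_ugm3"]], on=["region_id", "date"], how="left"
        )
    else:
        out["pm25_ugm3"] = np.nan
    n_missing_pm25 = int(out["pm25_ugm3"].isna().sum())

    out["year"] = out["date"].dt.year
    out["month"] = out["date"].dt.month
    out["dow"] = out["date"].dt.dayofweek + 1  # ISO: Monday = 1
    report = {"n_records_outside_span": n_outside, "n_missing_pm25": n_missing_pm25}
    if n_outside:
        log.info("aggregate_counts: %d record(s) outside the calendar span excluded", n_outside)
    cols = [
        "region_id", "date", "year", "month", "dow",
        "count", "exposure_level", "holiday", "pm25_ugm3",
    ]
    return out[cols], report
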