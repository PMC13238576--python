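"""Descriptive surfaces: agreement cross-tabulations, trends, period comparisons.

Everything here reduces heatwave calendars and grouped presentation records
to the summary tables an epidemiological report prints: a 2x2 cross-tab of
location-days by the two index variants with discordance percentages,
annual heatwave-day counts with Gamma log-link trendlines, characteristics
tables (counts and column percentages), and early-vs-late period comparisons
in percentage points.  Percentages are rounded half-up at one decimal.
"""

from __future__ import annotations

import calendar as _calendar
import json
import logging
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from importlib import resources

import numpy as np
import pandas as pd
import statsmodels.api as sm

log = logging.getLogger(__name__)


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Decimal half-up rounding (1.25 -> 1.3 at one digit), as tables print."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def location_days(n_regions: int, start_year: int, end_year: int) -> int:
    """Total location-days: regions x (365 or 366) summed over calendar years."""
    days = sum(366 if _calendar.isleap(y) else 365 for y in range(start_year, end_year + 1))
    return n_regions * days


def column_percentage(count: int, total: int) -> float:
    """Column percentage at one decimal, half-up; NaN when the column is empty."""
    if total == 0:
        return float("nan")
    return round_half_up(100.0 * count / total, 1)


def load_nt_summary() -> dict:
    """Published NT 2001-2023 summary tabulations shipped with the package."""
    text = resources.files("ntheat.data").joinpath(
        "nt_heatwave_summary_2001_2023.json"
    ).read_text()
    return json.loads(text)


# ---------------------------------------------------------------------------
# Two-index agreement
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class IndexCrosstab:
    """2x2 location-day agreement between the T and TH heatwave calendars."""

    both: int
    t_only: int
    th_only: int
    neither: int

    @property
    def total(self) -> int:
        return self.both + self.t_only + self.th_only + self.neither

    @property
    def t_margin(self) -> int:
        return self.both + self.t_only

    @property
    def th_margin(self) -> int:
        return self.both + self.th_only

    @property
    def t_only_pct(self) -> float:
        """Share of T-index heatwave days missed by the TH index (%)."""
        return column_percentage(self.t_only, self.t_margin)

    @property
    def th_only_pct(self) -> float:
        """Share of TH-index heatwave days missed by the T index (%)."""
        return column_percentage(self.th_only, self.th_margin)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "t_non_heatwave": [self.neither, self.th_only],
                "t_heatwave": [self.t_only, self.both],
            },
            index=["th_non_heatwave", "th_heatwave"],
        )


def crosstab_indexes(cal_t: pd.DataFrame, cal_th: pd.DataFrame) -> IndexCrosstab:
    """Cross-tabulate heatwave status over identical region-day spans.

    Both inputs are long calendars with region_id, date, severity (or
    exposure_level); a span mismatch is rejected.
    """
    kt = cal_t.set_index(["region_id", "date"]).sort_index()
    kth = cal_th.set_index(["region_id", "date"]).sort_index()
    if not kt.index.equals(kth.index):
        raise ValueError("calendars do not cover identical region-days")
    col = "severity" if "severity" in kt.columns else "exposure_level"
    hw_t = (kt[col] != "none").to_numpy()
    hw_th = (kth[col] != "none").to_numpy()
    return IndexCrosstab(
        both=int((hw_t & hw_th).sum()),
        t_only=int((hw_t & ~hw_th).sum()),
        th_only=int((~hw_t & hw_th).sum()),
        neither=int((~hw_t & ~hw_th).sum()),
    )


# ---------------------------------------------------------------------------
# Annual trend (Gamma GLM, log link)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TrendFit:
    """log E[count_t] = intercept + slope * t, t = years since the first year."""

    intercept: float
    slope: float
    n_years_used: int
    n_zero_dropped: int


def fit_gamma_trend(years, counts) -> TrendFit:
    """Gamma GLM with log link of annual counts on the year index.

    Zero-count years lie outside the Gamma support and are excluded with a
    logged note; at least three positive years are required.
    """
    years = np.asarray(years, dtype=float)
    counts = np.asarray(counts, dtype=float)
    pos = counts > 0
    n_zero = int((~pos).sum())
    if n_zero:
        log.info("fit_gamma_trend: excluded %d zero-count year(s)", n_zero)
    years, counts = years[pos], counts[pos]
    if len(years) < 3:
        raise ValueError("need at least 3 positive annual counts for a trend")
    t = years - years.min()
    if np.allclose(counts, counts[0]):
        # perfectly flat series: IRLS degenerates (zero deviance), answer is exact
        return TrendFit(
            intercept=float(np.log(counts[0])), slope=0.0,
            n_years_used=len(years), n_zero_dropped=n_zero,
        )
    Xd = sm.add_constant(t)
    model = sm.GLM(counts, Xd, family=sm.families.Gamma(link=sm.families.links.Log()))
    res = model.fit()
    return TrendFit(
        intercept=float(res.params[0]),
        slope=float(res.params[1]),
        n_years_used=len(years),
        n_zero_dropped=n_zero,
    )


def heatwave_trend(
    calendar: pd.DataFrame,
    zone_map: dict[str, str] | None = None,
    intensity: str = "any",
) -> pd.DataFrame:
    """Annual heatwave location-day counts per climate zone with fitted trends.

    ``intensity`` selects which days count: "any" (all heatwave days), "low"
    or "severe_extreme".  All-zero series are skipped with a log entry.
    Returns one row per zone: zone, intercept, slope, n_years_used,
    n_zero_dropped.
    """
    cal = calendar.copy()
    cal["date"] = pd.to_datetime(cal["date"])
    cal["year"] = cal["date"].dt.year
    if intensity == "any":
        hit = cal["exposure_level"] != "none"
    else:
        hit = cal["exposure_level"] == intensity
    cal["hit"] = hit.astype(int)
    cal["zone"] = (
        cal["region_id"].map(zone_map) if zone_map else "all"
    )
    rows = []
    for zone, grp in cal.groupby("zone"):
        annual = grp.groupby("year")["hit"].sum()
        if (annual == 0).all():
            log.info("heatwave_trend: zone %s has no heatwave days; trend skipped", zone)
            continue
        fit = fit_gamma_trend(annual.index.to_numpy(), annual.to_numpy())
        rows.append(
            {
                "zone": zone,
                "intercept": fit.intercept,
                "slope": fit.slope,
                "n_years_used": fit.n_years_used,
                "n_zero_dropped": fit.n_zero_dropped,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Characteristics table
# ---------------------------------------------------------------------------

def descriptive_table(
    records: pd.DataFrame,
    calendars: dict[str, pd.DataFrame],
    characteristics: list[str],
) -> pd.DataFrame:
    """Counts and column percentages per characteristic x intensity x variant.

    ``records`` carries exposure_region, date and the characteristic columns;
    ``calendars`` maps variant name to a long severity calendar.  Each
    variant-intensity column counts presentations on that variant's days at
    that intensity; percentages are of the column total (suppressed where the
    column is empty).
    """
    rec = records.copy()
    rec["date"] = pd.to_datetime(rec["date"])
    out_rows = []
    for variant, cal in calendars.items():
        cal = cal.copy()
        cal["date"] = pd.to_datetime(cal["date"])
        merged = rec.merge(
            cal[["region_id", "date", "exposure_level"]],
            left_on=["exposure_region", "date"],
            right_on=["region_id", "date"],
            how="inner",
        )
        for intensity in ("low", "severe_extreme"):
            sub = merged[merged["exposure_level"] == intensity]
            total = len(sub)
            out_rows.append(
                {
                    "variant": variant, "intensity": intensity,
                    "characteristic": "total", "category": "total",
                    "count": total, "pct": 100.0 if total else float("nan"),
                }
            )
            for char in characteristics:
                counts = sub[char].value_counts()
                for category, count in counts.items():
                    out_rows.append(
                        {
                            "variant": variant, "intensity": intensity,
                            "characteristic": char, "category": category,
                            "count": int(count),
                            "pct": column_percentage(int(count), total),
                        }
                    )
    return pd.DataFrame(out_rows)


# ---------------------------------------------------------------------------
# Period comparison
# ---------------------------------------------------------------------------

def period_comparison(
    calendar: pd.DataFrame,
    early: tuple[int, int],
    late: tuple[int, int],
    zone_map: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Percent of location-days meeting heatwave criteria in two periods.

    Periods are inclusive (start_year, end_year) pairs and must not overlap.
    Returns one row per zone x intensity with early/late percentages (one
    decimal, half-up) and the change in percentage points.
    """
    e0, e1 = early
    l0, l1 = late
    if e0 > e1 or l0 > l1:
        raise ValueError("periods must be (start_year, end_year) with start <= end")
    if not (e1 < l0 or l1 < e0):
        raise ValueError("periods must not overlap")
    cal = calendar.copy()
    cal["date"] = pd.to_datetime(cal["date"])
    cal["year"] = cal["date"].dt.year
    years = cal["year"]
    if not ((years.min() <= e0) and (e1 <= years.max()) and (l1 <= years.max()) and (years.min() <= l0)):
        raise ValueError("a period lies outside the calendar span")
    cal["zone"] = cal["region_id"].map(zone_map) if zone_map else "all"
    rows = []
    for zone, grp in cal.groupby("zone"):
        for intensity in ("low", "severe_extreme", "any"):
            hit = (grp["exposure_level"] != "none") if intensity == "any" else (
                grp["exposure_level"] == intensity
            )
            res = {}
            for name, (y0, y1) in (("early", (e0, e1)), ("late", (l0, l1))):
                in_period = (grp["year"] >= y0) & (grp["year"] <= y1)
                denom = int(in_period.sum())
                res[name] = 100.0 * int((hit & in_period).sum()) / denom if denom else float("nan")
            early_pct = round_half_up(res["early"], 1)
            late_pct = round_half_up(res["late"], 1)
            rows.append(
                {
                    "zone": zone,
                    "intensity": intensity,
                    "early_pct": early_pct,
                    "late_pct": late_pct,
                    # differenced after rounding, as printed tables are read
                    "change_points": round_half_up(late_pct - early_pct, 1),
                }
            )
    return pd.DataFrame(rows)
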