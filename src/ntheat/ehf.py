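"""Excess Heat Factor (EHF) heatwave detection and severity classification.

The EHF marks heatwave conditions as the product of two anomalies of a daily
driver series (mean temperature for the T variant, an apparent-temperature
heat index for the TH variant):

* significance index  EHI_sig(i)  = mean(driver over the 3-day window at i) - T95
* acclimatization     EHI_accl(i) = same 3-day mean - mean(driver over the
  preceding 30 days)
* EHF(i) = EHI_sig(i) * max(1, EHI_accl(i))   [degC^2]

T95 is a climatological percentile (default 95th) of the driver over a fixed
reference period; positive EHF marks a heatwave day.  Severity tiers compare
EHF against the 85th percentile (EHF85) of positive reference-period EHF
values: low (0 < EHF < EHF85), severe (>= EHF85), extreme (>= 3 x EHF85).
Severe and extreme are collapsed into one level for regression analysis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .climate import RegionDailySeries

log = logging.getLogger(__name__)

VARIANT_T = "T"
VARIANT_TH = "TH"

SEVERITY_LEVELS = ("none", "low", "severe", "extreme")
EXPOSURE_LEVELS = ("none", "low", "severe_extreme")


@dataclass(frozen=True)
class EHFParams:
    """Configuration of the EHF computation.

    ``sig_orientation`` selects whether the 3-day significance window looks
    forward from day i (days i..i+2, the default) or backward (days i-2..i);
    the 30-day acclimatization window always ends the day before the
    significance window starts.
    """

    variant: str = VARIANT_T
    ref_start: int = 1960
    ref_end: int = 2011
    climatology_percentile: float = 95.0
    severity_percentile: float = 85.0
    accl_window: int = 30
    sig_window: int = 3
    sig_orientation: str = "forward"
    extreme_multiplier: float = 3.0
    label_window_days: bool = False

    def __post_init__(self) -> None:
        if self.variant not in (VARIANT_T, VARIANT_TH):
            raise ValueError("variant must be 'T' or 'TH'")
        if not self.ref_start < self.ref_end:
            raise ValueError("reference start year must precede end year")
        for p in (self.climatology_percentile, self.severity_percentile):
            if not 0 < p < 100:
                raise ValueError("percentiles must lie in (0, 100)")
        if self.accl_window < 1 or self.sig_window < 1:
            raise ValueError("window lengths must be >= 1")
        if self.sig_orientation not in ("forward", "trailing"):
            raise ValueError("sig_orientation must be 'forward' or 'trailing'")


@dataclass(frozen=True)
class ClimatologyThresholds:
    """Reference statistics for one region and variant."""

    region_id: str
    variant: str
    t95: float
    ehf85: float


# ---------------------------------------------------------------------------
# Heat index (apparent temperature)
# ---------------------------------------------------------------------------

def compute_heat_index(tmean_c, rh_pct):
    """NWS heat index (apparent temperature) in degC.

    Rothfusz (1990) regression evaluated in degF with the standard NWS
    branch logic: below 40 degF the heat index is the temperature itself;
    otherwise the simple formula 0.5*(alpha + T) with
    alpha = 61 + 1.2*(T-68) + 0.094*RH is used, and when it reaches 80 degF
    the full regression applies with the low-humidity (RH < 13%, 80-112 degF)
    and high-humidity (RH > 85%, 80-87 degF) adjustments.

    Accepts scalars or arrays; RH outside [0, 100] is rejected.
    """
    t = np.asarray(tmean_c, dtype=float)
    rh = np.asarray(rh_pct, dtype=float)
    if not (np.all(np.isfinite(t)) and np.all(np.isfinite(rh))):
        raise ValueError("temperature and RH must be finite")
    if (rh < 0).any() or (rh > 100).any():
        raise ValueError("relative humidity must lie in [0, 100]")
    t, rh = np.broadcast_arrays(t, rh)

    t_f = t * 9.0 / 5.0 + 32.0
    alpha = 61.0 + (t_f - 68.0) * 1.2 + rh * 0.094
    simple = 0.5 * (alpha + t_f)

    # Full Rothfusz regression
    hi = (
        -42.379
        + 2.04901523 * t_f
        + 10.14333127 * rh
        - 0.22475541 * t_f * rh
        - 6.83783e-3 * t_f**2
        - 5.481717e-2 * rh**2
        + 1.22874e-3 * t_f**2 * rh
        + 8.5282e-4 * t_f * rh**2
        - 1.99e-6 * t_f**2 * rh**2
    )
    low_rh = (rh < 13) & (t_f >= 80) & (t_f <= 112)
    with np.errstate(invalid="ignore"):
        adj1 = ((13.0 - rh) / 4.0) * np.sqrt(
            np.clip((17.0 - np.abs(t_f - 95.0)) / 17.0, 0.0, None)
        )
    hi = np.where(low_rh, hi - adj1, hi)
    high_rh = (rh > 85) & (t_f >= 80) & (t_f <= 87)
    adj2 = ((rh - 85.0) / 10.0) * ((87.0 - t_f) / 2.0)
    hi = np.where(high_rh, hi + adj2, hi)

    out_f = np.where(t_f <= 40.0, t_f, np.where(simple > 79.0, hi, simple))
    out = (out_f - 32.0) * 5.0 / 9.0
    if np.isscalar(tmean_c) and np.isscalar(rh_pct):
        return float(out)
    return out


def driver_series(series: RegionDailySeries, params: EHFParams) -> pd.Series:
    """The daily driver for the configured variant, indexed by date.

    The T and TH pipelines are the same code path; only this series differs.
    """
    if params.variant == VARIANT_T:
        values = series.tmean_c
    else:
        if series.heat_index_c is not None:
            values = series.heat_index_c
        else:
            values = compute_heat_index(series.tmean_c, series.rh_pct)
    return pd.Series(values, index=series.dates, name="driver")


# ---------------------------------------------------------------------------
# Climatology and EHF series
# ---------------------------------------------------------------------------

def compute_climatology_threshold(driver: pd.Series, params: EHFParams) -> float:
    """Climatological percentile (default 95th) of the driver over the reference period.

    All calendar days of the reference years enter; linear-interpolation
    percentile definition.
    """
    years = driver.index.year
    sel = driver[(years >= params.ref_start) & (years <= params.ref_end)].dropna()
    if sel.empty:
        raise ValueError(
            f"reference period {params.ref_start}-{params.ref_end} does not overlap the series"
        )
    return float(np.percentile(sel.to_numpy(), params.climatology_percentile))


def compute_ehf_series(driver: pd.Series, t95: float, params: EHFParams) -> pd.DataFrame:
    """Per-day EHI_sig, EHI_accl and EHF for a gap-free daily driver series.

    Days whose significance or acclimatization window is incomplete are NaN.
    Returns a frame indexed by date with columns driver, ehi_sig, ehi_accl, ehf.
    """
    idx = pd.DatetimeIndex(driver.index)
    if len(idx) > 1 and not (np.diff(idx.asi8) == 24 * 3600 * 10**9).all():
        raise ValueError("driver series must be daily and gap-free")
    x = driver.astype(float)
    k, m = params.sig_window, params.accl_window
    sig = x.rolling(k).mean()
    if params.sig_orientation == "forward":
        # window at i covers days i..i+k-1; accl covers the m days before i
        sig = sig.shift(-(k - 1))
        accl_hist = x.rolling(m).mean().shift(1)
    else:
        # window at i covers days i-k+1..i; accl covers the m days before that
        accl_hist = x.rolling(m).mean().shift(k)
    if len(x) < m + k:
        log.warning(
            "series of %d days shorter than accl+sig windows (%d); all days undefined",
            len(x),
            m + k,
        )
    undefined = sig.isna() | accl_hist.isna()
    ehi_sig = (sig - t95).mask(undefined)
    ehi_accl = (sig - accl_hist).mask(undefined)
    ehf = ehi_sig * np.maximum(1.0, ehi_accl)
    out = pd.DataFrame(
        {"driver": x, "ehi_sig": ehi_sig, "ehi_accl": ehi_accl, "ehf": ehf}
    )
    out.index.name = "date"
    return out


def compute_severity_threshold(ehf: pd.DataFrame, params: EHFParams) -> float:
    """Severity percentile (default 85th) of strictly positive reference-period EHF."""
    years = ehf.index.year
    ref = ehf.loc[(years >= params.ref_start) & (years <= params.ref_end), "ehf"]
    pos = ref[ref > 0].dropna().to_numpy()
    if pos.size == 0:
        raise ValueError(
            "no positive EHF values in the reference period; climate input is "
            "degenerate or the reference window is wrong"
        )
    return float(np.percentile(pos, params.severity_percentile))


def classify_heatwave_days(
    ehf: pd.DataFrame, ehf85: float, params: EHFParams
) -> pd.DataFrame:
    """Label each day none/low/severe/extreme and collapse to analysis exposure levels.

    A day is a heatwave day iff its EHF is positive (the 3-day significance
    window embeds the persistence requirement).  Severity thresholds are
    closed below: EHF >= EHF85 is severe, EHF >= extreme_multiplier*EHF85 is
    extreme.  With ``label_window_days`` every day covered by a positive-EHF
    significance window inherits the most severe covering value.
    """
    if not ehf85 > 0:
        raise ValueError("EHF85 must be positive")
    e = ehf["ehf"].to_numpy(copy=True)
    if params.label_window_days:
        stacked = np.full((params.sig_window, len(e)), np.nan)
        for j in range(params.sig_window):
            shift = j if params.sig_orientation == "forward" else -j
            stacked[j] = np.roll(e, shift)
            if shift > 0:
                stacked[j, :shift] = np.nan
            elif shift < 0:
                stacked[j, shift:] = np.nan
        with np.errstate(invalid="ignore"):
            e = np.where(np.isnan(stacked).all(axis=0), np.nan, np.nanmax(stacked, axis=0))
    severity = np.full(len(e), "none", dtype=object)
    with np.errstate(invalid="ignore"):
        severity[e > 0] = "low"
        severity[e >= ehf85] = "severe"
        severity[e >= params.extreme_multiplier * ehf85] = "extreme"
    exposure = np.where(
        np.isin(severity, ("severe", "extreme")),
        "severe_extreme",
        np.where(severity == "low", "low", "none"),
    )
    out = pd.DataFrame(
        {"ehf": ehf["ehf"], "severity": severity, "exposure_level": exposure},
        index=ehf.index,
    )
    out.index.name = "date"
    return out


# ---------------------------------------------------------------------------
# Region-level driver and multi-region calendars
# ---------------------------------------------------------------------------

def heatwave_calendar(
    series: RegionDailySeries, params: EHFParams
) -> tuple[pd.DataFrame, ClimatologyThresholds, pd.DataFrame]:
    """Full EHF pipeline for one region: thresholds, EHF series, severity calendar."""
    drv = driver_series(series, params)
    t95 = compute_climatology_threshold(drv, params)
    ehf = compute_ehf_series(drv, t95, params)
    ehf85 = compute_severity_threshold(ehf, params)
    cal = classify_heatwave_days(ehf, ehf85, params)
    thresholds = ClimatologyThresholds(
        region_id=series.region_id, variant=params.variant, t95=t95, ehf85=ehf85
    )
    return cal, thresholds, ehf


def build_calendars(
    series: dict[str, RegionDailySeries], params: EHFParams
) -> tuple[pd.DataFrame, list[ClimatologyThresholds]]:
    """Severity calendars for every region, as one long frame.

    Columns: region_id, date, variant, ehf, severity, exposure_level.
    """
    frames = []
    thresholds = []
    for region_id in sorted(series):
        cal, thr, _ = heatwave_calendar(series[region_id], params)
        cal = cal.reset_index()
        cal.insert(0, "region_id", region_id)
        cal.insert(2, "variant", params.variant)
        frames.append(cal)
        thresholds.append(thr)
    return pd.concat(frames, ignore_index=True), thresholds


def with_variant(params: EHFParams, variant: str) -> EHFParams:
    """The same parameter set applied to the other driver variant."""
    return replace(params, variant=variant)
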