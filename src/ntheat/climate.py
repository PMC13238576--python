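"""Gridded climate ingestion and per-region daily weather series.

Turns hourly or daily gridded temperature / dewpoint fields (or a per-region
daily CSV) into one gap-free daily series of mean temperature and relative
humidity per spatial exposure unit (SA2-like region).  Humidity is derived
from temperature and dewpoint with the Magnus saturation-vapor-pressure form;
regional values are area-weighted means over grid cells with precomputed
weights.

Day boundaries follow Northern Territory civil time (UTC+9:30, no daylight
saving), so exposure days line up with emergency-department presentation
dates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import xarray as xr

log = logging.getLogger(__name__)

# Magnus / Alduchov-Eskridge saturation vapor pressure constants (hPa, degC)
MAGNUS_A = 6.1094
MAGNUS_B = 17.625
MAGNUS_C = 243.04

#: Northern Territory civil-time offset from UTC in hours (no DST).
NT_UTC_OFFSET_HOURS = 9.5

#: Plausible physical range for screen temperature and dewpoint, degC.
PLAUSIBLE_RANGE_C = (-20.0, 60.0)


def saturation_vapor_pressure(temperature_c):
    """Magnus saturation vapor pressure e_s(T) in hPa for T in degC."""
    t = np.asarray(temperature_c, dtype=float)
    return MAGNUS_A * np.exp(MAGNUS_B * t / (t + MAGNUS_C))


def derive_relative_humidity(temperature_c, dewpoint_c):
    """Relative humidity (%) from temperature and dewpoint, both in degC.

    RH = 100 * e_s(Td) / e_s(T) with the Magnus form.  Dewpoints above the
    temperature are physically impossible (supersaturation); those values are
    clamped to 100% and counted in a single logged warning.

    Returns a scalar for scalar input, otherwise an ndarray.  The result is
    clamped to [0, 100].
    """
    t = np.asarray(temperature_c, dtype=float)
    td = np.asarray(dewpoint_c, dtype=float)
    if not (np.all(np.isfinite(t)) and np.all(np.isfinite(td))):
        raise ValueError("temperature and dewpoint must be finite")
    n_super = int(np.count_nonzero(td > t))
    if n_super:
        log.warning(
            "dewpoint exceeds temperature for %d value(s); clamping RH to 100%%",
            n_super,
        )
    rh = 100.0 * saturation_vapor_pressure(td) / saturation_vapor_pressure(t)
    rh = np.clip(rh, 0.0, 100.0)
    if np.isscalar(temperature_c) and np.isscalar(dewpoint_c):
        return float(rh)
    return rh


@dataclass
class GridField:
    """A single-variable gridded field on a regular (time, y, x) grid.

    ``values`` has shape (n_times, ny, nx); ``mask`` marks missing cells
    (True = missing).  Cells are indexed row-major from the northwest corner,
    so region weights can reference flat indices portably.
    """

    name: str
    times: pd.DatetimeIndex
    values: np.ndarray
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("values must have shape (time, y, x)")
        self.times = pd.DatetimeIndex(self.times)
        if len(self.times) != self.values.shape[0]:
            raise ValueError("time axis length mismatch")
        if len(self.times) > 1:
            steps = np.diff(self.times.asi8)
            if not (steps > 0).all():
                raise ValueError("time axis must be strictly increasing")
            if len(set(steps)) != 1:
                raise ValueError("time axis must be equally spaced")
        if self.mask is None:
            self.mask = ~np.isfinite(self.values)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.values.shape:
                raise ValueError("mask shape must match values")
            self.mask = self.mask | ~np.isfinite(self.values)
        valid = self.values[~self.mask]
        lo, hi = PLAUSIBLE_RANGE_C
        if valid.size and ((valid < lo).any() or (valid > hi).any()):
            raise ValueError(
                f"{self.name}: values outside plausible range [{lo}, {hi}] degC"
            )

    @property
    def n_cells(self) -> int:
        return self.values.shape[1] * self.values.shape[2]

    def flat_values(self) -> np.ndarray:
        """(time, cell) view with masked cells as NaN."""
        out = np.where(self.mask, np.nan, self.values)
        return out.reshape(self.values.shape[0], -1)


def shift_to_local(field: GridField, utc_offset_hours: float = NT_UTC_OFFSET_HOURS) -> GridField:
    """Return a copy of ``field`` with the time axis shifted from UTC to local civil time."""
    return GridField(
        name=field.name,
        times=field.times + pd.Timedelta(hours=utc_offset_hours),
        values=field.values.copy(),
        mask=field.mask.copy(),
    )


def daily_aggregate(field: GridField, max_missing_hours: int = 0) -> GridField:
    """Aggregate an hourly field to local-calendar daily means.

    Timestamps are taken to already be in local civil time.  Partially covered
    first/last days are dropped (logged).  Per cell, a day is valid only when
    the number of missing hours does not exceed ``max_missing_hours``
    (default 0: all 24 hours required); invalid day-cells are masked.
    """
    if len(field.times) < 2:
        raise ValueError("hourly field needs at least two timestamps")
    step = field.times[1] - field.times[0]
    if step != pd.Timedelta(hours=1):
        raise ValueError("daily_aggregate expects an hourly time axis")
    days = field.times.normalize()
    day_codes, day_index = pd.factorize(days)
    counts = np.bincount(day_codes)
    keep_days = counts == 24
    n_dropped = int((~keep_days).sum())
    if n_dropped:
        log.info("daily_aggregate: dropped %d partially covered boundary day(s)", n_dropped)
    keep_rows = keep_days[day_codes]
    vals = field.values[keep_rows]
    msk = field.mask[keep_rows]
    kept_days = day_index[keep_days]
    n_days = len(kept_days)
    _, ny, nx = field.values.shape
    vals = vals.reshape(n_days, 24, ny, nx)
    msk = msk.reshape(n_days, 24, ny, nx)
    n_missing = msk.sum(axis=1)
    with np.errstate(invalid="ignore"):
        summed = np.where(msk, 0.0, vals).sum(axis=1)
        n_valid = 24 - n_missing
        mean = np.where(n_valid > 0, summed / np.maximum(n_valid, 1), np.nan)
    day_mask = n_missing > max_missing_hours
    mean = np.where(day_mask, np.nan, mean)
    return GridField(
        name=field.name,
        times=pd.DatetimeIndex(kept_days),
        values=mean,
        mask=day_mask,
    )


def validate_region_weights(weights: pd.DataFrame, n_cells: int) -> None:
    """Check the region-weight table invariants; raise ValueError on violation."""
    required = {"region_id", "cell_index", "weight"}
    if not required.issubset(weights.columns):
        raise ValueError(f"weights table must have columns {sorted(required)}")
    if (weights["weight"] < 0).any():
        raise ValueError("weights must be non-negative")
    cells = weights["cell_index"].to_numpy()
    if (cells < 0).any() or (cells >= n_cells).any():
        raise ValueError("weight references a grid cell outside the field")
    sums = weights.groupby("region_id")["weight"].sum()
    if not np.allclose(sums.to_numpy(), 1.0, atol=1e-9):
        bad = sums[~np.isclose(sums, 1.0, atol=1e-9)].index.tolist()
        raise ValueError(f"weights do not sum to 1 for region(s) {bad}")


def zonal_mean(field: GridField, weights: pd.DataFrame) -> pd.DataFrame:
    """Area-weighted regional means of a daily field.

    Weights are renormalized per day over the non-masked subset of each
    region's cells; a region-day with every referenced cell masked propagates
    as NaN and is counted in one logged message.

    Returns a long frame with columns region_id, date, value.
    """
    validate_region_weights(weights, field.n_cells)
    flat = field.flat_values()  # (time, cell), NaN where masked
    valid = np.isfinite(flat)
    frames = []
    n_all_masked = 0
    for region_id, grp in weights.groupby("region_id", sort=True):
        idx = grp["cell_index"].to_numpy(dtype=int)
        w = grp["weight"].to_numpy(dtype=float)
        sub = flat[:, idx]
        sub_valid = valid[:, idx]
        denom = sub_valid @ w
        num = np.where(sub_valid, sub, 0.0) @ w
        with np.errstate(invalid="ignore", divide="ignore"):
            value = np.where(denom > 0, num / np.where(denom > 0, denom, 1.0), np.nan)
        n_all_masked += int((denom <= 0).sum())
        frames.append(
            pd.DataFrame({"region_id": region_id, "date": field.times, "value": value})
        )
    if n_all_masked:
        log.warning("zonal_mean: %d region-day(s) had all cells masked", n_all_masked)
    return pd.concat(frames, ignore_index=True)


@dataclass
class RegionDailySeries:
    """One region's consecutive daily mean temperature and relative humidity."""

    region_id: str
    dates: pd.DatetimeIndex
    tmean_c: np.ndarray
    rh_pct: np.ndarray
    heat_index_c: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        self.dates = pd.DatetimeIndex(self.dates)
        self.tmean_c = np.asarray(self.tmean_c, dtype=float)
        self.rh_pct = np.asarray(self.rh_pct, dtype=float)
        n = len(self.dates)
        if len(self.tmean_c) != n or len(self.rh_pct) != n:
            raise ValueError("per-day vectors must all have the same length")
        if n > 1:
            deltas = np.diff(self.dates.asi8)
            if not (deltas == 24 * 3600 * 10**9).all():
                raise ValueError("dates must be consecutive daily with no gaps")
        finite_rh = self.rh_pct[np.isfinite(self.rh_pct)]
        if finite_rh.size and ((finite_rh < 0).any() or (finite_rh > 100).any()):
            raise ValueError("relative humidity must lie in [0, 100]")
        if self.heat_index_c is not None:
            self.heat_index_c = np.asarray(self.heat_index_c, dtype=float)
            if len(self.heat_index_c) != n:
                raise ValueError("per-day vectors must all have the same length")

    def to_frame(self) -> pd.DataFrame:
        out = pd.DataFrame(
            {
                "region_id": self.region_id,
                "date": self.dates,
                "tmean_c": self.tmean_c,
                "rh_pct": self.rh_pct,
            }
        )
        if self.heat_index_c is not None:
            out["heat_index_c"] = self.heat_index_c
        return out


def build_region_series(
    temperature: GridField,
    dewpoint: GridField,
    weights: pd.DataFrame,
) -> dict[str, RegionDailySeries]:
    """Daily regional temperature and humidity from daily gridded fields.

    Relative humidity is derived per grid cell from the daily temperature and
    dewpoint means, then averaged regionally with the same weights as
    temperature, keeping RH inside [0, 100].
    """
    if not temperature.times.equals(dewpoint.times):
        raise ValueError("temperature and dewpoint fields must share a time axis")
    combined_mask = temperature.mask | dewpoint.mask
    t_vals = np.where(combined_mask, np.nan, temperature.values)
    td_vals = np.where(combined_mask, np.nan, dewpoint.values)
    td_safe = np.where(combined_mask, 0.0, np.minimum(td_vals, t_vals))
    t_safe = np.where(combined_mask, 0.0, t_vals)
    n_super = int(np.count_nonzero((~combined_mask) & (td_vals > t_vals)))
    if n_super:
        log.warning(
            "dewpoint exceeds temperature for %d grid cell-day(s); clamping RH to 100%%",
            n_super,
        )
    rh = 100.0 * saturation_vapor_pressure(td_safe) / saturation_vapor_pressure(t_safe)
    rh = np.clip(rh, 0.0, 100.0)
    rh_field = GridField.__new__(GridField)  # bypass temperature-range check for RH
    rh_field.name = "relative_humidity"
    rh_field.times = temperature.times
    rh_field.values = np.where(combined_mask, np.nan, rh)
    rh_field.mask = combined_mask.copy()

    t_regional = zonal_mean(
        GridField(temperature.name, temperature.times, t_vals, combined_mask), weights
    )
    rh_regional = zonal_mean(rh_field, weights)
    out: dict[str, RegionDailySeries] = {}
    for region_id, tgrp in t_regional.groupby("region_id"):
        rgrp = rh_regional[rh_regional["region_id"] == region_id]
        out[str(region_id)] = RegionDailySeries(
            region_id=str(region_id),
            dates=pd.DatetimeIndex(tgrp["date"]),
            tmean_c=tgrp["value"].to_numpy(),
            rh_pct=rgrp["value"].to_numpy(),
        )
    return out


# ---------------------------------------------------------------------------
# File interfaces
# ---------------------------------------------------------------------------

_KELVIN_UNITS = {"k", "kelvin", "degk"}
_CELSIUS_UNITS = {"c", "degc", "celsius", "degree_celsius", "degrees_celsius"}


def read_grid_netcdf(path, variable: str) -> GridField:
    """Read one variable from a (time, y, x) NetCDF file into a GridField.

    Kelvin fields (by the ``units`` attribute) are converted to degC.  Uses
    xarray's scipy backend, so NetCDF3 classic files are the supported format.
    """
    with xr.open_dataset(path, engine="scipy") as ds:
        da = ds[variable]
        if tuple(da.dims) != ("time", "y", "x"):
            raise ValueError("expected dimensions (time, y, x)")
        values = da.values.astype(float)
        units = str(da.attrs.get("units", "degC")).lower()
        if units in _KELVIN_UNITS:
            values = values - 273.15
        elif units not in _CELSIUS_UNITS:
            raise ValueError(f"unrecognized units attribute {units!r}")
        times = pd.DatetimeIndex(da["time"].values)
    return GridField(name=variable, times=times, values=values)


def write_grid_netcdf(path, fields: list[GridField]) -> None:
    """Write GridFields sharing a time axis to a NetCDF3 file (scipy backend)."""
    data_vars = {}
    for f in fields:
        data_vars[f.name] = (
            ("time", "y", "x"),
            np.where(f.mask, np.nan, f.values),
            {"units": "degC"},
        )
    ds = xr.Dataset(data_vars, coords={"time": fields[0].times})
    ds.to_netcdf(path, engine="scipy")


def read_region_daily_csv(path) -> dict[str, RegionDailySeries]:
    """Per-region fallback input: region_id, date, tmean_c and rh_pct or dewpoint_c."""
    df = pd.read_csv(path, parse_dates=["date"])
    if "rh_pct" not in df.columns:
        if "dewpoint_c" not in df.columns:
            raise ValueError("need either rh_pct or dewpoint_c column")
        df["rh_pct"] = derive_relative_humidity(
            df["tmean_c"].to_numpy(), df["dewpoint_c"].to_numpy()
        )
    out: dict[str, RegionDailySeries] = {}
    for region_id, grp in df.groupby("region_id", sort=True):
        grp = grp.sort_values("date")
        out[str(region_id)] = RegionDailySeries(
            region_id=str(region_id),
            dates=pd.DatetimeIndex(grp["date"]),
            tmean_c=grp["tmean_c"].to_numpy(),
            rh_pct=grp["rh_pct"].to_numpy(),
        )
    return out


def write_region_daily_csv(series: dict[str, RegionDailySeries], path) -> None:
    pd.concat([s.to_frame() for s in series.values()], ignore_index=True).to_csv(
        path, index=False
    )
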