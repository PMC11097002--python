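"""Attach lagged environmental values and elevation to occurrences.

For every cleaned occurrence this pulls land-surface temperature and
soil-moisture percentile at lags 0, 1 and 2 months (calendar-correct
across year boundaries), ranks the lagged temperatures against the
cell's climatology, samples the static elevation grid, and sets one
completeness flag per downstream analysis so each stage excludes exactly
its own incomplete records.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import DataError
from .grids import MonthlyGrid, month_index

__all__ = ["kelvin_to_celsius", "lag_month", "percentile_rank",
           "sample_grid", "enrich", "LAGS"]

LAGS = (0, 1, 2)


def kelvin_to_celsius(dn_or_kelvin, scale: float = 1.0, offset: float = 0.0):
    """Decode a (possibly scaled) Kelvin value to degrees Celsius.

    celsius = (dn * scale + offset) - 273.15; with scale 1 and offset 0
    this is a plain Kelvin-to-Celsius conversion (satellite temperature
    products commonly store digital numbers with a 0.02 scale factor).
    Missing values (NaN) propagate.
    """
    if scale <= 0:
        raise DataError(f"scale must be > 0, got {scale}")
    v = np.asarray(dn_or_kelvin, dtype=float)
    out = (v * scale + offset) - 273.15
    return float(out) if np.isscalar(dn_or_kelvin) else out


def lag_month(year: int, month: int, k: int) -> tuple[int, int]:
    """The calendar month ``k`` months before (year, month)."""
    if not 1 <= month <= 12:
        raise DataError(f"month {month} not in 1..12")
    if k < 0:
        raise DataError(f"lag must be >= 0, got {k}")
    idx = month_index(year, month) - k
    return idx // 12, idx % 12 + 1


def percentile_rank(value, reference) -> float:
    """Percentile of ``value`` within a reference series.

    100 * (# reference values <= value) / (# non-missing reference
    values).  The <= convention makes downstream ">= 70th percentile"
    thresholds inclusive; a value equal to the reference maximum (or a
    constant reference) ranks at 100.  Empty reference or missing value
    -> NaN.
    """
    ref = np.asarray(reference, dtype=float)
    ref = ref[np.isfinite(ref)]
    if ref.size == 0 or not np.isfinite(value):
        return float("nan")
    return 100.0 * float(np.sum(ref <= value)) / ref.size


def sample_grid(grid: MonthlyGrid, lon, lat, year=None, month=None) -> float:
    """Nearest-cell point lookup; see :meth:`MonthlyGrid.sample`."""
    return grid.sample(lon, lat, year, month)


def _lagged_values(grid: MonthlyGrid, iy, ix, years, months, k):
    """Vectorized lagged lookup for many records on one monthly grid."""
    mi = years * 12 + (months - 1) - k
    t = mi - month_index(*grid.start)
    valid = (iy >= 0) & (ix >= 0) & (t >= 0) & (t < grid.n_times)
    tc = np.clip(t, 0, max(grid.n_times - 1, 0))
    vals = grid.values[tc, np.clip(iy, 0, None), np.clip(ix, 0, None)]
    return np.where(valid, vals, np.nan)


def _cell_climatology_rank(grid: MonthlyGrid, iy, ix, values, lag_months,
                           mode: str) -> np.ndarray:
    """Percentile of per-record values within their cell's climatology.

    ``mode='all'`` ranks against every month of the cell's record (the
    default, matching the drought-percentile convention of the moisture
    product this temperature is coupled to); ``mode='calendar'`` ranks
    only against the same calendar month.
    """
    out = np.full(values.shape, np.nan)
    ok = (iy >= 0) & (ix >= 0) & np.isfinite(values)
    cal = np.asarray(lag_months) % 12  # calendar month (0-based) of the lagged date
    grid_cal = (np.arange(grid.n_times) + grid.start[1] - 1) % 12
    for cell in set(zip(iy[ok].tolist(), ix[ok].tolist())):
        sel = ok & (iy == cell[0]) & (ix == cell[1])
        series = grid.values[:, cell[0], cell[1]]
        if mode == "all":
            ref = np.sort(series[np.isfinite(series)])
            if ref.size:
                out[sel] = 100.0 * np.searchsorted(ref, values[sel], side="right") / ref.size
        else:
            for cm in np.unique(cal[sel]):
                sub = sel & (cal == cm)
                ref = series[grid_cal == cm]
                ref = np.sort(ref[np.isfinite(ref)])
                if ref.size:
                    out[sub] = 100.0 * np.searchsorted(ref, values[sub], side="right") / ref.size
    return out


def enrich(occurrences: pd.DataFrame, lst: MonthlyGrid, rzsm: MonthlyGrid,
           elev: MonthlyGrid, climatology: str = "all") -> pd.DataFrame:
    """Enrich cleaned occurrences with lagged environment and elevation.

    Adds ``lst_c_lag{0,1,2}``, ``rzsm_pct_lag{0,1,2}``,
    ``lst_pctile_lag{1,2}`` (percentile of the lagged LST within the
    cell's climatology), ``elevation_m``, and per-analysis completeness
    flags ``complete_temperature`` (LST lags 1 and 2 present),
    ``complete_moisture`` (RZSM lags 1 and 2 present) and
    ``complete_coupling`` (all six lagged constituents present).  A
    record missing RZSM is thereby excluded from the moisture and
    coupling analyses but still usable for the temperature analysis.

    Raises if the temperature and moisture grids share no months.
    """
    if climatology not in ("all", "calendar"):
        raise DataError(f"unknown climatology mode {climatology!r}")
    for g, name in ((lst, "lst"), (rzsm, "rzsm")):
        if g.static:
            raise DataError(f"{name} grid must be monthly")
    lo = max(month_index(*lst.start), month_index(*rzsm.start))
    hi = min(month_index(*lst.start) + lst.n_times,
             month_index(*rzsm.start) + rzsm.n_times)
    if hi <= lo:
        raise DataError("LST and RZSM grids have disjoint time coverage")

    out = occurrences.reset_index(drop=True).copy()
    lon = out["lon"].to_numpy(dtype=float)
    lat = out["lat"].to_numpy(dtype=float)
    years = out["year"].to_numpy(dtype=int)
    months = out["month"].to_numpy(dtype=int)

    iy_l, ix_l = lst.cell_index(lon, lat)
    iy_r, ix_r = rzsm.cell_index(lon, lat)

    lag_vals = {}
    for k in LAGS:
        lag_vals[("lst", k)] = _lagged_values(lst, iy_l, ix_l, years, months, k)
        lag_vals[("rzsm", k)] = _lagged_values(rzsm, iy_r, ix_r, years, months, k)
        out[f"lst_c_lag{k}"] = lag_vals[("lst", k)]
        out[f"rzsm_pct_lag{k}"] = lag_vals[("rzsm", k)]

    for k in (1, 2):
        lag_mi = years * 12 + (months - 1) - k
        out[f"lst_pctile_lag{k}"] = _cell_climatology_rank(
            lst, iy_l, ix_l, lag_vals[("lst", k)], lag_mi, climatology)

    ev = np.array([elev.sample(lo_, la_) for lo_, la_ in zip(lon, lat)])
    if "elevation_m" in occurrences.columns:  # keep prior value where grid is silent
        prior = occurrences["elevation_m"].to_numpy(dtype=float)
        ev = np.where(np.isfinite(ev), ev, prior)
    out["elevation_m"] = ev

    out["complete_temperature"] = (np.isfinite(lag_vals[("lst", 1)])
                                   & np.isfinite(lag_vals[("lst", 2)]))
    out["complete_moisture"] = (np.isfinite(lag_vals[("rzsm", 1)])
                                & np.isfinite(lag_vals[("rzsm", 2)]))
    cc = np.ones(len(out), dtype=bool)
    for k in LAGS:
        cc &= np.isfinite(lag_vals[("lst", k)]) & np.isfinite(lag_vals[("rzsm", k)])
    out["complete_coupling"] = cc
    return out
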