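"""Temporal trend analyses.

Three families: per-species logistic trends in high-elevation occurrence
(the altitudinal range-shift analysis), per-location Mann-Kendall trends
of the monthly environment and logistic trends of monthly heat-moisture
coupling frequency with increase/decrease classification, and
time-windowed PCA of (elevation, lag-1 LST, lag-1 RZSM).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .coupling import CouplingConfig
from .errors import DataError
from .grids import MonthlyGrid, month_index
from .stats import (LogitFit, MKResult, fit_logit_trend, mann_kendall,
                    odds_summary, pca_3var, PCAResult)

__all__ = ["LocationSeries", "TrendClass", "high_elevation_flag",
           "elevation_trend", "build_location_series", "location_env_trends",
           "coupling_frequency_trend", "classify_all_locations", "windowed_pca"]


def high_elevation_flag(elevation_m: float, cutoff: float = 1000.0,
                        inclusive: bool = False) -> bool:
    """Montane indicator.  The trend analysis reads its cutoff strictly
    (elevation must exceed 1000 m); the host analysis uses the inclusive
    reading (1000 m or higher).  Negative elevations are valid values."""
    if not np.isfinite(elevation_m):
        raise DataError("elevation is missing")
    return bool(elevation_m >= cutoff) if inclusive else bool(elevation_m > cutoff)


def elevation_trend(occurrences: pd.DataFrame, cutoff: float = 1000.0,
                    inclusive: bool = False) -> tuple[LogitFit, dict]:
    """Logistic trend of one species' montane-occurrence odds on year.

    Records without elevation are excluded.  Returns the fit (its
    ``summary_row`` has the conventional log-odds estimate / SE / Z / p
    layout) and the odds summary over the observed year span.  An
    all-one or all-zero indicator sets the separation flag rather than
    raising.
    """
    df = occurrences[np.isfinite(occurrences["elevation_m"].to_numpy(dtype=float))]
    if df["year"].nunique() < 2:
        raise DataError("elevation trend needs >=2 distinct years")
    y = np.array([high_elevation_flag(e, cutoff, inclusive)
                  for e in df["elevation_m"]], dtype=float)
    t = df["year"].to_numpy(dtype=float)
    fit = fit_logit_trend(t, y)
    return fit, odds_summary(fit, t.min(), t.max())


# ----------------------------------------------------------------------
# Per-location monthly series
# ----------------------------------------------------------------------

@dataclass
class LocationSeries:
    """Aligned monthly LST/RZSM series at one grid cell."""

    lon: float
    lat: float
    elevation_m: float
    start: tuple[int, int]
    lst_c: np.ndarray
    rzsm_pct: np.ndarray

    @property
    def n_months(self) -> int:
        return self.lst_c.size

    def coupling_series(self, config: CouplingConfig = CouplingConfig()) -> np.ndarray:
        """Month-by-month coupling indicator (1/0, NaN where either
        constituent is missing — coupling is defined only for months with
        both variables present)."""
        lst, rz = self.lst_c, self.rzsm_pct
        present = np.isfinite(lst) & np.isfinite(rz)
        hit = present & (lst >= config.temp_threshold_c) & (
            rz >= config.moisture_pctile_threshold)
        return np.where(present, hit.astype(float), np.nan)


def build_location_series(occurrences: pd.DataFrame, lst: MonthlyGrid,
                          rzsm: MonthlyGrid, elev: MonthlyGrid) -> list[LocationSeries]:
    """Compile monthly series at the grid cells of observed occurrences.

    Locations are the deduplicated LST-grid cells of the records; the
    RZSM series is sampled at the cell-centre coordinate of that cell.
    Series cover the months the two monthly grids share.
    """
    lo = max(month_index(*lst.start), month_index(*rzsm.start))
    hi = min(month_index(*lst.start) + lst.n_times,
             month_index(*rzsm.start) + rzsm.n_times)
    if hi <= lo:
        raise DataError("LST and RZSM grids have disjoint time coverage")
    sl_l = slice(lo - month_index(*lst.start), hi - month_index(*lst.start))
    start = (lo // 12, lo % 12 + 1)

    iy, ix = lst.cell_index(occurrences["lon"].to_numpy(dtype=float),
                            occurrences["lat"].to_numpy(dtype=float))
    cells = sorted({(int(a), int(b)) for a, b in zip(iy, ix) if a >= 0 and b >= 0})
    out = []
    for cy, cx in cells:
        clon, clat = float(lst.lon[cx]), float(lst.lat[cy])
        ry, rx = rzsm.cell_index(clon, clat)
        ry, rx = int(ry), int(rx)
        if ry < 0 or rx < 0:
            continue
        rz_full = np.full(hi - lo, np.nan)
        r0 = lo - month_index(*rzsm.start)
        rz_full[:] = rzsm.values[r0:r0 + (hi - lo), ry, rx]
        out.append(LocationSeries(
            lon=clon, lat=clat, elevation_m=elev.sample(clon, clat),
            start=start, lst_c=lst.values[sl_l, cy, cx].copy(),
            rzsm_pct=rz_full))
    return out


def location_env_trends(series: LocationSeries, min_months: int = 24) -> dict:
    """Mann-Kendall trend of the monthly LST and RZSM series."""
    out = {}
    for name, vals in (("lst", series.lst_c), ("rzsm", series.rzsm_pct)):
        n = int(np.isfinite(vals).sum())
        if n < min_months:
            out[name] = MKResult(np.nan, np.nan, np.nan, np.nan, np.nan, n,
                                 reason=f"needs >={min_months} months, got {n}")
        else:
            out[name] = mann_kendall(vals)
    return out


@dataclass
class TrendClass:
    """Direction of a coupling-frequency trend at one location:
    'increase' / 'decrease' require the Wald p below alpha (and a
    non-separated fit); everything else is 'none'."""

    label: str
    slope: float
    p_wald: float


def coupling_frequency_trend(series: LocationSeries,
                             config: CouplingConfig = CouplingConfig(),
                             alpha: float = 0.05, min_months: int = 24):
    """Logistic trend of the monthly coupling indicator at one location.

    The binary series (lag-0 conjunction month by month) is regressed on
    the month index; the odds summary spans the full observed window.
    Returns (fit, odds, TrendClass); a location where coupling never (or
    always) occurs yields a separation-flagged fit classified 'none'.
    """
    c = series.coupling_series(config)
    ok = np.isfinite(c)
    if ok.sum() < min_months:
        raise DataError(f"needs >={min_months} decidable months, got {int(ok.sum())}")
    t = np.arange(c.size, dtype=float)[ok]
    fit = fit_logit_trend(t, c[ok])
    odds = odds_summary(fit, t.min(), t.max())
    if fit.separation or not fit.p_wald < alpha:
        label = "none"
    else:
        label = "increase" if fit.slope > 0 else "decrease"
    return fit, odds, TrendClass(label, fit.slope, fit.p_wald)


def classify_all_locations(locations: list[LocationSeries],
                           config: CouplingConfig = CouplingConfig(),
                           cutoff: float = 1000.0, alpha: float = 0.05,
                           min_months: int = 24):
    """Stratified shares of increasing/decreasing coupling trends.

    Locations are split at the elevation cutoff (strictly above vs not);
    per stratum the percentage classified increase and decrease is
    reported (remainder implicitly 'none').  Returns (summary dict,
    per-location table).  An empty stratum reports missing percentages.
    """
    rows = []
    for loc in locations:
        try:
            fit, odds, cls = coupling_frequency_trend(loc, config, alpha, min_months)
            label, slope, p = cls.label, cls.slope, cls.p_wald
            sep = fit.separation
        except DataError:
            label, slope, p, sep = "undetermined", np.nan, np.nan, False
        rows.append({"lon": loc.lon, "lat": loc.lat,
                     "elevation_m": loc.elevation_m,
                     "slope": slope, "p_wald": p, "separation": sep,
                     "class": label})
    table = pd.DataFrame(rows)

    summary = {}
    determined = table[table["class"] != "undetermined"]
    for name, stratum in (("above", determined[determined["elevation_m"] > cutoff]),
                          ("below", determined[determined["elevation_m"] <= cutoff])):
        n = len(stratum)
        if n == 0:
            summary[name] = {"n": 0, "pct_increase": None, "pct_decrease": None}
        else:
            summary[name] = {
                "n": n,
                "pct_increase": 100.0 * (stratum["class"] == "increase").sum() / n,
                "pct_decrease": 100.0 * (stratum["class"] == "decrease").sum() / n,
            }
    summary["cutoff_m"] = cutoff
    summary["cutoff_rule"] = "strictly above vs at-or-below"
    summary["alpha"] = alpha
    return summary, table


def windowed_pca(enriched: pd.DataFrame, window: tuple[int, int]) -> PCAResult:
    """PCA of (elevation, lag-1 LST, lag-1 RZSM) within a year window.

    ``window`` is an inclusive (first_year, last_year) range.  Only
    complete rows enter; fewer than 3 raises with the count.
    """
    y0, y1 = window
    sel = enriched[(enriched["year"] >= y0) & (enriched["year"] <= y1)]
    cols = sel[["elevation_m", "lst_c_lag1", "rzsm_pct_lag1"]].astype(float)
    cols = cols.dropna()
    if len(cols) < 3:
        raise DataError(f"window {window} has {len(cols)} complete records, needs >=3")
    return pca_3var(cols, variables=["elevation_m", "lst_c_lag1", "rzsm_pct_lag1"])
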