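"""Heat-moisture coupling detection and per-species association.

A heat-moisture coupling event is a month in which land-surface
temperature is at or above 25 degC while the root-zone soil-moisture
percentile is at or above 70 at the same location — the window in which
warm, wet soil favours parasitic-weed seed preconditioning.  An
occurrence is "coupled" when such an event happened in its observation
month or either of the two preceding months (lags 0, 1, 2).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigError

__all__ = ["CouplingConfig", "coupling_at_lag", "coupling_any",
           "coupling_flags_frame", "species_association"]


@dataclass(frozen=True)
class CouplingConfig:
    """Thresholds and lag window for coupling detection.

    Defaults are the study definition: LST >= 25 degC and RZSM
    percentile >= 70, inclusive at both boundaries, over lags {0, 1, 2}
    months before the observation.
    """

    temp_threshold_c: float = 25.0
    moisture_pctile_threshold: float = 70.0
    lags: tuple[int, ...] = (0, 1, 2)

    def __post_init__(self):
        if not np.isfinite(self.temp_threshold_c) or not np.isfinite(self.moisture_pctile_threshold):
            raise ConfigError("coupling thresholds must be finite")
        if not self.lags or not set(self.lags) <= {0, 1, 2}:
            raise ConfigError(f"lags must be a non-empty subset of {{0,1,2}}, got {self.lags}")

    def as_dict(self) -> dict:
        return {"temp_threshold_c": self.temp_threshold_c,
                "moisture_pctile_threshold": self.moisture_pctile_threshold,
                "lags": list(self.lags)}


def _missing(v) -> bool:
    return v is None or (isinstance(v, float) and np.isnan(v))


def coupling_at_lag(lst_c, rzsm_pct, config: CouplingConfig = CouplingConfig()):
    """Coupling status for one month: True/False, or None if either
    constituent is missing (missing is not false)."""
    if _missing(lst_c) or _missing(rzsm_pct):
        return None
    return bool(lst_c >= config.temp_threshold_c
                and rzsm_pct >= config.moisture_pctile_threshold)


def coupling_any(lst_by_lag, rzsm_by_lag, config: CouplingConfig = CouplingConfig()):
    """Any-lag coupling status of one occurrence.

    ``lst_by_lag``/``rzsm_by_lag`` are indexable by lag (0, 1, 2).  True
    as soon as any configured lag couples (both variables from the same
    month); if no lag is true and any configured lag is undecidable the
    record is undecidable (None) — incomplete records are excluded
    downstream rather than counted as uncoupled.
    """
    saw_missing = False
    for k in config.lags:
        flag = coupling_at_lag(lst_by_lag[k], rzsm_by_lag[k], config)
        if flag is True:
            return True
        if flag is None:
            saw_missing = True
    return None if saw_missing else False


def coupling_flags_frame(enriched: pd.DataFrame,
                         config: CouplingConfig = CouplingConfig()) -> pd.Series:
    """Vectorized :func:`coupling_any` over an enriched occurrence table.

    Expects columns ``lst_c_lag{k}`` and ``rzsm_pct_lag{k}``.  Returns a
    float Series: 1.0 coupled, 0.0 not coupled, NaN undecidable.
    """
    n = len(enriched)
    any_true = np.zeros(n, dtype=bool)
    any_missing = np.zeros(n, dtype=bool)
    for k in config.lags:
        lst = enriched[f"lst_c_lag{k}"].to_numpy(dtype=float)
        rz = enriched[f"rzsm_pct_lag{k}"].to_numpy(dtype=float)
        present = np.isfinite(lst) & np.isfinite(rz)
        hit = present & (lst >= config.temp_threshold_c) & (
            rz >= config.moisture_pctile_threshold)
        any_true |= hit
        any_missing |= ~present
    out = np.where(any_true, 1.0, np.where(any_missing, np.nan, 0.0))
    return pd.Series(out, index=enriched.index, name="coupled")


def species_association(enriched: pd.DataFrame,
                        config: CouplingConfig = CouplingConfig()) -> pd.DataFrame:
    """Per-species percentage of occurrences preceded by a coupling event.

    Only decidable records count: ``n_complete`` is the number whose
    coupling status resolves to true or false, ``pct_coupled`` is
    100 * n_coupled / n_complete (NaN when a species has no decidable
    record).  Output rows are ordered by species name and echo the
    thresholds used.
    """
    flags = coupling_flags_frame(enriched, config)
    rows = []
    for species, idx in enriched.groupby("species").groups.items():
        f = flags.loc[idx]
        n_complete = int(f.notna().sum())
        n_coupled = int((f == 1.0).sum())
        pct = 100.0 * n_coupled / n_complete if n_complete else np.nan
        rows.append({"species": species, "n_complete": n_complete,
                     "n_coupled": n_coupled, "pct_coupled": pct})
    out = pd.DataFrame(rows).sort_values("species").reset_index(drop=True)
    for key, val in config.as_dict().items():
        out.attrs[key] = val
    return out
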