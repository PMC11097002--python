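"""Cross-referencing parasite occurrences with host-crop harvested areas.

Presence is a conservative binary check: at least one of the parasite's
host crops has nonzero harvested area at the occurrence's nearest grid
cell in a given epoch.  Both epochs are evaluated on the same occurrence
set, so epoch differences reflect the crop layers alone.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import ConfigError, DataError
from .grids import MonthlyGrid

__all__ = ["DEFAULT_HOST_MAP", "host_present", "presence_report"]

#: Study host lists: bean broomrape on cool-season legumes, Asiatic
#: witchweed on cereal crops (millet treated as one layer).
DEFAULT_HOST_MAP = {
    "Orobanche crenata": ("beans", "peas", "lentils"),
    "Striga asiatica": ("maize", "sorghum", "millet", "rice"),
}


def host_present(lon: float, lat: float, species: str,
                 epoch_grids: dict[str, MonthlyGrid],
                 hostmap: dict = DEFAULT_HOST_MAP):
    """True iff any host crop's area at the nearest cell is > 0.

    None (undecidable) when the point falls outside every host grid.
    An empty host list is a vacuous disjunction: False.
    """
    if species not in hostmap:
        raise ConfigError(f"species {species!r} not in host map")
    decidable = False
    for crop in hostmap[species]:
        if crop not in epoch_grids:
            raise ConfigError(f"host crop {crop!r} missing from epoch grids")
        v = epoch_grids[crop].sample(lon, lat)
        if np.isfinite(v):
            decidable = True
            if v > 0:
                return True
    return False if (decidable or not hostmap[species]) else None


def presence_report(occurrences: pd.DataFrame, crop_grids: dict,
                    hostmap: dict = DEFAULT_HOST_MAP,
                    elevation_cutoff: float = 1000.0,
                    inclusive: bool = True) -> pd.DataFrame:
    """Host-presence percentages per species x epoch.

    ``crop_grids`` maps epoch -> {crop: grid}.  ``pct_all`` is over all
    decidable records of the species, ``pct_high_elev`` over decidable
    records at or above the elevation cutoff (inclusive by default, the
    host analysis' reading of the montane threshold).  Strata with no
    decidable records report NaN with count 0.
    """
    if "elevation_m" not in occurrences.columns:
        raise DataError("occurrences must carry elevation_m (enrich first)")
    rows = []
    for species in sorted(hostmap):
        occ = occurrences[occurrences["species"] == species]
        elev = occ["elevation_m"].to_numpy(dtype=float)
        high = np.isfinite(elev) & ((elev >= elevation_cutoff) if inclusive
                                    else (elev > elevation_cutoff))
        for epoch in sorted(crop_grids):
            grids = crop_grids[epoch]
            flags = np.array([
                _as_float(host_present(lo, la, species, grids, hostmap))
                for lo, la in zip(occ["lon"], occ["lat"])])
            rows.append({
                "species": species, "epoch": epoch,
                "n_all": int(np.isfinite(flags).sum()),
                "pct_all": _pct(flags),
                "n_high_elev": int(np.isfinite(flags[high]).sum()),
                "pct_high_elev": _pct(flags[high]),
            })
    out = pd.DataFrame(rows)
    out.attrs["elevation_cutoff_m"] = elevation_cutoff
    out.attrs["cutoff_rule"] = "inclusive (>=)" if inclusive else "strict (>)"
    return out


def _as_float(flag) -> float:
    return np.nan if flag is None else float(flag)


def _pct(flags: np.ndarray) -> float:
    ok = np.isfinite(flags)
    return 100.0 * flags[ok].mean() if ok.any() else np.nan
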