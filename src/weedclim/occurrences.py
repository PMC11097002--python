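"""Reading, validating and cleaning species occurrence tables.

Occurrence downloads (GBIF-style delimited text) arrive with duplicate
rows, missing or junk coordinates, and unparseable dates.  Cleaning
assigns every input row exactly one fate — retained, or dropped for the
first matching reason in a fixed order — so that the cleaning report
always reconciles with the input row count.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .errors import DataError

__all__ = ["STUDY_SPECIES", "DEFAULT_COLUMN_MAP", "CleaningReport",
           "read_occurrences", "clean_occurrences"]

#: The eight parasitic species of the study set.
STUDY_SPECIES = (
    "Orobanche crenata", "Orobanche cumana", "Orobanche minor",
    "Phelipanche aegyptiaca", "Phelipanche ramosa",
    "Striga asiatica", "Striga gesnerioides", "Striga hermonthica",
)

#: Standard field -> column name in a GBIF-style download.
DEFAULT_COLUMN_MAP = {
    "species": "species",
    "lon": "decimalLongitude",
    "lat": "decimalLatitude",
    "date": "eventDate",        # used when year/month columns are absent
    "year": "year",
    "month": "month",
    "record_id": "record_id",
    "elevation_m": "elevation_m",
}

#: Fixed precedence of drop reasons; the first matching reason wins.
DROP_ORDER = ("missing_species", "bad_coordinates", "bad_date", "duplicate")


@dataclass
class CleaningReport:
    n_input: int
    n_retained: int
    missing_species: int
    bad_coordinates: int
    bad_date: int
    duplicates: int
    coordinate_rule: str = ("dropped when missing, outside [-180,180]x[-90,90], "
                            "or exactly (0,0)")

    def reconciles(self) -> bool:
        return (self.n_retained + self.missing_species + self.bad_coordinates
                + self.bad_date + self.duplicates) == self.n_input

    def to_json(self, path=None) -> str:
        text = json.dumps(asdict(self), indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text


def read_occurrences(path, column_map: dict | None = None,
                     delimiter: str | None = None) -> pd.DataFrame:
    """Read a delimited occurrence table into the raw standard layout.

    Unparseable fields become missing values, never dropped rows — all
    filtering happens in :func:`clean_occurrences`.  Dates are parsed to
    (year, month); explicit year/month columns take precedence over a
    date column.  Missing mandatory columns raise, listing them.
    """
    cmap = {**DEFAULT_COLUMN_MAP, **(column_map or {})}
    if delimiter is None:
        delimiter = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    raw = pd.read_csv(path, sep=delimiter, dtype=str, keep_default_na=True)

    mandatory = ["species", "lon", "lat"]
    missing_cols = [cmap[k] for k in mandatory if cmap[k] not in raw.columns]
    has_ym = cmap["year"] in raw.columns and cmap["month"] in raw.columns
    has_date = cmap["date"] in raw.columns
    if not has_ym and not has_date:
        missing_cols.append(f"{cmap['date']} (or {cmap['year']}+{cmap['month']})")
    if missing_cols:
        raise DataError(f"missing mandatory columns: {', '.join(missing_cols)}")

    out = pd.DataFrame(index=raw.index)
    if cmap["record_id"] in raw.columns:
        out["record_id"] = raw[cmap["record_id"]]
    else:
        out["record_id"] = [f"row{i:06d}" for i in range(len(raw))]
    species = raw[cmap["species"]].astype("string").str.strip()
    out["species"] = species.where(species.notna() & (species != ""), pd.NA)
    out["lon"] = pd.to_numeric(raw[cmap["lon"]], errors="coerce")
    out["lat"] = pd.to_numeric(raw[cmap["lat"]], errors="coerce")

    if has_ym:
        out["year"] = pd.to_numeric(raw[cmap["year"]], errors="coerce")
        out["month"] = pd.to_numeric(raw[cmap["month"]], errors="coerce")
    else:
        dates = pd.to_datetime(raw[cmap["date"]], errors="coerce", format="mixed")
        out["year"] = dates.dt.year.astype(float)
        out["month"] = dates.dt.month.astype(float)
    if cmap["elevation_m"] in raw.columns:
        out["elevation_m"] = pd.to_numeric(raw[cmap["elevation_m"]], errors="coerce")
    return out


def clean_occurrences(raw: pd.DataFrame):
    """Purge defective rows and duplicates; return (clean, report).

    Drop reasons, in precedence order: missing species identification;
    missing/out-of-range/(0,0) coordinates; missing or invalid
    observation date (records without a usable month cannot enter any
    lagged analysis); duplicate of an earlier row on (species, lon,
    lat, year, month) — the first occurrence in file order is kept.
    Records missing only elevation are retained (elevation is enriched
    later).  Cleaning never fails; it reports, and is idempotent.
    """
    df = raw.copy()
    n_input = len(df)

    no_species = df["species"].isna()
    lon, lat = df["lon"], df["lat"]
    bad_coord = (lon.isna() | lat.isna()
                 | (lon < -180) | (lon > 180) | (lat < -90) | (lat > 90)
                 | ((lon == 0) & (lat == 0)))
    bad_date = (df["year"].isna() | df["month"].isna()
                | (df["month"] < 1) | (df["month"] > 12)
                | (df["month"] % 1 != 0) | (df["year"] % 1 != 0))

    reason = pd.Series("keep", index=df.index)
    reason[bad_date] = "bad_date"
    reason[bad_coord] = "bad_coordinates"       # higher precedence overwrites
    reason[no_species] = "missing_species"

    candidates = df[reason == "keep"]
    dup = candidates.duplicated(subset=["species", "lon", "lat", "year", "month"],
                                keep="first")
    reason.loc[candidates.index[dup]] = "duplicate"

    clean = df[reason == "keep"].copy()
    clean["year"] = clean["year"].astype(int)
    clean["month"] = clean["month"].astype(int)
    clean = clean.reset_index(drop=True)

    counts = reason.value_counts()
    report = CleaningReport(
        n_input=n_input,
        n_retained=len(clean),
        missing_species=int(counts.get("missing_species", 0)),
        bad_coordinates=int(counts.get("bad_coordinates", 0)),
        bad_date=int(counts.get("bad_date", 0)),
        duplicates=int(counts.get("duplicate", 0)),
    )
    if not report.reconciles():  # pragma: no cover - internal consistency
        raise DataError("cleaning report does not reconcile with input rows")
    return clean, report
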