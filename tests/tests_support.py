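"""Shared helpers for the test suite."""

import pandas as pd


def standardize(raw: pd.DataFrame) -> pd.DataFrame:
    """GBIF-style generator output -> the cleaned-table column layout."""
    df = raw.rename(columns={"decimalLongitude": "lon", "decimalLatitude": "lat"})
    df["year"] = df["year"].astype(float)
    df["month"] = df["month"].astype(float)
    df["species"] = df["species"].astype("string")
    return df
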