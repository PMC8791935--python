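"""Bundled reference tables.

``table1_cities.csv`` holds the published city-by-city summary of the
original European analysis: population, the maximum daily Stringency Index
reached, and the central estimate with 95% credible limits of the excess
deaths attributable to each pollutant's Lockdown - BAU change over
February-July 2020.  Burden cells are missing for Pristina (Kosovo), whose
crude death rate was unavailable.  The table serves as a fixed input for
aggregation checks: the TOTAL row of the report is reproduced by summing
the printed city rows.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

BURDEN_POLLUTANTS = ("no2", "o3", "pm25", "pm10")


def load_reference_city_table() -> pd.DataFrame:
    """The published 47-city reference table (one row per city)."""
    with resources.files("lockdownair.data").joinpath("table1_cities.csv").open() as fh:
        return pd.read_csv(fh)


def reference_table_totals(table: pd.DataFrame | None = None) -> dict[str, float]:
    """TOTAL-row aggregation of the reference city table.

    Sums the populations of all listed cities and, per pollutant, the
    central burden estimates of the cities that have them (46 of 47).
    """
    if table is None:
        table = load_reference_city_table()
    out = {"population": float(table["population"].sum())}
    for p in BURDEN_POLLUTANTS:
        col = f"{p}_deaths"
        out[f"{p}_deaths"] = float(table[col].sum(skipna=True))
    return out
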