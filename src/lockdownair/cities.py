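"""City metadata records and their CSV dialect.

Each city carries the static quantities the analysis needs: coordinates for
the spatial covariance, population and crude all-cause death rate for the
health impact assessment, and NDVI (greenness) and built-up area share as
city-level covariates of the pollution model.  The crude death rate is
stored on the *annual* per-person scale and converted to daily downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

CITY_COLUMNS = [
    "city_id",
    "name",
    "country",
    "lon",
    "lat",
    "population",
    "ndvi",
    "builtup",
    "crude_death_rate",
]


@dataclass(frozen=True)
class City:
    city_id: str
    name: str
    country: str
    lon: float
    lat: float
    population: float
    ndvi: float
    builtup: float
    crude_death_rate: float  # deaths per person per year

    def __post_init__(self) -> None:
        if self.population <= 0:
            raise ValueError(f"{self.city_id}: population must be positive")
        if not 0.0 < self.crude_death_rate < 0.05:
            raise ValueError(f"{self.city_id}: crude death rate outside (0, 0.05)/year")
        if not -90.0 <= self.lat <= 90.0:
            raise ValueError(f"{self.city_id}: latitude outside [-90, 90]")
        if not -180.0 <= self.lon <= 180.0:
            raise ValueError(f"{self.city_id}: longitude outside [-180, 180]")


def cities_to_frame(cities: list[City]) -> pd.DataFrame:
    return pd.DataFrame([asdict(c) for c in cities], columns=CITY_COLUMNS)


def frame_to_cities(frame: pd.DataFrame) -> list[City]:
    missing = [c for c in CITY_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"city table missing columns: {missing}")
    return [City(**{k: row[k] for k in CITY_COLUMNS}) for _, row in frame.iterrows()]


def read_cities(path) -> list[City]:
    return frame_to_cities(pd.read_csv(path))


def write_cities(cities: list[City], path) -> None:
    cities_to_frame(cities).to_csv(path, index=False)


def city_coords(cities: list[City]) -> np.ndarray:
    """(n, 2) array of (lon, lat) in degrees."""
    return np.array([[c.lon, c.lat] for c in cities], dtype=float)


def zscore_covariates(cities: list[City]) -> tuple[np.ndarray, np.ndarray]:
    """NDVI and built-up area z-scored across cities (ddof=0).

    Constant columns map to zeros rather than dividing by zero.
    """
    ndvi = np.array([c.ndvi for c in cities], dtype=float)
    built = np.array([c.builtup for c in cities], dtype=float)

    def z(v: np.ndarray) -> np.ndarray:
        s = v.std()
        return (v - v.mean()) / s if s > 0 else np.zeros_like(v)

    return z(ndvi), z(built)
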