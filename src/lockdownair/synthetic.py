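"""Synthetic study generator with known ground truth.

Emulates the three inputs of the analysis so the whole pipeline is testable
end-to-end without any external download:

* city metadata over a Europe-like bounding box,
* a daily panel of the nine policy indicators per country, following the
  observed trajectory shape — flat at zero through February, an abrupt jump
  to near-maximum stringency in March, a plateau, then stepwise relaxation
  from mid-May,
* daily pollutant differences (Lockdown - BAU, µg/m³) generated directly
  from the statistical structure the pollution model assumes: a shared
  anchored-spline response to the Stringency Index plus spatially correlated
  city deviations (Matérn Gaussian fields), city-specific sum-to-zero
  day-of-week effects, z-scored NDVI / built-up covariate effects, and
  i.i.d. Gaussian residual noise.

The generator records every coefficient it used in a :class:`SyntheticTruth`
so parameter-recovery experiments can compare estimates against the truth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from datetime import date, timedelta
from pathlib import Path

import numpy as np
import pandas as pd

from .cities import City, cities_to_frame, city_coords, write_cities, zscore_covariates
from .spatial import sample_matern_fields
from .splines import SplineSpec
from .stringency import SI_INDICATORS, compute_si, write_policy_panel

DEFAULT_START = date(2020, 2, 1)
DEFAULT_END = date(2020, 7, 31)
POLLUTANTS = ("no2", "o3", "pm25", "pm10")

#: Default true exposure-response: a smooth negative curve reaching about
#: -6.5 µg/m³ at SI = 80, steeper at high stringency (NO2-like magnitude).
def default_target_curve(si: np.ndarray) -> np.ndarray:
    return -6.5 * (np.asarray(si, dtype=float) / 80.0) ** 2


@dataclass
class SyntheticTruth:
    """Ground-truth coefficients behind one generated pollutant panel."""

    fixed_spline_coefficients: np.ndarray  # (4,) in anchored-basis units
    city_deviations: np.ndarray  # (n_cities, 4)
    dow_effects: np.ndarray  # (n_cities, 7), rows sum to zero
    ndvi_coef: float
    builtup_coef: float
    residual_sd: float
    matern_range_km: float
    matern_sd: float
    seed: int
    smoothness_nu: float = 1.0

    def __post_init__(self) -> None:
        self.fixed_spline_coefficients = np.asarray(self.fixed_spline_coefficients, float)
        self.city_deviations = np.atleast_2d(np.asarray(self.city_deviations, float))
        self.dow_effects = np.atleast_2d(np.asarray(self.dow_effects, float))
        if self.fixed_spline_coefficients.shape != (4,):
            raise ValueError("fixed_spline_coefficients must be a 4-vector")
        if self.city_deviations.shape[1] != 4:
            raise ValueError("city_deviations must have 4 columns")
        if self.dow_effects.shape[1] != 7:
            raise ValueError("dow_effects must have 7 columns")
        if np.abs(self.dow_effects.sum(axis=1)).max() > 1e-10:
            raise ValueError("each city's day-of-week effects must sum to zero")
        if self.residual_sd < 0:
            raise ValueError("residual_sd must be >= 0")
        if self.matern_range_km <= 0 or self.matern_sd < 0:
            raise ValueError("invalid Matérn hyperparameters")

    def true_curve(self, spec: SplineSpec, si_grid: np.ndarray, city: int | None = None) -> np.ndarray:
        """True mean change over an SI grid (fixed curve, or city's curve)."""
        coef = self.fixed_spline_coefficients.copy()
        if city is not None:
            coef = coef + self.city_deviations[city]
        return spec.basis(si_grid) @ coef

    def to_json(self, path) -> None:
        payload = {
            "fixed_spline_coefficients": self.fixed_spline_coefficients.tolist(),
            "city_deviations": self.city_deviations.tolist(),
            "dow_effects": self.dow_effects.tolist(),
            "ndvi_coef": self.ndvi_coef,
            "builtup_coef": self.builtup_coef,
            "residual_sd": self.residual_sd,
            "matern_range_km": self.matern_range_km,
            "matern_sd": self.matern_sd,
            "seed": self.seed,
            "smoothness_nu": self.smoothness_nu,
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path) -> "SyntheticTruth":
        return cls(**json.loads(Path(path).read_text()))


def generate_cities(n: int, seed: int) -> list[City]:
    """n synthetic cities in a Europe-like box (lon -10..30, lat 35..65).

    Populations are log-uniform in [1e5, 1e7]; crude death rates uniform in
    [0.008, 0.012] per person-year; NDVI and built-up share uniform on
    plausible urban ranges.  Most cities get their own country, with every
    fifth city sharing its predecessor's country so within-country sharing
    of the policy series is exercised.
    """
    if n < 2:
        raise ValueError("need at least 2 cities (spatial covariance undefined for fewer)")
    rng = np.random.default_rng(seed)
    lon = rng.uniform(-10.0, 30.0, n)
    lat = rng.uniform(35.0, 65.0, n)
    population = 10 ** rng.uniform(5.0, 7.0, n)
    cdr = rng.uniform(0.008, 0.012, n)
    ndvi = rng.uniform(0.1, 0.6, n)
    builtup = rng.uniform(0.05, 0.6, n)
    cities = []
    for i in range(n):
        country_idx = i - 1 if (i % 5 == 4) else i
        cities.append(
            City(
                city_id=f"city{i:03d}",
                name=f"City {i:03d}",
                country=f"country{country_idx:03d}",
                lon=float(lon[i]),
                lat=float(lat[i]),
                population=float(population[i]),
                ndvi=float(ndvi[i]),
                builtup=float(builtup[i]),
                crude_death_rate=float(cdr[i]),
            )
        )
    return cities


def generate_policy_panel(
    cities: list[City],
    start_date: date = DEFAULT_START,
    end_date: date = DEFAULT_END,
    seed: int = 0,
) -> pd.DataFrame:
    """Daily levels of the nine SI indicators, shared within each country.

    Every indicator sits at 0 until a country-specific onset (about a fifth
    of the way through the window: early/mid March for the default window),
    steps up to near-maximum within about ten days, plateaus, and steps down
    after a country-specific relaxation date (mid-May onwards by default).
    Each indicator series has at most five change-points.
    """
    if not cities:
        raise ValueError("empty city list")
    if not start_date < end_date:
        raise ValueError("start_date must precede end_date")
    dates = pd.date_range(start_date, end_date, freq="D")
    n_days = len(dates)
    rng = np.random.default_rng(seed)
    countries = sorted({c.country for c in cities})
    country_levels: dict[str, dict[str, np.ndarray]] = {}
    for country in countries:
        onset = int(n_days * rng.uniform(0.18, 0.28))
        relax = int(n_days * rng.uniform(0.58, 0.72))
        levels = {}
        for ind, max_level in SI_INDICATORS.items():
            top = max_level if rng.random() < 0.8 else max(1, max_level - 1)
            series = np.zeros(n_days, dtype=int)
            # stepwise ramp-up over ~10 days, in two or three steps
            step1 = min(onset + int(rng.integers(3, 7)), n_days)
            series[onset:] = max(1, top // 2)
            series[step1:] = top
            # stepwise relaxation: halfway down, then to a low floor
            if relax < n_days:
                mid = max(1, top // 2)
                floor = int(rng.integers(0, 2)) if mid > 0 else 0
                step2 = min(relax + int(rng.integers(10, 25)), n_days)
                series[relax:] = mid
                series[step2:] = min(floor, mid)
            levels[ind] = np.minimum(series, max_level)
        country_levels[country] = levels
    rows = []
    for c in cities:
        levels = country_levels[c.country]
        for ind, max_level in SI_INDICATORS.items():
            rows.append(
                pd.DataFrame(
                    {
                        "city_id": c.city_id,
                        "date": dates,
                        "indicator_id": ind,
                        "level": levels[ind],
                        "max_level": max_level,
                    }
                )
            )
    return pd.concat(rows, ignore_index=True)


def sample_city_deviations(
    cities: list[City],
    range_km: float,
    sd: float,
    nu: float = 1.0,
    n_fields: int = 4,
    seed: int | None = None,
) -> np.ndarray:
    """(n_cities, n_fields) independent Matérn Gaussian field draws."""
    return sample_matern_fields(
        city_coords(cities), range_km, sd, nu=nu, n_fields=n_fields,
        rng=np.random.default_rng(seed),
    )


def default_truth(
    cities: list[City],
    spec: SplineSpec,
    seed: int,
    curve=default_target_curve,
    residual_sd: float = 1.5,
    matern_range_km: float = 600.0,
    matern_sd: float = 0.8,
    dow_sd: float = 0.3,
    ndvi_coef: float = -0.5,
    builtup_coef: float = 0.8,
) -> SyntheticTruth:
    """Ground truth whose fixed curve matches ``curve`` on the spline span.

    The fixed spline coefficients are the least-squares projection of the
    target curve onto the anchored basis over a dense SI grid, so the "true
    curve" used in recovery experiments is exactly representable.
    """
    lo, hi = spec.boundary
    grid = np.linspace(lo, hi, 200)
    basis = spec.basis(grid)
    beta, *_ = np.linalg.lstsq(basis, curve(grid), rcond=None)
    rng = np.random.default_rng(seed)
    b = sample_city_deviations(
        cities, matern_range_km, matern_sd, n_fields=4,
        seed=int(rng.integers(2**31 - 1)),
    )
    dow = rng.normal(0.0, dow_sd, size=(len(cities), 7))
    dow -= dow.mean(axis=1, keepdims=True)
    return SyntheticTruth(
        fixed_spline_coefficients=beta,
        city_deviations=b,
        dow_effects=dow,
        ndvi_coef=ndvi_coef,
        builtup_coef=builtup_coef,
        residual_sd=residual_sd,
        matern_range_km=matern_range_km,
        matern_sd=matern_sd,
        seed=seed,
    )


def generate_pollution_panel(
    cities: list[City],
    si_series: pd.DataFrame,
    truth: SyntheticTruth,
    pollutant: str = "no2",
    spec: SplineSpec | None = None,
) -> pd.DataFrame:
    """Daily pollutant differences from the generative model.

    y_it = sum_k (beta_k + b_ik) B_k(SI_it) + dow effect + gamma2 NDVI_i(z)
    + gamma3 BuiltUp_i(z) + Normal(0, residual_sd) noise, with the anchored
    natural-spline basis built from the pooled SI distribution (or an
    explicit ``spec``).  Deterministic given ``truth.seed``.
    """
    if truth.city_deviations.shape[0] != len(cities):
        raise ValueError("truth.city_deviations rows must match number of cities")
    si = si_series.copy()
    si["date"] = pd.to_datetime(si["date"])
    vals = si["si"].to_numpy(dtype=float)
    if np.any((vals < 0) | (vals > 100)):
        raise ValueError("SI values outside [0, 100]")
    if spec is None:
        if np.unique(vals).size >= 5:
            spec = SplineSpec.from_si_values(vals)
        else:
            # degenerate SI support (e.g. all zeros): fixed fallback knots
            spec = SplineSpec((20.0, 40.0, 60.0), (0.0, 80.0))
    city_index = {c.city_id: i for i, c in enumerate(cities)}
    missing = set(si["city_id"]) - set(city_index)
    if missing:
        raise ValueError(f"SI series contains unknown cities: {sorted(missing)[:3]}")
    si = si.sort_values(["city_id", "date"]).reset_index(drop=True)
    idx = si["city_id"].map(city_index).to_numpy()
    basis = spec.basis(si["si"].to_numpy(dtype=float))
    coef = truth.fixed_spline_coefficients[None, :] + truth.city_deviations[idx]
    y = np.einsum("nk,nk->n", basis, coef)
    dow = si["date"].dt.dayofweek.to_numpy()
    y += truth.dow_effects[idx, dow]
    ndvi_z, built_z = zscore_covariates(cities)
    y += truth.ndvi_coef * ndvi_z[idx] + truth.builtup_coef * built_z[idx]
    if truth.residual_sd > 0:
        rng = np.random.default_rng([truth.seed, sum(ord(ch) for ch in pollutant)])
        y = y + rng.normal(0.0, truth.residual_sd, size=len(y))
    return pd.DataFrame(
        {"city_id": si["city_id"], "date": si["date"], "pollutant": pollutant, "y": y}
    )


def generate_policy_pollution_panel(
    cities: list[City],
    policies: pd.DataFrame,
    policy_id: str,
    truth: SyntheticTruth,
    alpha: float,
    a_city: np.ndarray | None = None,
    pollutant: str = "no2",
    spec: SplineSpec | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Pollutant panel with an explicit per-policy term injected.

    Builds y from the usual structure on the *leave-one-out* SI, then adds
    (alpha + a_i) z_it for the studied policy, matching the decomposition
    model's generative form.  Returns (panel, si_loo, z_series).
    """
    from .stringency import si_without, standardize_policy_variable

    si_loo = si_without(policies, policy_id)
    z = standardize_policy_variable(policies, policy_id, validate=False)
    panel = generate_pollution_panel(cities, si_loo, truth, pollutant=pollutant, spec=spec)
    city_index = {c.city_id: i for i, c in enumerate(cities)}
    merged = panel.merge(z, on=["city_id", "date"], how="left")
    if merged["z"].isna().any():
        raise ValueError("policy panel does not cover the SI series")
    a = np.zeros(len(cities)) if a_city is None else np.asarray(a_city, dtype=float)
    idx = merged["city_id"].map(city_index).to_numpy()
    panel = panel.copy()
    panel["y"] = merged["y"].to_numpy() + (alpha + a[idx]) * merged["z"].to_numpy()
    return panel, si_loo, z


@dataclass
class SyntheticDataset:
    """A complete generated study: inputs plus the truth that produced them."""

    cities: list[City]
    policies: pd.DataFrame
    si: pd.DataFrame
    spec: SplineSpec
    truth: SyntheticTruth
    pollution: pd.DataFrame
    pollutant: str = "no2"
    start: date = DEFAULT_START
    end: date = DEFAULT_END

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_cities(self.cities, outdir / "cities.csv")
        write_policy_panel(self.policies, outdir / "policies.csv")
        si = self.si.copy()
        si["date"] = pd.to_datetime(si["date"]).dt.strftime("%Y-%m-%d")
        si.to_csv(outdir / "si.csv", index=False)
        pol = self.pollution.copy()
        pol["date"] = pd.to_datetime(pol["date"]).dt.strftime("%Y-%m-%d")
        pol.to_csv(outdir / "pollution.csv", index=False)
        self.truth.to_json(outdir / "truth.json")


def generate_dataset(
    n_cities: int = 47,
    seed: int = 1,
    start_date: date = DEFAULT_START,
    end_date: date = DEFAULT_END,
    pollutant: str = "no2",
    truth_kwargs: dict | None = None,
) -> SyntheticDataset:
    """Generate a full synthetic study (cities, policies, SI, pollution, truth)."""
    cities = generate_cities(n_cities, seed)
    policies = generate_policy_panel(cities, start_date, end_date, seed=seed + 1)
    si = compute_si(policies)
    spec = SplineSpec.from_si_values(si["si"].to_numpy(dtype=float))
    truth = default_truth(cities, spec, seed=seed + 2, **(truth_kwargs or {}))
    pollution = generate_pollution_panel(cities, si, truth, pollutant=pollutant, spec=spec)
    return SyntheticDataset(
        cities=cities, policies=policies, si=si, spec=spec, truth=truth,
        pollution=pollution, pollutant=pollutant, start=start_date, end=end_date,
    )
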