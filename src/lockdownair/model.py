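"""Spatially structured Bayesian non-linear mixed model of pollutant change
on lockdown stringency.

The model for the daily pollutant difference (Lockdown - BAU) y_it of city i
on day t is

    y_it = f(x_it; beta + b_i) + gamma1_i[DOW_t] + gamma2 NDVI_i
           + gamma3 BuiltUp_i + eps_it,

where x_it is the daily Stringency Index, f is a natural cubic spline with
four degrees of freedom (knots at the pooled 25/50/75% SI quantiles)
anchored at SI = 0, beta the shared spline coefficients and b_i
city-specific deviations.  Each of the four deviation coordinates carries an
independent Matérn Gaussian-process prior over great-circle distance with
penalized-complexity hyperpriors.  Day-of-week effects gamma1_i are
city-specific and constrained to sum to zero per city; NDVI and built-up
area are z-scored across cities.  There is no intercept anywhere: at SI = 0
the model predicts exactly zero change for every city.

Usage follows the Model/Results convention::

    model = StringencyPollutionModel(pollution, si, cities)
    res = model.fit(seed=1)
    res.summary()
    res.predict_curve()          # Fig. 2-style average curve with 95% CrI
    res.predict_at_si(80.0)      # Fig. 3-style per-city change at SI = 80
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cities import City, city_coords, zscore_covariates
from .engine import (
    EngineSettings,
    FlatComponent,
    LinearGaussianModel,
    MaternComponent,
    Posterior,
    sum_to_zero_contrast,
)
from .spatial import PCPrior
from .splines import SplineSpec

SPLINE_DIM = 4
DOW_LEVELS = 7


def _aligned_design_frame(
    panel: pd.DataFrame, si: pd.DataFrame, cities: list[City]
) -> pd.DataFrame:
    """Merge pollutant and SI panels on (city, date); validate alignment."""
    pollutants = panel["pollutant"].unique()
    if len(pollutants) != 1:
        raise ValueError(f"one pollutant per fit; got {sorted(pollutants)}")
    p = panel.copy()
    p["date"] = pd.to_datetime(p["date"])
    s = si.copy()
    s["date"] = pd.to_datetime(s["date"])
    merged = p.merge(s[["city_id", "date", "si"]], on=["city_id", "date"], how="left")
    if merged["si"].isna().any():
        missing = merged.loc[merged["si"].isna(), ["city_id", "date"]].head(3)
        raise ValueError(f"SI series does not cover all city-days, e.g.\n{missing}")
    known = {c.city_id for c in cities}
    unknown = set(merged["city_id"]) - known
    if unknown:
        raise ValueError(f"panel contains cities without metadata: {sorted(unknown)[:3]}")
    if not np.isfinite(merged["y"].to_numpy(dtype=float)).all():
        raise ValueError("pollutant differences contain non-finite values")
    return merged.sort_values(["city_id", "date"]).reset_index(drop=True)


def build_design(
    frame: pd.DataFrame,
    cities: list[City],
    spec: SplineSpec,
    pc_prior: PCPrior,
    nu: float = 1.0,
) -> tuple[list, np.ndarray, dict]:
    """Assemble the design components shared by both regression stages.

    Returns (components, y, info) where components hold the fixed spline
    block, the four Matérn city-deviation blocks, the per-city sum-to-zero
    day-of-week block and the z-scored covariate block.
    """
    order = [c.city_id for c in cities]
    present = set(frame["city_id"])
    fit_cities = [c for c in cities if c.city_id in present]
    if not fit_cities:
        raise ValueError("no overlap between panel and city metadata")
    city_index = {c.city_id: i for i, c in enumerate(fit_cities)}
    idx = frame["city_id"].map(city_index).to_numpy()
    n, nc = len(frame), len(fit_cities)

    basis = spec.basis(frame["si"].to_numpy(dtype=float))
    onehot = np.zeros((n, nc))
    onehot[np.arange(n), idx] = 1.0

    coords = city_coords(fit_cities)
    components: list = [FlatComponent("beta", basis)]
    for k in range(SPLINE_DIM):
        components.append(
            MaternComponent(f"b{k}", onehot * basis[:, [k]], coords, pc_prior, nu)
        )
    contrast = sum_to_zero_contrast(DOW_LEVELS)
    dow = frame["date"].dt.dayofweek.to_numpy()
    dow_full = np.zeros((n, DOW_LEVELS))
    dow_full[np.arange(n), dow] = 1.0
    dow_design = np.zeros((n, nc * (DOW_LEVELS - 1)))
    dow_free = dow_full @ contrast  # (n, 6)
    for i in range(nc):
        cols = slice(i * (DOW_LEVELS - 1), (i + 1) * (DOW_LEVELS - 1))
        dow_design[:, cols] = dow_free * onehot[:, [i]]
    components.append(FlatComponent("dow", dow_design))
    ndvi_z, built_z = zscore_covariates(fit_cities)
    components.append(
        FlatComponent("covariates", np.column_stack([ndvi_z[idx], built_z[idx]]))
    )
    y = frame["y"].to_numpy(dtype=float)
    info = {
        "cities": fit_cities,
        "city_index": city_index,
        "contrast": contrast,
        "basis": basis,
        "row_city": idx,
        "dropped": [cid for cid in order if cid not in present],
    }
    return components, y, info


class StringencyPollutionModel:
    """Model object: daily pollutant change regressed on the Stringency Index.

    Parameters
    ----------
    panel : long pollutant-difference frame (city_id, date, pollutant, y),
        a single pollutant.
    si : stringency series (city_id, date, si in [0, 100]).
    cities : city metadata records (coordinates, NDVI, built-up area).
    spec : spline specification; derived from the pooled SI distribution
        when omitted.
    pc_prior : penalized-complexity prior settings shared by the four
        Matérn fields.
    nu : Matérn smoothness (default 1, the standard choice in 2-D).
    """

    def __init__(
        self,
        panel: pd.DataFrame,
        si: pd.DataFrame,
        cities: list[City],
        spec: SplineSpec | None = None,
        pc_prior: PCPrior | None = None,
        nu: float = 1.0,
    ):
        self.frame = _aligned_design_frame(panel, si, cities)
        self.pollutant = str(self.frame["pollutant"].iloc[0])
        if spec is None:
            spec = SplineSpec.from_si_values(self.frame["si"].to_numpy(dtype=float))
        self.spec = spec
        self.pc_prior = pc_prior or PCPrior()
        self.nu = nu
        self.components, self.y, self.info = build_design(
            self.frame, cities, spec, self.pc_prior, nu
        )
        self.cities = self.info["cities"]
        self.engine = LinearGaussianModel(self.y, self.components)

    def fit(
        self,
        seed: int,
        n_draws: int = 1000,
        settings: EngineSettings | None = None,
    ) -> "PollutionResults":
        settings = settings or EngineSettings()
        settings.seed = seed
        settings.n_draws = n_draws
        posterior = self.engine.fit(settings)
        return PollutionResults(self, posterior)


@dataclass
class PollutionResults:
    """Posterior fit of the stringency-pollution model.

    Exposes draws of every model block, posterior-predictive curves over the
    SI range (Fig. 2 analogue) and per-city predictions at a fixed SI
    (Fig. 3 analogue).
    """

    model: StringencyPollutionModel
    posterior: Posterior
    _gamma1_cache: np.ndarray | None = field(default=None, repr=False)

    # -- draw accessors -----------------------------------------------------
    @property
    def beta_draws(self) -> np.ndarray:
        """(n_draws, 4) fixed spline coefficients."""
        return self.posterior.block("beta")

    @property
    def b_draws(self) -> np.ndarray:
        """(n_draws, n_cities, 4) city deviations."""
        s = self.posterior.draws.shape[0]
        nc = len(self.model.cities)
        out = np.empty((s, nc, SPLINE_DIM))
        for k in range(SPLINE_DIM):
            out[:, :, k] = self.posterior.block(f"b{k}")
        return out

    @property
    def gamma1_draws(self) -> np.ndarray:
        """(n_draws, n_cities, 7) day-of-week effects; each row sums to 0."""
        if self._gamma1_cache is None:
            free = self.posterior.block("dow")
            s = free.shape[0]
            nc = len(self.model.cities)
            contrast = self.model.info["contrast"]
            self._gamma1_cache = np.einsum(
                "snk,jk->snj", free.reshape(s, nc, DOW_LEVELS - 1), contrast
            )
        return self._gamma1_cache

    @property
    def gamma2_draws(self) -> np.ndarray:
        return self.posterior.block("covariates")[:, 0]

    @property
    def gamma3_draws(self) -> np.ndarray:
        return self.posterior.block("covariates")[:, 1]

    @property
    def residual_sd_draws(self) -> np.ndarray:
        return self.posterior.sigma_draws

    @property
    def diagnostics(self) -> dict:
        return self.posterior.diagnostics

    def spatial_hyperparameters(self) -> pd.DataFrame:
        """Posterior summaries of each spatial field's (range_km, sd)."""
        rows = []
        for k in range(SPLINE_DIM):
            hyp = self.posterior.hyper_draws(f"b{k}")
            for name, draws in hyp.items():
                rows.append(
                    {
                        "field": f"b{k}",
                        "parameter": name,
                        "mean": float(draws.mean()),
                        "lo95": float(np.percentile(draws, 2.5)),
                        "hi95": float(np.percentile(draws, 97.5)),
                    }
                )
        return pd.DataFrame(rows)

    # -- prediction ---------------------------------------------------------
    def _curve_draws(self, si_grid: np.ndarray, city_id: str | None) -> np.ndarray:
        basis = self.model.spec.basis(si_grid)
        coef = self.beta_draws
        if city_id is not None:
            i = self.model.info["city_index"].get(city_id)
            if i is None:
                raise KeyError(f"unknown city_id {city_id!r}")
            coef = coef + self.b_draws[:, i, :]
        return coef @ basis.T  # (n_draws, n_grid)

    def predict_curve(
        self,
        si_grid: np.ndarray | None = None,
        city_id: str | None = None,
    ) -> pd.DataFrame:
        """Posterior mean and 95% credible band of f over an SI grid.

        The curve isolates the spline term: the shared beta for the average
        curve, beta + b_i for a city.  DOW and covariate terms are excluded.
        Default grid: SI 0..80 (higher levels were rarely observed).
        """
        if si_grid is None:
            si_grid = np.linspace(0.0, 80.0, 81)
        si_grid = np.asarray(si_grid, dtype=float)
        lo, hi = self.model.spec.boundary
        extrapolated = (si_grid < lo) | (si_grid > hi)
        if extrapolated.any():
            warnings.warn(
                "SI grid extends beyond the fitted boundary; curve is a linear "
                "extrapolation there",
                RuntimeWarning,
                stacklevel=2,
            )
        draws = self._curve_draws(si_grid, city_id)
        return pd.DataFrame(
            {
                "si": si_grid,
                "mean": draws.mean(axis=0),
                "lo95": np.percentile(draws, 2.5, axis=0),
                "hi95": np.percentile(draws, 97.5, axis=0),
                "extrapolated": extrapolated,
            }
        )

    def predict_at_si(self, si: float) -> pd.DataFrame:
        """Per-city posterior mean and 95% credible limits of change at one SI."""
        grid = np.array([float(si)])
        rows = []
        for c in self.model.cities:
            draws = self._curve_draws(grid, c.city_id)[:, 0]
            rows.append(
                {
                    "city_id": c.city_id,
                    "mean": float(draws.mean()),
                    "lo95": float(np.percentile(draws, 2.5)),
                    "hi95": float(np.percentile(draws, 97.5)),
                }
            )
        return pd.DataFrame(rows)

    def fitted_draws(self) -> np.ndarray:
        """(n_draws, n_obs) posterior draws of the linear predictor."""
        return self.model.engine.fitted_draws(self.posterior)

    # -- reporting ----------------------------------------------------------
    def summary(self) -> str:
        """Plain-text posterior summary table."""

        def ci(d):
            return f"{d.mean():9.3f} [{np.percentile(d, 2.5):8.3f}, {np.percentile(d, 97.5):8.3f}]"

        lines = [
            f"Stringency-pollution model: {self.model.pollutant}",
            f"  cities: {len(self.model.cities)}   observations: {self.model.engine.n}",
            f"  spline knots: {self.model.spec.interior_knots} "
            f"boundary: {self.model.spec.boundary}",
            f"  converged: {self.diagnostics['converged']}",
            "",
            "  coefficient        mean [95% CrI]",
        ]
        for k in range(SPLINE_DIM):
            lines.append(f"  beta[{k}]      {ci(self.beta_draws[:, k])}")
        lines.append(f"  gamma2 (NDVI) {ci(self.gamma2_draws)}")
        lines.append(f"  gamma3 (BU)   {ci(self.gamma3_draws)}")
        lines.append(f"  residual sd   {ci(self.residual_sd_draws)}")
        for _, r in self.spatial_hyperparameters().iterrows():
            lines.append(
                f"  {r['field']}.{r['parameter']:<9} {r['mean']:9.3f} "
                f"[{r['lo95']:8.3f}, {r['hi95']:8.3f}]"
            )
        return "\n".join(lines)

    def curve_table(self, si_grid: np.ndarray | None = None) -> pd.DataFrame:
        """Average curve table in the (si, mean, lo95, hi95) CSV dialect."""
        return self.predict_curve(si_grid)[["si", "mean", "lo95", "hi95"]]

    def plot_curve(self, si_grid: np.ndarray | None = None, ax=None):
        """Average exposure-response curve with its 95% band and thin
        per-city curves (Fig.-style display).  Returns the axes."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(6, 4))
        for c in self.model.cities:
            city = self.predict_curve(si_grid, city_id=c.city_id)
            ax.plot(city["si"], city["mean"], color="0.75", lw=0.6, zorder=1)
        avg = self.predict_curve(si_grid)
        ax.fill_between(avg["si"], avg["lo95"], avg["hi95"], alpha=0.3, zorder=2)
        ax.plot(avg["si"], avg["mean"], lw=2.0, zorder=3)
        ax.axhline(0.0, color="k", lw=0.5)
        ax.set_xlabel("Stringency Index (%)")
        ax.set_ylabel(f"{self.model.pollutant} change (µg/m³)")
        return ax
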