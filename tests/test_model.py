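"""Stringency-pollution model: identifiability, recovery, prediction
contracts and calibration of the marginal-likelihood engine."""

import datetime as dt
import warnings

import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

from lockdownair import StringencyPollutionModel, compute_si, generate_dataset
from lockdownair.engine import EngineSettings
from lockdownair.spatial import PCPrior
from lockdownair.splines import SplineSpec
from lockdownair.synthetic import (
    SyntheticTruth,
    default_truth,
    generate_cities,
    generate_policy_panel,
    generate_pollution_panel,
)

from conftest import curve_recovery_metrics


@pytest.fixture(scope="module")
def zero_noise_fit():
    """Known truth with no city deviations, DOW effects or noise."""
    cities = generate_cities(8, 1)
    si = compute_si(generate_policy_panel(cities, seed=2))
    spec = SplineSpec.from_si_values(si["si"].to_numpy())
    beta = np.array([-2.0, -5.0, -8.0, -9.0])
    truth = SyntheticTruth(
        beta, np.zeros((8, 4)), np.zeros((8, 7)), -0.5, 0.8, 0.0, 600.0, 0.0, seed=0
    )
    panel = generate_pollution_panel(cities, si, truth, spec=spec)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        res = StringencyPollutionModel(panel, si, cities, spec=spec).fit(
            seed=3, n_draws=200
        )
    return truth, spec, res


def test_noiseless_identifiability(zero_noise_fit):
    """With zero noise the posterior mean curve reproduces the truth."""
    truth, spec, res = zero_noise_fit
    grid = np.linspace(0.0, 80.0, 41)
    err = np.abs(
        res.predict_curve(grid)["mean"].to_numpy() - truth.true_curve(spec, grid)
    ).max()
    assert err < 1e-3


def test_no_intercept_prediction_zero_at_si_zero(zero_noise_fit, small_fit):
    """Anchored basis + sum-to-zero DOW: change at SI=0 is exactly 0."""
    for res in (zero_noise_fit[2], small_fit):
        at0 = res.predict_at_si(0.0)
        np.testing.assert_array_equal(at0[["mean", "lo95", "hi95"]].to_numpy(), 0.0)
        curve0 = res.predict_curve(np.array([0.0]))
        assert float(curve0["hi95"].iloc[0] - curve0["lo95"].iloc[0]) == 0.0


def test_spatial_sd_to_zero_reduces_to_penalized_least_squares():
    """Forcing the spatial sd to zero recovers the non-spatial ridge fit."""
    cities = generate_cities(8, 1)
    si = compute_si(generate_policy_panel(cities, seed=2))
    spec = SplineSpec.from_si_values(si["si"].to_numpy())
    truth = default_truth(cities, spec, seed=9, matern_sd=0.0)
    panel = generate_pollution_panel(cities, si, truth, spec=spec)
    tight = PCPrior(range0=500.0, alpha_range=0.5, sd0=1e-5, alpha_sd=1e-8)
    model = StringencyPollutionModel(panel, si, cities, spec=spec, pc_prior=tight)
    res = model.fit(seed=4, n_draws=400)
    # oracle: flat-prior penalized LS on the design without deviation blocks
    x = np.concatenate(
        [c.x for c in model.components if c.name in ("beta", "dow", "covariates")],
        axis=1,
    )
    sig2 = float(res.residual_sd_draws.mean()) ** 2
    prec = x.T @ x / sig2 + np.eye(x.shape[1]) / 1e6
    oracle = np.linalg.solve(prec, x.T @ model.y / sig2)[:4]
    assert np.abs(res.beta_draws.mean(axis=0) - oracle).max() < 0.06


def test_credible_band_is_percentiles_of_draws(small_fit):
    grid = np.linspace(0.0, 80.0, 17)
    curve = small_fit.predict_curve(grid)
    draws = small_fit.beta_draws @ small_fit.model.spec.basis(grid).T
    np.testing.assert_allclose(curve["lo95"], np.percentile(draws, 2.5, axis=0))
    np.testing.assert_allclose(curve["hi95"], np.percentile(draws, 97.5, axis=0))


def test_city_curve_minus_average_is_deviation_spline(small_fit):
    grid = np.linspace(0.0, 80.0, 9)
    cid = small_fit.model.cities[0].city_id
    city = small_fit._curve_draws(grid, cid)
    avg = small_fit._curve_draws(grid, None)
    dev = small_fit.b_draws[:, 0, :] @ small_fit.model.spec.basis(grid).T
    np.testing.assert_allclose(city - avg, dev, atol=1e-10)


def test_predict_at_si_consistent_with_curve(small_fit):
    at = small_fit.predict_at_si(60.0)
    for i, c in enumerate(small_fit.model.cities):
        curve = small_fit.predict_curve(np.array([60.0]), city_id=c.city_id)
        assert at.loc[i, "mean"] == pytest.approx(float(curve["mean"].iloc[0]))
        assert at.loc[i, "lo95"] == pytest.approx(float(curve["lo95"].iloc[0]))


def test_gamma1_draws_sum_to_zero_per_city(small_fit):
    sums = small_fit.gamma1_draws.sum(axis=2)
    assert np.abs(sums).max() < 1e-9


def test_posterior_predictive_mean_matches_sample_mean(small_fit):
    """Gaussian-likelihood calibration: fitted mean tracks the data mean."""
    fitted = small_fit.fitted_draws().mean()
    y = small_fit.model.y
    assert abs(fitted - y.mean()) < 0.05 * y.std()


def test_full_scale_curve_recovery(full_scale_experiment):
    ds, res = full_scale_experiment
    rmse_frac, coverage = curve_recovery_metrics(ds, res)
    assert rmse_frac <= 0.20
    assert coverage >= 0.85
    assert res.diagnostics["converged"]


def test_city_ranking_recovery_under_heterogeneity():
    """Predicted per-city change at SI=80 ranks cities like the truth when
    between-city heterogeneity dominates the noise."""
    ds = generate_dataset(
        n_cities=30, seed=11, pollutant="no2",
        truth_kwargs=dict(matern_sd=2.0, residual_sd=1.0),
    )
    res = StringencyPollutionModel(ds.pollution, ds.si, ds.cities, spec=ds.spec).fit(
        seed=3, n_draws=400
    )
    at80 = res.predict_at_si(80.0)
    b80 = ds.spec.basis(np.array([80.0]))[0]
    true80 = ds.truth.city_deviations @ b80 + ds.truth.fixed_spline_coefficients @ b80
    assert spearmanr(at80["mean"], true80).statistic >= 0.8


def test_simulation_based_calibration_beta_coverage():
    """95% interval coverage for the fixed spline coefficients across 20
    small replicates stays near nominal."""
    hits = total = 0
    for rep in range(20):
        seed = 300 + rep
        cities = generate_cities(10, seed)
        si = compute_si(
            generate_policy_panel(cities, dt.date(2020, 2, 1), dt.date(2020, 4, 1), seed=seed + 1)
        )
        spec = SplineSpec.from_si_values(si["si"].to_numpy())
        truth = default_truth(cities, spec, seed=seed + 2)
        panel = generate_pollution_panel(cities, si, truth, spec=spec)
        res = StringencyPollutionModel(panel, si, cities, spec=spec).fit(
            seed=seed + 3, n_draws=300
        )
        lo = np.percentile(res.beta_draws, 2.5, axis=0)
        hi = np.percentile(res.beta_draws, 97.5, axis=0)
        hits += int(np.sum((lo <= truth.fixed_spline_coefficients) & (truth.fixed_spline_coefficients <= hi)))
        total += 4
    assert 0.80 <= hits / total <= 1.0


def test_validation_errors():
    ds = generate_dataset(n_cities=4, seed=19)
    two = ds.pollution.copy()
    two.loc[two.index[:10], "pollutant"] = "o3"
    with pytest.raises(ValueError, match="one pollutant"):
        StringencyPollutionModel(two, ds.si, ds.cities)
    gap_si = ds.si.iloc[: len(ds.si) // 2]
    with pytest.raises(ValueError, match="cover"):
        StringencyPollutionModel(ds.pollution, gap_si, ds.cities)


def test_fit_requires_seed():
    ds = generate_dataset(n_cities=4, seed=23)
    model = StringencyPollutionModel(ds.pollution, ds.si, ds.cities, spec=ds.spec)
    with pytest.raises(ValueError, match="seed"):
        model.engine.fit(EngineSettings(seed=None))


def test_extrapolation_warns(small_fit):
    hi = small_fit.model.spec.boundary[1]
    with pytest.warns(RuntimeWarning, match="boundary"):
        curve = small_fit.predict_curve(np.array([hi + 10.0]))
    assert bool(curve["extrapolated"].iloc[0])
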