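"""Shared fixtures: synthetic study generation and the expensive model fits.

The recovery experiments (full-size Eq.-style fits, replicated null
calibration) are session-scoped so unit tests and the acceptance checks
reuse one computation.
"""

from __future__ import annotations

import datetime as dt

import numpy as np
import pytest

from lockdownair import StringencyPollutionModel, generate_dataset
from lockdownair.policy import PolicyEffectModel
from lockdownair.splines import SplineSpec
from lockdownair.stringency import si_without
from lockdownair.synthetic import (
    default_truth,
    generate_cities,
    generate_policy_panel,
    generate_policy_pollution_panel,
    sample_city_deviations,
)

FULL_SEED = 20200201
POLICY_SEED = 20200301


@pytest.fixture(scope="session")
def small_dataset():
    """12 cities over the full study window: quick, fully featured."""
    return generate_dataset(n_cities=12, seed=3, pollutant="no2")


@pytest.fixture(scope="session")
def small_fit(small_dataset):
    model = StringencyPollutionModel(
        small_dataset.pollution, small_dataset.si, small_dataset.cities,
        spec=small_dataset.spec,
    )
    return model.fit(seed=5, n_draws=400)


@pytest.fixture(scope="session")
def full_scale_experiment():
    """47 cities x 182 days recovery experiment with fixed seeds."""
    ds = generate_dataset(n_cities=47, seed=FULL_SEED, pollutant="no2")
    model = StringencyPollutionModel(ds.pollution, ds.si, ds.cities, spec=ds.spec)
    res = model.fit(seed=7, n_draws=500)
    return ds, res


@pytest.fixture(scope="session")
def policy_recovery_experiment():
    """Eq.-2-style recovery: known alpha injected for one policy, 47 cities."""
    alpha_true = -2.0
    cities = generate_cities(47, POLICY_SEED)
    policies = generate_policy_panel(cities, seed=POLICY_SEED + 1)
    si_loo = si_without(policies, "C6")
    spec = SplineSpec.from_si_values(si_loo["si"].to_numpy())
    truth = default_truth(cities, spec, seed=POLICY_SEED + 2)
    a = sample_city_deviations(cities, 600.0, 0.5, seed=POLICY_SEED + 3)[:, 0]
    panel, _, _ = generate_policy_pollution_panel(
        cities, policies, "C6", truth, alpha_true, a_city=a, spec=spec
    )
    res = PolicyEffectModel(panel, policies, "C6", cities, spec=spec).fit(
        seed=9, n_draws=400
    )
    return alpha_true, res


@pytest.fixture(scope="session")
def null_policy_replicates():
    """20 small replicates with alpha = 0: per-replicate 95% CrIs for alpha."""
    intervals = []
    for rep in range(20):
        seed = 1000 + rep
        cities = generate_cities(10, seed)
        policies = generate_policy_panel(
            cities, dt.date(2020, 2, 1), dt.date(2020, 4, 30), seed=seed + 1
        )
        si_loo = si_without(policies, "C2")
        spec = SplineSpec.from_si_values(si_loo["si"].to_numpy())
        truth = default_truth(cities, spec, seed=seed + 2)
        panel, _, _ = generate_policy_pollution_panel(
            cities, policies, "C2", truth, 0.0, spec=spec
        )
        res = PolicyEffectModel(panel, policies, "C2", cities, spec=spec).fit(
            seed=seed + 3, n_draws=300
        )
        e = res.effect()
        intervals.append((e.alpha_lo95, e.alpha_hi95))
    return intervals


def curve_recovery_metrics(ds, res, si_max=80.0, n_grid=41):
    """RMSE (as a fraction of the true curve's range) and 95% CrI coverage."""
    grid = np.linspace(0.0, si_max, n_grid)
    true = ds.truth.true_curve(ds.spec, grid)
    curve = res.predict_curve(grid)
    rmse = float(np.sqrt(np.mean((curve["mean"].to_numpy() - true) ** 2)))
    coverage = float(
        np.mean((curve["lo95"].to_numpy() <= true) & (true <= curve["hi95"].to_numpy()))
    )
    return rmse / float(true.max() - true.min()), coverage
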