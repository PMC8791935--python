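"""Health impact assessment: risk conversion, the attributable-risk formula,
aggregation, Monte-Carlo intervals and the city/TOTAL report."""

import math

import numpy as np
import pandas as pd
import pytest

from lockdownair.cities import City
from lockdownair.datasets import load_reference_city_table, reference_table_totals
from lockdownair.hia import (
    HealthImpactAssessment,
    MortalityCoefficient,
    daily_burden,
    load_risk_config,
    make_report,
    mc_uncertainty,
    rr_to_xi,
    total_burden,
)


def make_city(i: int, population=1e6, cdr=0.01) -> City:
    return City(
        city_id=f"c{i}", name=f"C{i}", country="X", lon=float(i), lat=45.0,
        population=population, ndvi=0.3, builtup=0.3, crude_death_rate=cdr,
    )


def make_panel(city_ids, n_days=10, y=1.0, pollutant="no2", seed=None):
    dates = pd.date_range("2020-02-01", periods=n_days)
    rng = np.random.default_rng(seed)
    rows = []
    for cid in city_ids:
        vals = np.full(n_days, y) if seed is None else rng.normal(0, 5, n_days)
        rows.append(
            pd.DataFrame({"city_id": cid, "date": dates, "pollutant": pollutant, "y": vals})
        )
    return pd.concat(rows, ignore_index=True)


COEFF = rr_to_xi("no2", 1.01, 1.005, 1.015, 10.0)


class TestRiskConversion:
    def test_null_risk(self):
        c = rr_to_xi("no2", 1.0, 1.0, 1.0, 10.0)
        assert c.xi == 0.0 and c.xi_se == 0.0

    def test_hand_formula(self):
        c = rr_to_xi("no2", 1.01, 1.005, 1.015, 10.0)
        assert c.xi == pytest.approx(math.log(1.01) / 10.0)
        assert c.xi_se == pytest.approx(
            (math.log(1.015) - math.log(1.005)) / (2 * 1.96 * 10.0)
        )

    def test_doubling_increment_halves_coefficient(self):
        c10 = rr_to_xi("no2", 1.01, 1.005, 1.015, 10.0)
        c20 = rr_to_xi("no2", 1.01, 1.005, 1.015, 20.0)
        assert c20.xi == pytest.approx(c10.xi / 2)
        assert c20.xi_se == pytest.approx(c10.xi_se / 2)

    def test_disordered_ci_rejected(self):
        with pytest.raises(ValueError):
            rr_to_xi("no2", 1.01, 1.015, 1.005, 10.0)
        with pytest.raises(ValueError):
            MortalityCoefficient("no2", 0.001, -1.0, 1.01, 10.0, (1.0, 1.02))


class TestDailyBurden:
    def test_zero_change_or_zero_risk_gives_zero(self):
        assert daily_burden(0.0, 0.01, 1e6, 0.001) == 0.0
        assert daily_burden(5.0, 0.01, 1e6, 0.0) == 0.0

    def test_direct_formula_oracle(self):
        d = daily_burden(-10.0, 0.01, 1e6, 0.001)
        expected = (0.01 / 365.25) * 1e6 * (1.0 - math.exp(0.001 * 10.0))
        assert d == pytest.approx(expected, rel=1e-14)
        assert d < 0  # pollution decrease: avoided deaths

    def test_sign_convention(self):
        rng = np.random.default_rng(0)
        y = rng.normal(0, 10, 200)
        d = daily_burden(y, 0.01, 1e6, 0.001)
        np.testing.assert_array_equal(np.sign(d), np.sign(y))


class TestTotals:
    def test_zero_panel_zero_totals(self):
        res = total_burden(make_panel(["c0", "c1"], y=0.0), [make_city(0), make_city(1)], COEFF)
        assert (res.city_totals["total"] == 0).all() and res.grand_total == 0.0

    def test_constant_days_additivity(self):
        n = 12
        res = total_burden(make_panel(["c0"], n_days=n, y=-4.0), [make_city(0)], COEFF)
        one_day = daily_burden(-4.0, 0.01, 1e6, COEFF.xi)
        assert res.grand_total == pytest.approx(n * one_day, rel=1e-12)

    def test_date_split_additivity(self):
        cities = [make_city(0), make_city(1)]
        panel = make_panel(["c0", "c1"], n_days=30, seed=5)
        full = total_burden(panel, cities, COEFF)
        cut = panel["date"] < panel["date"].median()
        a = total_burden(panel[cut], cities, COEFF)
        b = total_burden(panel[~cut], cities, COEFF)
        assert full.grand_total == pytest.approx(a.grand_total + b.grand_total, rel=1e-12)

    def test_city_without_metadata_rejected(self):
        with pytest.raises(ValueError, match="death rate"):
            total_burden(make_panel(["c0", "ghost"]), [make_city(0)], COEFF)


class TestMonteCarlo:
    def test_zero_se_collapses_intervals_exactly(self):
        coeff = MortalityCoefficient("no2", 0.001, 0.0, 1.01, 10.0, (1.01, 1.01))
        res = mc_uncertainty(make_panel(["c0"], seed=2), [make_city(0)], coeff, n_mc=50, seed=1)
        assert res.grand_lo95 == res.grand_total == res.grand_hi95
        np.testing.assert_array_equal(res.city_totals["lo95"], res.city_totals["total"])
        np.testing.assert_array_equal(res.city_totals["hi95"], res.city_totals["total"])

    def test_seed_reproducibility(self):
        panel = make_panel(["c0", "c1"], seed=3)
        cities = [make_city(0), make_city(1)]
        a = mc_uncertainty(panel, cities, COEFF, n_mc=200, seed=9)
        b = mc_uncertainty(panel, cities, COEFF, n_mc=200, seed=9)
        pd.testing.assert_frame_equal(a.city_totals, b.city_totals)
        assert (a.grand_lo95, a.grand_hi95) == (b.grand_lo95, b.grand_hi95)

    def test_intervals_contain_point_for_small_se(self):
        panel = make_panel(["c0"], n_days=20, y=-6.0)
        for seed in (1, 2, 3):
            res = mc_uncertainty(panel, [make_city(0)], COEFF, n_mc=500, seed=seed)
            assert res.grand_lo95 <= res.grand_total <= res.grand_hi95

    def test_percentile_endpoints_stable_in_n_mc(self):
        """Doubling the draw count moves the endpoints by less than the
        Monte-Carlo standard error of the percentile estimator."""
        panel = make_panel(["c0"], n_days=20, y=-6.0)
        city = [make_city(0)]
        lo1k = mc_uncertainty(panel, city, COEFF, n_mc=1000, seed=4).grand_lo95
        lo2k = mc_uncertainty(panel, city, COEFF, n_mc=2000, seed=4).grand_lo95
        reps = [
            mc_uncertainty(panel, city, COEFF, n_mc=1000, seed=100 + k).grand_lo95
            for k in range(15)
        ]
        mc_se = np.std(reps, ddof=1)
        assert abs(lo2k - lo1k) < 4.0 * mc_se


class TestReport:
    def burdens(self, cities, panel_cities=None, seed=7):
        panel_cities = panel_cities or [c.city_id for c in cities]
        out = {}
        for pol in ("no2", "o3"):
            meta = [c for c in cities if c.city_id in panel_cities]
            out[pol] = mc_uncertainty(
                make_panel(panel_cities, pollutant=pol, seed=seed), meta,
                rr_to_xi(pol, 1.01, 1.005, 1.015, 10.0), n_mc=100, seed=seed
            )
        return out

    def test_total_row_sums_city_rows(self):
        cities = [make_city(i) for i in range(3)]
        report = make_report(self.burdens(cities), cities)
        total = report[report["city"] == "TOTAL"].iloc[0]
        body = report[report["city"] != "TOTAL"]
        assert total["population"] == pytest.approx(body["population"].sum())
        assert total["no2_total"] == pytest.approx(body["no2_total"].sum())

    def test_single_city_total_equals_city_row(self):
        cities = [make_city(0)]
        report = make_report(self.burdens(cities), cities)
        assert report.loc[1, "no2_total"] == pytest.approx(report.loc[0, "no2_total"])

    def test_city_without_burden_renders_na_and_is_excluded(self):
        cities = [make_city(i) for i in range(3)]
        burdens = self.burdens(cities, panel_cities=["c0", "c1"])
        report = make_report(burdens, cities)
        assert np.isnan(report.loc[2, "no2_total"])
        total = report[report["city"] == "TOTAL"].iloc[0]
        assert total["no2_total"] == pytest.approx(
            report.loc[[0, 1], "no2_total"].sum()
        )
        # population column still counts every city
        assert total["population"] == pytest.approx(3e6)

    def test_inconsistent_city_sets_rejected(self):
        cities = [make_city(i) for i in range(2)]
        burdens = self.burdens(cities)
        burdens["o3"] = self.burdens(cities, panel_cities=["c0"])["o3"]
        with pytest.raises(ValueError, match="inconsistent"):
            make_report(burdens, cities)


def test_reference_city_table_structure():
    table = load_reference_city_table()
    assert len(table) == 47
    na_rows = table[table["no2_deaths"].isna()]
    assert list(na_rows["city"]) == ["Pristina"]
    totals = reference_table_totals(table)
    assert totals["population"] > 8e7


def test_bundled_risk_config_loads():
    coeffs = load_risk_config()
    assert set(coeffs) == {"no2", "o3", "pm25", "pm10"}
    for c in coeffs.values():
        assert c.xi > 0 and c.xi_se > 0
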