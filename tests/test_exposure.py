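import numpy as np
import pandas as pd
import pytest

from pmcox.exposure import (
    ExposureError,
    ZipMonthSurface,
    fit_residual_model,
    haversine_miles,
    match_to_grid,
    monitor_subset,
    moving_average_12,
    person_month_exposure,
    restrict_low_pm,
    validate_residual_vs_tracers,
    warm_season_ozone,
)
from pmcox.months import month_index


class TestGridMatching:
    def test_coincident_point_wins(self):
        centroids = pd.DataFrame({"zip": [1], "lat": [40.0], "lon": [-75.0]})
        grid = pd.DataFrame(
            {"point": [7, 9], "lat": [40.0, 41.0], "lon": [-75.0, -75.0]}
        )
        assert match_to_grid(centroids, grid)[1] == 7

    def test_tie_breaks_to_smaller_point_id(self):
        centroids = pd.DataFrame({"zip": [1], "lat": [40.0], "lon": [-75.0]})
        grid = pd.DataFrame(
            {"point": [9, 3], "lat": [41.0, 39.0], "lon": [-75.0, -75.0]}
        )
        # equidistant north/south neighbours -> the smaller id
        assert match_to_grid(centroids, grid)[1] == 3

    def test_matches_brute_force_nearest(self):
        rng = np.random.default_rng(3)
        centroids = pd.DataFrame(
            {"zip": np.arange(100), "lat": rng.uniform(25, 48, 100),
             "lon": rng.uniform(-124, -67, 100)}
        )
        grid = pd.DataFrame(
            {"point": np.arange(1000), "lat": rng.uniform(25, 48, 1000),
             "lon": rng.uniform(-124, -67, 1000)}
        )
        got = match_to_grid(centroids, grid)
        for _, row in centroids.iterrows():
            d = haversine_miles(row["lat"], row["lon"], grid["lat"], grid["lon"])
            assert got[row["zip"]] == grid["point"][int(np.argmin(d))]

    def test_empty_grid_rejected(self):
        with pytest.raises(ExposureError):
            match_to_grid(
                pd.DataFrame({"zip": [1], "lat": [0.0], "lon": [0.0]}),
                pd.DataFrame(columns=["point", "lat", "lon"]),
            )


class TestMovingAverage:
    def test_constant_series(self):
        out = moving_average_12(np.full(24, 10.0))
        assert np.allclose(out[11:], 10.0) and np.isnan(out[:11]).all()

    def test_arithmetic_mean_of_1_to_12(self):
        out = moving_average_12(np.arange(1.0, 25.0))
        assert out[11] == pytest.approx(6.5)

    def test_missing_month_yields_missing_signal(self):
        v = np.full(24, 5.0)
        v[15] = np.nan
        out = moving_average_12(v)
        assert np.isnan(out[15])
        assert np.isnan(out[20])  # window 9..20 contains the gap
        assert out[11] == pytest.approx(5.0)

    def test_linearity(self):
        rng = np.random.default_rng(8)
        x, y = rng.normal(size=40), rng.normal(size=40)
        lhs = moving_average_12(2.5 * x + 0.5 * y)
        rhs = 2.5 * moving_average_12(x) + 0.5 * moving_average_12(y)
        assert np.allclose(lhs[11:], rhs[11:])

    def test_window_crossing_a_move_mixes_both_zips(self):
        """Move at window month 7: window spans 6 months at 8.0 + 6 at 12.0."""
        start = month_index("2000-01")
        zips = np.array([1, 2])
        values = np.vstack([np.full(30, 8.0), np.full(30, 12.0)])
        surface = ZipMonthSurface("PM25", zips, start, values)
        cohort = pd.DataFrame(
            {"id": [1], "birth_month": [start - 70 * 12], "sex": ["F"],
             "race": ["White"], "follow_up_start": [start],
             "follow_up_end": [start + 29], "death_month": [np.nan],
             "icd10_cause": [None]}
        )
        residence = pd.DataFrame(
            {"id": [1, 1], "start_month": [start, start + 17], "zip": [1, 2]}
        )
        mat, s0 = person_month_exposure(cohort, residence, surface)
        assert s0 == start
        # at month index 22 the trailing window covers months 11..22:
        # 6 months in zip 1 (11..16) and 6 in zip 2 (17..22)
        assert mat[0, 22] == pytest.approx(10.0)
        assert mat[0, 16] == pytest.approx(8.0)
        assert mat[0, 28] == pytest.approx(12.0)


class TestWarmSeasonOzone:
    def _daily(self, year, values):
        idx = pd.date_range(f"{year}-01-01", f"{year}-12-31", freq="D")
        s = pd.Series(np.nan, index=idx)
        warm = (idx.month >= 4) & (idx.month <= 9)
        s[warm] = values
        return s

    def test_constant_60ppb(self):
        assert warm_season_ozone(self._daily(2003, 60.0), 2003) == pytest.approx(60.0)

    def test_alternating_days_average(self):
        s = self._daily(2003, 0.0)
        warm = s.notna()
        n = int(warm.sum())
        s[warm] = np.where(np.arange(n) % 2 == 0, 40.0, 60.0)
        assert warm_season_ozone(s, 2003) == pytest.approx(50.0, abs=0.1)

    def test_all_missing_gives_signal(self):
        idx = pd.date_range("2003-01-01", periods=10, freq="D")
        assert np.isnan(warm_season_ozone(pd.Series(np.nan, index=idx), 2003))

    def test_quarter_missing_tolerated_more_not(self):
        s = self._daily(2004, 55.0)
        warm_idx = s.dropna().index
        s[warm_idx[: int(0.2 * len(warm_idx))]] = np.nan
        assert warm_season_ozone(s, 2004) == pytest.approx(55.0)
        s[warm_idx[: int(0.3 * len(warm_idx))]] = np.nan
        assert np.isnan(warm_season_ozone(s, 2004))


class TestRestriction:
    def test_strictly_below_threshold(self):
        means = pd.Series({1: 9.0, 2: 11.0, 3: 10.0})
        kept = restrict_low_pm(means, 10)
        assert set(kept) == {1}  # 10.0 is not strictly below 10

    def test_nested_across_thresholds(self):
        rng = np.random.default_rng(1)
        means = pd.Series(rng.uniform(5, 15, 200))
        sets = [set(restrict_low_pm(means, t)) for t in (8, 10, 12)]
        assert sets[0] <= sets[1] <= sets[2]


class TestMonitorSubset:
    def test_monitor_at_centroid_retained(self):
        z = pd.DataFrame({"zip": [1], "lat": [40.0], "lon": [-75.0]})
        m = pd.DataFrame({"lat": [40.0], "lon": [-75.0]})
        assert list(monitor_subset(z, m)) == [1]

    def test_ten_miles_excluded_at_six_mile_radius(self):
        z = pd.DataFrame({"zip": [1], "lat": [40.0], "lon": [-75.0]})
        m = pd.DataFrame({"lat": [40.0 + 10 / 69.0], "lon": [-75.0]})  # ~10 mi north
        assert list(monitor_subset(z, m, 6.0)) == []

    def test_equals_brute_force_all_pairs(self):
        rng = np.random.default_rng(9)
        z = pd.DataFrame({"zip": np.arange(200), "lat": rng.uniform(39, 41, 200),
                          "lon": rng.uniform(-76, -74, 200)})
        m = pd.DataFrame({"lat": rng.uniform(39, 41, 20), "lon": rng.uniform(-76, -74, 20)})
        got = set(monitor_subset(z, m, 6.0))
        brute = {
            int(row["zip"])
            for _, row in z.iterrows()
            if (haversine_miles(row["lat"], row["lon"], m["lat"], m["lon"]) <= 6.0).any()
        }
        assert got == brute


class TestResidualModel:
    def test_perfect_fit_zero_residuals(self):
        x = np.linspace(5, 25, 50)
        model = fit_residual_model(2 * x, x)
        assert model.slope == pytest.approx(2.0)
        assert np.allclose(model.residuals, 0.0, atol=1e-10)

    def test_orthogonality_to_machine_precision(self):
        rng = np.random.default_rng(2)
        x = rng.normal(20, 5, 5000)
        y = 0.3 * x + rng.normal(0, 2, 5000)
        model = fit_residual_model(y, x)
        assert abs(np.cov(model.residuals, x)[0, 1]) < 1e-10 * np.std(x) * np.std(y)

    def test_independent_no2_gives_null_slope(self):
        rng = np.random.default_rng(4)
        n = 10_000
        pm = rng.normal(10, 3, n)
        no2 = rng.normal(15, 5, n)
        model = fit_residual_model(pm, no2)
        assert abs(model.slope) < 3 * (3 / 5) / np.sqrt(n)
        assert np.allclose(model.residuals, pm - np.mean(pm) - model.slope * (no2 - np.mean(no2)), atol=1e-8)

    def test_no2_shift_changes_intercept_not_residuals(self):
        rng = np.random.default_rng(6)
        no2 = rng.normal(15, 5, 500)
        pm = 0.4 * no2 + rng.normal(0, 1, 500)
        a = fit_residual_model(pm, no2)
        b = fit_residual_model(pm, no2 + 7.0)
        assert b.intercept == pytest.approx(a.intercept - 7.0 * a.slope, rel=1e-9)
        assert np.allclose(a.residuals, b.residuals, atol=1e-9)

    def test_constant_no2_rejected(self):
        with pytest.raises(ExposureError, match="singular"):
            fit_residual_model(np.arange(5.0), np.full(5, 3.0))


class TestTracerValidation:
    def _annual(self, n=60, seed=0):
        rng = np.random.default_rng(seed)
        return pd.DataFrame(
            {"zip": np.arange(n), "year": 2000, "pm25": rng.normal(10, 3, n),
             "residual": rng.normal(0, 1, n)}
        )

    def test_tracer_identical_to_residual_r1(self):
        annual = self._annual()
        tracers = pd.DataFrame(
            {"zip": annual["zip"], "year": 2000, "species": "ec",
             "value": annual["residual"]}
        )
        rep = validate_residual_vs_tracers(annual, tracers)
        r = rep.loc[(rep["species"] == "ec") & (rep["exposure"] == "residual"), "r"]
        assert r.iloc[0] == pytest.approx(1.0)

    def test_independent_tracer_near_zero(self):
        annual = self._annual(n=400, seed=1)
        rng = np.random.default_rng(2)
        tracers = pd.DataFrame(
            {"zip": annual["zip"], "year": 2000, "species": "ec",
             "value": rng.normal(size=400)}
        )
        rep = validate_residual_vs_tracers(annual, tracers)
        assert (rep["r"].abs() < 3 / np.sqrt(400)).all()

    def test_too_few_pairs_rejected(self):
        annual = self._annual(n=2)
        tracers = pd.DataFrame(
            {"zip": [0, 1], "year": 2000, "species": "ec", "value": [1.0, 2.0]}
        )
        with pytest.raises(ExposureError):
            validate_residual_vs_tracers(annual, tracers)
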