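"""Spline resampling, trend estimation, correlations, ARIMA fitting and
forecasting."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from wlgs import sociometry, timeseries
from wlgs.errors import (
    ConstantSeriesError,
    ExtrapolationError,
    InsufficientDataError,
    InsufficientOverlapError,
)


def irregular(days, values, name="s"):
    return pd.Series(values, index=days, name=name)


class TestSplineResample:
    def test_knots_reproduced_exactly(self, rng):
        days = np.sort(rng.choice(np.arange(1, 100), 12, replace=False))
        vals = rng.normal(50, 10, 12)
        out = timeseries.spline_resample(irregular(days, vals))
        assert np.allclose(out.loc[days].to_numpy(), vals, atol=1e-9)

    def test_linear_data_resampled_linearly(self):
        days = [1, 10, 20, 37, 55]
        out = timeseries.spline_resample(irregular(days, [2 * d + 3 for d in days]))
        assert np.allclose(out.to_numpy(), 2 * out.index.to_numpy() + 3, atol=1e-9)

    def test_idempotent_on_daily_series(self, rng):
        s = irregular(np.arange(1, 30), rng.normal(0, 1, 29))
        out = timeseries.spline_resample(s)
        assert np.allclose(out.to_numpy(), s.to_numpy(), atol=1e-9)

    def test_outside_range_raises(self):
        s = irregular([1, 5, 9, 13], [1.0, 2.0, 3.0, 4.0])
        with pytest.raises(ExtrapolationError):
            timeseries.spline_resample(s, grid=np.arange(0, 20))

    def test_too_few_points_raises(self):
        with pytest.raises(InsufficientDataError):
            timeseries.spline_resample(irregular([1, 2, 3], [1.0, 2.0, 3.0]))


class TestLinearTrend:
    def test_perfect_positive_trend(self):
        tr = timeseries.linear_trend(irregular(np.arange(10), np.arange(10, dtype=float)))
        assert tr.beta == pytest.approx(1.0)
        assert tr.r_squared == pytest.approx(1.0)

    def test_perfect_negative_trend_has_beta_minus_one(self):
        days = np.arange(20)
        tr = timeseries.linear_trend(irregular(days, -2.0 * days + 7.0))
        assert tr.beta == pytest.approx(-1.0)
        assert tr.slope == pytest.approx(-2.0)

    def test_beta_squared_equals_r_squared(self, rng):
        days = np.arange(50)
        tr = timeseries.linear_trend(irregular(days, -0.3 * days + rng.normal(0, 5, 50)))
        assert tr.beta**2 == pytest.approx(tr.r_squared, rel=1e-12)

    def test_beta_invariant_to_affine_rescaling(self, rng):
        days = np.arange(40)
        vals = 0.8 * days + rng.normal(0, 3, 40)
        a = timeseries.linear_trend(irregular(days, vals))
        b = timeseries.linear_trend(irregular(days * 3 + 11, vals * 0.01 - 5))
        assert a.beta == pytest.approx(b.beta, rel=1e-9)

    def test_constant_series_raises(self):
        with pytest.raises(ConstantSeriesError):
            timeseries.linear_trend(irregular([1, 2, 3, 4], [5.0, 5.0, 5.0, 5.0]))


class TestCorrelateSeries:
    def test_identical_series_correlate_perfectly(self, rng):
        s = irregular(np.arange(30), rng.normal(0, 1, 30))
        r, _ = timeseries.correlate_series(s, s)
        assert r == pytest.approx(1.0)

    def test_negated_series_correlate_at_minus_one(self, rng):
        s = irregular(np.arange(30), rng.normal(0, 1, 30))
        r, _ = timeseries.correlate_series(s, -s)
        assert r == pytest.approx(-1.0)

    def test_alignment_uses_day_intersection(self, rng):
        a = irregular(np.arange(0, 40), rng.normal(0, 1, 40))
        b = irregular(np.arange(20, 60), rng.normal(0, 1, 40))
        r, p = timeseries.correlate_series(a, b)
        r2, p2 = stats.pearsonr(a.loc[20:39], b.loc[20:39])
        assert r == pytest.approx(r2)

    def test_insufficient_overlap_raises(self):
        a = irregular([1, 2, 3], [1.0, 2.0, 3.0])
        b = irregular([3, 4, 5], [1.0, 2.0, 3.0])
        with pytest.raises(InsufficientOverlapError):
            timeseries.correlate_series(a, b)

    def test_type_one_error_rate_calibrated(self):
        # independent white noise: rejections at alpha=.05 near nominal
        rg = np.random.default_rng(123)
        hits = 0
        n_rep = 1000
        for _ in range(n_rep):
            a = irregular(np.arange(60), rg.normal(0, 1, 60))
            b = irregular(np.arange(60), rg.normal(0, 1, 60))
            _, p = timeseries.correlate_series(a, b)
            hits += p < 0.05
        assert 0.035 <= hits / n_rep <= 0.065


class TestChoicesCorrelation:
    def make_table(self, rng):
        pairs = list(itertools.combinations("ABCDEF", 2))
        t_ab = {p: float(v) for p, v in zip(pairs, rng.permutation(15) + 1)}
        from conftest import daily_matrix
        return sociometry.time_to_choices(daily_matrix(t_ab, T=1000))

    def test_identical_tables_correlate_perfectly(self, rng):
        t = self.make_table(rng)
        r, _ = timeseries.choices_correlation(t, t)
        assert r == pytest.approx(1.0)

    def test_matches_flattened_spearman(self, rng):
        a, b = self.make_table(rng), self.make_table(rng)
        r, p = timeseries.choices_correlation(a, b)
        r2, p2 = stats.spearmanr(a.ordered_cells().to_numpy(), b.ordered_cells().to_numpy())
        assert (r, p) == pytest.approx((r2, p2))

    def test_permutation_null_centers_at_zero(self, rng):
        a = self.make_table(rng)
        base = a.ordered_cells().to_numpy()
        rs = []
        for _ in range(2000):
            rs.append(stats.spearmanr(base, rng.permutation(base))[0])
        # mean under the permutation null ~ 0 within Monte-Carlo error
        assert abs(np.mean(rs)) < 3 * np.std(rs) / np.sqrt(len(rs))

    def test_hand_built_swap_matches_rank_formula(self):
        # two tables differing by two concordant swaps; Spearman via the
        # rank formula evaluated independently
        x = np.array([2, 1, 0, 0, 0, 2, 1, 0, 0, 0])
        y = np.array([1, 2, 0, 0, 0, 1, 2, 0, 0, 0])
        rx = stats.rankdata(x)
        ry = stats.rankdata(y)
        expect = np.corrcoef(rx, ry)[0, 1]
        assert stats.spearmanr(x, y)[0] == pytest.approx(expect)


class TestArima:
    def test_white_noise_selects_degenerate_model(self):
        rg = np.random.default_rng(42)
        s = irregular(np.arange(1, 201), rg.normal(10, 1, 200))
        fr = timeseries.fit_arima(s, d=0, max_pq=2)
        assert fr.order == (0, 0, 0)
        fc = timeseries.forecast(fr, 3)
        assert np.allclose(fc["forecast"], s.mean(), atol=0.5)

    def test_ar_coefficient_recovered_on_integrated_series(self):
        rg = np.random.default_rng(7)
        n = 400
        x = np.zeros(n)
        e = rg.normal(0, 1, n)
        for t in range(1, n):
            x[t] = 0.6 * x[t - 1] + e[t]
        s = irregular(np.arange(1, n + 1), np.cumsum(x))
        fr = timeseries.fit_arima(s, order=(1, 1, 0))
        assert fr.params["ar.L1"] == pytest.approx(0.6, abs=0.15)

    def test_refit_is_deterministic(self, rng):
        s = irregular(np.arange(1, 101), np.cumsum(rng.normal(0, 1, 100)))
        a = timeseries.fit_arima(s, d=1, max_pq=1)
        b = timeseries.fit_arima(s, d=1, max_pq=1)
        assert a.order == b.order
        assert np.allclose(a.params.to_numpy(), b.params.to_numpy())

    def test_too_short_series_raises(self):
        with pytest.raises(InsufficientDataError):
            timeseries.fit_arima(irregular(np.arange(10), np.arange(10, dtype=float)))


class TestForecast:
    def test_random_walk_forecast_is_flat_at_last_value(self, rng):
        s = irregular(np.arange(1, 101), np.cumsum(rng.normal(0, 1, 100)))
        fr = timeseries.fit_arima(s, order=(0, 1, 0))
        fc = timeseries.forecast(fr, 5)
        assert np.allclose(fc["forecast"], s.iloc[-1], atol=1e-6)
        assert list(fc.index) == [101, 102, 103, 104, 105]

    def test_interval_coverage_near_nominal(self):
        # random-walk generator, 95% intervals at h=3
        rg = np.random.default_rng(11)
        cover = 0
        n_rep = 200
        for _ in range(n_rep):
            w = np.cumsum(rg.normal(0, 1, 105))
            fr = timeseries.fit_arima(irregular(np.arange(100), w[:100]), order=(0, 1, 0))
            fc = timeseries.forecast(fr, 3)
            cover += fc["lo"].iloc[2] <= w[102] <= fc["hi"].iloc[2]
        assert 0.90 <= cover / n_rep <= 0.99

    def test_long_horizon_smoke(self, rng):
        # day-470 cut with a 45-day horizon on a ~455-day daily series
        s = irregular(np.arange(15, 471), 20000 + np.cumsum(rng.normal(0, 300, 456)))
        fr = timeseries.fit_arima(s, order=(1, 1, 0))
        fc = timeseries.forecast(fr, 45)
        assert len(fc) == 45 and np.isfinite(fc.to_numpy()).all()

    def test_bad_horizon_raises(self, rng):
        s = irregular(np.arange(1, 101), np.cumsum(rng.normal(0, 1, 100)))
        fr = timeseries.fit_arima(s, order=(0, 1, 0))
        with pytest.raises(ValueError):
            timeseries.forecast(fr, 0)


def test_series_csv_round_trip(tmp_path, rng):
    s = pd.Series(rng.normal(0, 1, 20), index=np.arange(1, 21), name="crti_ppm")
    path = tmp_path / "s.csv"
    timeseries.write_series(s, path)
    back = timeseries.read_series(path)
    assert np.allclose(back.to_numpy(), s.to_numpy())
    assert list(back.index) == list(s.index)
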