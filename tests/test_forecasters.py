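"""Forecaster behaviour: naive definitions, kNN vs brute force, adapters."""

import itertools

import numpy as np
import pandas as pd
import pytest

import wardflow as wf
from wardflow import forecasters as fc
from wardflow.features import TARGET_COLUMN


def series(values, start="2021-03-01"):
    idx = pd.date_range(start, periods=len(values))
    return pd.DataFrame({"discharges": values,
                         "admissions": 0,
                         "occupancy": 30}, index=idx)


def day_after(daily):
    return daily.index[-1] + pd.Timedelta(days=1)


def knn_brute_force(values, p, k, loss, weights=None):
    """Exhaustive enumeration oracle: scan every window, sort by (distance,
    start), combine the k matched next values."""
    values = np.asarray(values, dtype=float)
    query = values[-p:]
    cands = []
    for s in range(len(values) - p):
        w = values[s:s + p]
        cands.append((float(np.sqrt(((w - query) ** 2).sum())), s,
                      values[s + p]))
    cands.sort(key=lambda t: (t[0], t[1]))
    nxt = np.array([c[2] for c in cands[:k]])
    if loss == "robust_median":
        return float(np.median(nxt))
    w = np.full(k, 1 / k) if weights is None else np.asarray(weights)
    return float(w @ nxt)


class TestNaives:
    def test_last_weekday_is_direct_lookup(self):
        daily = series(np.arange(30))
        d = day_after(daily)
        assert wf.forecasters.naive_last_weekday(daily, d) == daily.loc[
            d - pd.Timedelta(days=7), "discharges"]

    def test_trailing_means_hand_example(self):
        daily = series([1] * 14 + [8, 9, 7, 8, 10, 6, 8])
        d = day_after(daily)
        assert fc.naive_mean_week(daily, d) == pytest.approx(8.0)
        assert fc.naive_mean_3weeks(daily, d) == pytest.approx(
            (14 + 56) / 21)

    @pytest.mark.parametrize("fn", [fc.naive_last_weekday, fc.naive_mean_week,
                                    fc.naive_mean_3weeks])
    def test_constant_series(self, fn):
        daily = series([5.0] * 30)
        assert fn(daily, day_after(daily)) == pytest.approx(5.0)

    def test_mean_3weeks_of_periodic_series_is_period_mean(self):
        week = [4, 5, 6, 7, 12, 2, 1]
        daily = series(week * 5)
        assert fc.naive_mean_3weeks(daily, day_after(daily)) == pytest.approx(
            np.mean(week))

    def test_insufficient_history(self):
        daily = series([3, 4, 5])
        with pytest.raises(fc.InsufficientHistoryError):
            fc.naive_mean_week(daily, day_after(daily))
        with pytest.raises(fc.InsufficientHistoryError):
            fc.naive_last_weekday(daily, day_after(daily))

    def test_full_history_matches_lookup_everywhere(self):
        rng = np.random.default_rng(0)
        daily = series(rng.poisson(8, size=200).astype(float))
        y = daily["discharges"]
        for d in daily.index[10::13]:
            assert fc.naive_last_weekday(daily.loc[:d - pd.Timedelta(days=1)],
                                         d) == y.loc[d - pd.Timedelta(days=7)]


class TestKnn:
    def test_worked_example(self):
        """history [5,3,8,5,3,8,5,3], p=2, k=2: both zero-distance matches
        of the query [5,3] are followed by 8."""
        daily = series([5, 3, 8, 5, 3, 8, 5, 3])
        cfg = wf.KnnConfig(p=2, k=2)
        assert wf.knn_forecast(daily, cfg, day_after(daily)) == pytest.approx(8.0)

    @pytest.mark.parametrize("loss", ["robust_median", "weighted_quadratic"])
    def test_constant_history(self, loss):
        daily = series([4.0] * 20)
        cfg = wf.KnnConfig(p=3, k=5, loss=loss)
        assert wf.knn_forecast(daily, cfg, day_after(daily)) == pytest.approx(4.0)

    def test_uniform_weighted_quadratic_is_plain_mean(self):
        rng = np.random.default_rng(2)
        vals = rng.poisson(8, size=40).astype(float)
        daily = series(vals)
        d = day_after(daily)
        got = wf.knn_forecast(daily, wf.KnnConfig(3, 4, "weighted_quadratic"),
                              d)
        assert got == pytest.approx(
            knn_brute_force(vals, 3, 4, "weighted_quadratic"))

    def test_exhaustive_oracle_equivalence(self):
        """Implementation matches the brute-force oracle exactly for all
        series lengths <= 30, p <= 5, k <= 5, both losses."""
        rng = np.random.default_rng(42)
        for n in (10, 17, 23, 30):
            for rep in range(3):
                vals = rng.integers(0, 15, size=n).astype(float)
                daily = series(vals)
                d = day_after(daily)
                for p, k in itertools.product(range(1, 6), range(1, 6)):
                    if n - p < k:
                        continue
                    for loss in ("robust_median", "weighted_quadratic"):
                        got = wf.knn_forecast(daily, wf.KnnConfig(p, k, loss),
                                              d)
                        want = knn_brute_force(vals, p, k, loss)
                        assert got == want, (n, rep, p, k, loss)

    def test_median_output_within_training_range(self):
        rng = np.random.default_rng(9)
        vals = rng.poisson(8, size=60).astype(float)
        daily = series(vals)
        f = wf.knn_forecast(daily, wf.KnnConfig(7, 5), day_after(daily))
        assert vals.min() <= f <= vals.max()

    def test_too_few_candidates(self):
        daily = series([1, 2, 3, 4, 5])
        with pytest.raises(fc.InsufficientHistoryError):
            wf.knn_forecast(daily, wf.KnnConfig(p=3, k=5), day_after(daily))


class TestTuneKnn:
    def test_periodic_series_achieves_zero_validation_rmse(self):
        week = [4.0, 5, 6, 7, 12, 2, 1]
        daily = series(week * 12)
        cfg = wf.tune_knn(daily, p_grid=(2, 7), k_grid=(1, 2))
        model = fc.KnnPatternForecaster(p=cfg.p, k=cfg.k, loss=cfg.loss)
        y = daily["discharges"]
        errs = [y.loc[d] - model.forecast(daily.loc[:d - pd.Timedelta(days=1)],
                                          d)
                for d in daily.index[-14:]]
        assert np.sqrt(np.mean(np.square(errs))) == pytest.approx(0.0)

    def test_shift_invariance_of_winning_config(self):
        rng = np.random.default_rng(4)
        vals = rng.poisson(8, size=120).astype(float)
        a = wf.tune_knn(series(vals), (2, 3, 7), (2, 5))
        b = wf.tune_knn(series(vals + 100.0), (2, 3, 7), (2, 5))
        assert (a.p, a.k) == (b.p, b.k)

    def test_tuned_rmse_is_grid_minimum(self):
        rng = np.random.default_rng(6)
        vals = rng.poisson(8, size=150).astype(float)
        daily = series(vals)
        p_grid, k_grid = (2, 7), (2, 5, 10)
        cfg = wf.tune_knn(daily, p_grid, k_grid)

        def val_rmse(p, k):
            n = len(vals)
            n_val = max(1, int(round(0.2 * n)))
            errs = [vals[t] - fc._knn_point_forecast(vals[:t], p, k,
                                                     "robust_median")
                    for t in range(n - n_val, n)]
            return np.sqrt(np.mean(np.square(errs)))

        best = val_rmse(cfg.p, cfg.k)
        for p in p_grid:
            for k in k_grid:
                assert best <= val_rmse(p, k) + 1e-12


class TestArima:
    def test_constant_series_forecasts_constant(self):
        daily = series([7.0] * 120)
        f = fc.arima_forecast(daily, day_after(daily))
        assert f == pytest.approx(7.0)

    def test_white_noise_recovers_mean(self):
        """Monte-Carlo known-process recovery: averaged over replicate
        white-noise series, the one-step forecast is unbiased for mu within
        the single-window 3 SE band (averaging absorbs the extra variance
        that AICc model selection adds to any one forecast)."""
        rng = np.random.default_rng(1)
        mu, sigma, n = 10.0, 1.0, 180
        forecasts = []
        for _ in range(10):
            daily = series(mu + sigma * rng.standard_normal(n))
            forecasts.append(fc.arima_forecast(daily, day_after(daily)))
        assert abs(np.mean(forecasts) - mu) < 3 * sigma / np.sqrt(90)

    def test_insufficient_history(self):
        daily = series([7.0] * 30)
        with pytest.raises(fc.InsufficientHistoryError):
            fc.arima_forecast(daily, day_after(daily))

    def test_armax_beats_arima_on_deterministic_weekly_pattern(self):
        """With a purely weekly signal, day-of-week regressors should
        essentially eliminate the error while plain ARIMA keeps some."""
        week = np.array([9.0, 10, 11, 12, 16, 4, 3])
        n = 150
        vals = np.tile(week, n // 7 + 1)[:n]
        daily = series(vals)
        arima = fc.ArimaForecaster().fit(daily.iloc[:0])
        armax = fc.ArmaxForecaster().fit(daily.iloc[:0])
        errs = {"arima": [], "armax": []}
        for d in daily.index[-10:]:
            hist = daily.loc[:d - pd.Timedelta(days=1)]
            actual = daily.loc[d, "discharges"]
            errs["arima"].append(abs(actual - arima.forecast(hist, d)))
            errs["armax"].append(abs(actual - armax.forecast(hist, d)))
        assert np.mean(errs["armax"]) < np.mean(errs["arima"])


@pytest.fixture(scope="module")
def feature_split(sim_small_module):
    daily, X = sim_small_module
    split = X.index[len(X) - 40]
    train = X.loc[:split]
    test = X.loc[X.index > split]
    return daily, train, test


@pytest.fixture(scope="module")
def sim_small_module():
    cfg = wf.default_config(n_days=300)
    tables = wf.simulate_ward(cfg)
    visits = wf.ingest.join_tables(*tables)
    days = pd.date_range(cfg.start_date, periods=cfg.n_days)
    daily = wf.derive_daily_series(visits, days)
    X = wf.build_feature_matrix(daily, visits)
    return daily, X


class TestFeatureModels:
    def test_rf_learns_exact_lag_copy_target(self, feature_split):
        """With the target replaced by an exact copy of the lag-7 discharge
        column, the forest should reproduce it almost perfectly."""
        _, train, test = feature_split
        train = train.copy()
        test = test.copy()
        train[TARGET_COLUMN] = train["dis_lag_7"]
        test[TARGET_COLUMN] = test["dis_lag_7"]
        preds = fc.rf_forecast(train, test, n_estimators=200)
        mae = np.mean(np.abs(test[TARGET_COLUMN].to_numpy() - preds.to_numpy()))
        assert mae < 0.5

    def test_forest_averaging_reduces_error(self, feature_split):
        """A 300-tree forest never does worse than a single tree on held-out
        rows (variance reduction), averaged over 3 seeds."""
        _, train, test = feature_split
        y = test[TARGET_COLUMN].to_numpy()
        r1, r300 = [], []
        for seed in range(3):
            small = fc.rf_forecast(train, test, n_estimators=1,
                                   max_features_grid=(0.5,), random_state=seed)
            big = fc.rf_forecast(train, test, n_estimators=300,
                                 max_features_grid=(0.5,), random_state=seed)
            r1.append(np.sqrt(np.mean((y - small.to_numpy()) ** 2)))
            r300.append(np.sqrt(np.mean((y - big.to_numpy()) ** 2)))
        assert np.mean(r300) <= np.mean(r1)

    def test_svr_with_huge_tube_is_constant(self, feature_split):
        _, train, test = feature_split
        span = train[TARGET_COLUMN].max() - train[TARGET_COLUMN].min()
        preds = fc.svr_forecast(train, test, epsilon_grid=(5 * span,),
                                C_grid=(1.0,), gamma_factors=(1.0,))
        assert preds.std() == pytest.approx(0.0, abs=1e-6)

    def test_feature_importance_structure(self, feature_split):
        daily, train, test = feature_split
        rf = fc.RandomForestForecaster(n_estimators=100,
                                       max_features_grid=(0.5,))
        rf.fit(daily, features=train)
        imp = fc.feature_importance(rf)
        assert len(imp) == 108
        assert list(imp["rank"]) == list(range(1, 109))
        assert imp["importance"].is_monotonic_decreasing

    def test_unfitted_importance_rejected(self):
        with pytest.raises(ValueError):
            fc.feature_importance(fc.RandomForestForecaster())


class TestRegistry:
    def test_all_names_construct(self):
        for name in fc.MODEL_REGISTRY:
            assert fc.make_forecaster(name).name == name

    def test_unknown_name_lists_registry(self):
        with pytest.raises(KeyError, match="naive_lw"):
            fc.make_forecaster("nope")
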