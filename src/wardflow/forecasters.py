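"""One-step-ahead discharge forecasters behind a uniform interface.

Every forecaster is a scikit-learn style estimator:

* ``fit(daily, features=None)`` — consume the training block (a date-indexed
  daily series and, for the feature-based models, the predictor matrix) and
  tune whatever hyperparameters the model owns;
* ``forecast(history, target_date, features_row=None)`` — return the real-
  valued next-day discharge forecast using only ``history``, the daily series
  strictly before ``target_date``.

The three naive baselines and the k-nearest-neighbour pattern forecaster are
implemented from scratch (they are the bespoke surface of this package);
ARIMA/ARMAX delegate to statsmodels SARIMAX with a rolling 90-day refit, and
the random-forest / support-vector regressors delegate to scikit-learn with
the tuning protocols described in each class.

Forecasts are real-valued, not rounded: integer rounding is left to callers.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view
from sklearn.base import BaseEstimator
from sklearn.ensemble import RandomForestRegressor
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVR

from .features import TARGET_COLUMN, predictor_columns

logger = logging.getLogger(__name__)

__all__ = [
    "InsufficientHistoryError",
    "KnnConfig",
    "BaseForecaster",
    "LastWeekdayNaive",
    "MeanWeekNaive",
    "Mean3WeeksNaive",
    "KnnPatternForecaster",
    "ArimaForecaster",
    "ArmaxForecaster",
    "RandomForestForecaster",
    "SvrForecaster",
    "MODEL_REGISTRY",
    "make_forecaster",
    "naive_last_weekday",
    "naive_mean_week",
    "naive_mean_3weeks",
    "knn_forecast",
    "tune_knn",
    "arima_forecast",
    "armax_forecast",
    "rf_forecast",
    "svr_forecast",
    "feature_importance",
]

DAY = pd.Timedelta(days=1)


class InsufficientHistoryError(ValueError):
    """Not enough history before the target date for this forecaster."""


def _discharges(history: pd.DataFrame | pd.Series) -> pd.Series:
    if isinstance(history, pd.DataFrame):
        return history["discharges"]
    return history


# ---------------------------------------------------------------------------
# naive baselines
# ---------------------------------------------------------------------------

class BaseForecaster(BaseEstimator):
    """Common scikit-learn style surface; subclasses implement forecast()."""

    name = "base"

    def fit(self, daily: pd.DataFrame, features: pd.DataFrame | None = None):
        self.train_end_ = daily.index.max() if len(daily) else None
        return self

    def forecast(self, history, target_date, features_row=None) -> float:
        raise NotImplementedError

    def forecast_series(self, daily: pd.DataFrame, dates,
                        features: pd.DataFrame | None = None) -> pd.Series:
        """Convenience: one-step-ahead forecasts for each date, each using
        only the daily rows strictly before that date."""
        out = {}
        for d in dates:
            d = pd.Timestamp(d)
            history = daily.loc[: d - DAY]
            row = features.loc[d] if features is not None else None
            out[d] = self.forecast(history, d, features_row=row)
        return pd.Series(out, name=self.name)


class LastWeekdayNaive(BaseForecaster):
    """Forecast = the discharge count on the same weekday one week earlier."""

    name = "naive_lw"

    def forecast(self, history, target_date, features_row=None) -> float:
        y = _discharges(history)
        ref = pd.Timestamp(target_date).normalize() - 7 * DAY
        if len(y) < 7 or ref not in y.index:
            raise InsufficientHistoryError(
                f"no observation 7 days before {target_date}")
        return float(y.loc[ref])


class _TrailingMeanNaive(BaseForecaster):
    window: int = 7

    def forecast(self, history, target_date, features_row=None) -> float:
        y = _discharges(history)
        d = pd.Timestamp(target_date).normalize()
        win = y.loc[d - self.window * DAY: d - DAY]
        if len(win) < self.window:
            raise InsufficientHistoryError(
                f"need {self.window} trailing days before {target_date}, "
                f"have {len(win)}")
        return float(win.mean())


class MeanWeekNaive(_TrailingMeanNaive):
    """Forecast = mean of the trailing 7 daily discharge counts."""

    name = "naive_mw"
    window = 7


class Mean3WeeksNaive(_TrailingMeanNaive):
    """Forecast = mean of the trailing 21 daily discharge counts."""

    name = "naive_m3w"
    window = 21


# ---------------------------------------------------------------------------
# k-nearest-neighbour pattern forecaster
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class KnnConfig:
    """Pattern length p, neighbour count k, and the neighbour-combination
    loss: ``robust_median`` (median of matched next-day values — robust to
    the outlier-heavy discharge counts) or ``weighted_quadratic`` (weighted
    mean; ``weights`` orders by distance rank and must sum to 1, None means
    uniform)."""

    p: int
    k: int
    loss: str = "robust_median"
    weights: tuple[float, ...] | None = None

    def validate(self) -> None:
        if self.p < 1 or self.k < 1:
            raise ValueError("p and k must be >= 1")
        if self.loss not in ("robust_median", "weighted_quadratic"):
            raise ValueError(f"unknown loss {self.loss!r}")
        if self.weights is not None:
            w = np.asarray(self.weights, dtype=float)
            if len(w) != self.k or (w < 0).any() or abs(w.sum() - 1) > 1e-9:
                raise ValueError(
                    "weights must be k nonnegative reals summing to 1")


def _knn_point_forecast(values: np.ndarray, p: int, k: int, loss: str,
                        weights=None) -> float:
    """Core pattern-matching step on a plain value array.

    The query is the last p values; candidates are all complete windows of
    length p whose next value is also observed (the query window itself has
    no next value, so it is never a candidate).  Ties at equal distance are
    broken in favour of the earlier window start.
    """
    values = np.asarray(values, dtype=float)
    n = len(values)
    n_candidates = n - p
    if n_candidates < k:
        raise InsufficientHistoryError(
            f"need at least p + k = {p + k} days of history, have {n}")
    query = values[-p:]
    windows = sliding_window_view(values, p)[:n_candidates]
    dist = np.sqrt(((windows - query) ** 2).sum(axis=1))
    order = np.lexsort((np.arange(n_candidates), dist))
    matched_next = values[order[:k] + p]
    if loss == "robust_median":
        return float(np.median(matched_next))
    w = (np.full(k, 1.0 / k) if weights is None
         else np.asarray(weights, dtype=float))
    return float(w @ matched_next)


class KnnPatternForecaster(BaseForecaster):
    """Pattern-matching kNN regression on the discharge series.

    The last p daily discharge counts form the query; its k nearest
    historical windows (Euclidean distance) vote through their next-day
    values.  When ``p``/``k`` are None, :meth:`fit` tunes them by one-step-
    ahead RMSE on the last 20% of the training series (ties: smaller p,
    then smaller k).
    """

    name = "knn"

    def __init__(self, p=None, k=None, loss="robust_median", weights=None,
                 p_grid=(2, 3, 7, 14, 21), k_grid=(5, 10, 25, 50)):
        self.p = p
        self.k = k
        self.loss = loss
        self.weights = weights
        self.p_grid = p_grid
        self.k_grid = k_grid

    def fit(self, daily, features=None):
        super().fit(daily, features)
        if self.p is not None and self.k is not None:
            self.config_ = KnnConfig(self.p, self.k, self.loss, self.weights)
            self.config_.validate()
        else:
            self.config_ = tune_knn(daily, self.p_grid, self.k_grid,
                                    loss=self.loss, weights=self.weights)
        return self

    def forecast(self, history, target_date, features_row=None) -> float:
        cfg = getattr(self, "config_",
                      KnnConfig(self.p or 7, self.k or 5, self.loss,
                                self.weights))
        y = _discharges(history).loc[: pd.Timestamp(target_date) - DAY]
        return _knn_point_forecast(y.to_numpy(), cfg.p, cfg.k, cfg.loss,
                                   cfg.weights)


def tune_knn(train, p_grid, k_grid, *, loss="robust_median",
             weights=None) -> KnnConfig:
    """Select (p, k) minimizing one-step-ahead RMSE on the last 20% of the
    training series (at least one day).  Deterministic; ties favour the
    smaller p, then the smaller k.  Grid points that cannot produce a
    forecast for every validation day are skipped; if none survive the
    training series is too short."""
    p_grid, k_grid = sorted(set(p_grid)), sorted(set(k_grid))
    if not p_grid or not k_grid:
        raise ValueError("empty tuning grid")
    y = _discharges(train).to_numpy(dtype=float)
    n = len(y)
    n_val = max(1, int(round(0.2 * n)))
    val_idx = np.arange(n - n_val, n)
    best = None
    for p in p_grid:
        for k in k_grid:
            if val_idx[0] < p + k:  # first validation day lacks history
                continue
            errs = np.empty(n_val)
            for j, t in enumerate(val_idx):
                f = _knn_point_forecast(y[:t], p, k, loss, weights)
                errs[j] = y[t] - f
            rmse = float(np.sqrt(np.mean(errs ** 2)))
            if best is None or rmse < best[0] - 1e-12:
                best = (rmse, p, k)
    if best is None:
        raise InsufficientHistoryError(
            "training series too short for every (p, k) in the grids")
    cfg = KnnConfig(best[1], best[2], loss, weights)
    cfg.validate()
    return cfg


# ---------------------------------------------------------------------------
# ARIMA / ARMAX adapters (statsmodels SARIMAX, rolling 90-day refit)
# ---------------------------------------------------------------------------

class ArimaForecaster(BaseForecaster):
    """Rolling-refit ARIMA on the trailing discharge window.

    Each forecast refits on the trailing ``refit_window`` days (default 90,
    i.e. the past 3 months).  Orders (p, d, q) are chosen by AICc over a
    small grid; reselection happens every ``order_reselect_every`` forecasts
    (coefficients are still re-estimated daily).  A non-finite forecast is
    replaced by the trailing-week mean with a logged warning.
    """

    name = "arima"
    _use_exog = False

    def __init__(self, refit_window=90, max_p=2, max_d=1, max_q=2,
                 order_reselect_every=28):
        self.refit_window = refit_window
        self.max_p = max_p
        self.max_d = max_d
        self.max_q = max_q
        self.order_reselect_every = order_reselect_every

    def fit(self, daily, features=None):
        super().fit(daily, features)
        self.order_ = None
        self._forecasts_since_selection = 0
        return self

    # -- exogenous design ---------------------------------------------------
    def _exog(self, history: pd.DataFrame, window_index: pd.DatetimeIndex,
              target_date: pd.Timestamp):
        """Day-of-week indicator contrasts (Tue..Sun, Monday reference) plus
        previous-day occupancy, for the window rows and the target day."""
        def dow_block(idx):
            dow = pd.Index(idx).dayofweek
            return np.column_stack([(dow == i).astype(float)
                                    for i in range(1, 7)])
        o_prev = history["occupancy"].shift(1)
        o_win = o_prev.loc[window_index].to_numpy(dtype=float)
        if np.isnan(o_win[0]):
            o_win[0] = history["occupancy"].loc[window_index[0]]
        X = np.column_stack([dow_block(window_index), o_win])
        o_target = float(history["occupancy"].iloc[-1])
        x_next = np.concatenate(
            [dow_block([pd.Timestamp(target_date)])[0], [o_target]])
        return X, x_next[None, :]

    def _candidate_orders(self):
        return [(p, d, q)
                for d in range(self.max_d + 1)
                for p in range(self.max_p + 1)
                for q in range(self.max_q + 1)]

    @staticmethod
    def _fit_sarimax(y, order, exog):
        from statsmodels.tsa.statespace.sarimax import SARIMAX
        trend = "c" if order[1] == 0 else "n"
        model = SARIMAX(y, exog=exog, order=order, trend=trend,
                        enforce_stationarity=False, enforce_invertibility=False)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return model.fit(disp=False, maxiter=100)

    def _select_order(self, y, exog):
        best, best_ic = None, np.inf
        for order in self._candidate_orders():
            try:
                res = self._fit_sarimax(y, order, exog)
                ic = res.info_criteria("aicc")
            except Exception:
                continue
            if np.isfinite(ic) and ic < best_ic - 1e-9:
                best, best_ic = order, ic
        return best or (1, 0, 0)

    def forecast(self, history, target_date, features_row=None) -> float:
        y = _discharges(history)
        if len(y) < self.refit_window:
            raise InsufficientHistoryError(
                f"need {self.refit_window} days of history, have {len(y)}")
        window = y.iloc[-self.refit_window:]
        if np.ptp(window.to_numpy(dtype=float)) == 0.0:
            return float(window.iloc[0])  # constant window: differencing-safe
        exog = x_next = None
        if self._use_exog:
            exog, x_next = self._exog(history, window.index, target_date)
        if (getattr(self, "order_", None) is None
                or self._forecasts_since_selection
                >= self.order_reselect_every):
            self.order_ = self._select_order(window.to_numpy(float), exog)
            self._forecasts_since_selection = 0
        self._forecasts_since_selection += 1
        try:
            res = self._fit_sarimax(window.to_numpy(float), self.order_, exog)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                f = float(np.asarray(res.forecast(steps=1, exog=x_next))[0])
        except Exception:
            f = np.nan
        if not np.isfinite(f):
            logger.warning("%s produced a non-finite forecast for %s; "
                           "falling back to trailing-week mean",
                           self.name, target_date)
            f = MeanWeekNaive().forecast(history, target_date)
        return f


class ArmaxForecaster(ArimaForecaster):
    """ARIMA with known exogenous regressors: day-of-week indicator
    contrasts of the forecast day and previous-day ward occupancy."""

    name = "armax"
    _use_exog = True


# ---------------------------------------------------------------------------
# random forest / SVR adapters over the 108-predictor matrix
# ---------------------------------------------------------------------------

def _drop_zero_variance(X: pd.DataFrame) -> tuple[pd.DataFrame, list[str]]:
    variances = X.var(axis=0, ddof=0)
    dropped = list(variances.index[variances == 0.0])
    if dropped:
        logger.info("dropping %d zero-variance feature columns: %s",
                    len(dropped), dropped)
    return X.drop(columns=dropped), dropped


class RandomForestForecaster(BaseForecaster):
    """Random-forest regression on the full predictor matrix.

    Variables-per-split (``max_features``) is chosen by scanning the
    out-of-bag RMSE over ``max_features_grid``; the forest is then refit
    once on the whole training block (no daily refit).  Zero-variance
    columns are dropped with a logged list.  The seed is a constructor
    parameter and is recorded on the fitted model.
    """

    name = "rf"

    def __init__(self, n_estimators=300, max_features_grid=(0.33, 0.5, 0.7, 1.0),
                 min_samples_leaf=5, random_state=0):
        self.n_estimators = n_estimators
        self.max_features_grid = max_features_grid
        self.min_samples_leaf = min_samples_leaf
        self.random_state = random_state

    def fit(self, daily, features: pd.DataFrame = None):
        if features is None:
            raise ValueError("RandomForestForecaster requires the feature matrix")
        super().fit(daily, features)
        X = features[predictor_columns(features)]
        y = features[TARGET_COLUMN].to_numpy(dtype=float)
        X, self.dropped_ = _drop_zero_variance(X)
        self.columns_ = list(X.columns)
        best, best_oob = None, np.inf
        for mf in self.max_features_grid:
            rf = RandomForestRegressor(
                n_estimators=self.n_estimators, max_features=mf,
                min_samples_leaf=self.min_samples_leaf, oob_score=True,
                bootstrap=True, random_state=self.random_state, n_jobs=1)
            rf.fit(X.to_numpy(dtype=float), y)
            oob_rmse = float(np.sqrt(np.mean(
                (y - rf.oob_prediction_) ** 2)))
            if oob_rmse < best_oob - 1e-12:
                best, best_oob = mf, oob_rmse
        self.max_features_ = best
        self.oob_rmse_ = best_oob
        self.model_ = RandomForestRegressor(
            n_estimators=self.n_estimators, max_features=best,
            min_samples_leaf=self.min_samples_leaf,
            random_state=self.random_state, n_jobs=1)
        self.model_.fit(X.to_numpy(dtype=float), y)
        self.X_train_ = X
        self.y_train_ = y
        return self

    def forecast(self, history, target_date, features_row=None) -> float:
        if features_row is None:
            raise ValueError("RandomForestForecaster requires features_row")
        x = np.asarray(features_row[self.columns_], dtype=float)[None, :]
        return float(self.model_.predict(x)[0])


class SvrForecaster(BaseForecaster):
    """Epsilon-insensitive support-vector regression with an RBF kernel.

    (C, epsilon, kernel bandwidth) are chosen by grid search minimizing RMSE
    on the last 20% of the training rows (time-ordered split); predictors
    are standardized using training-set statistics only.  The bandwidth grid
    is centred on gamma0 = 1 / (2 * n_features) for standardized features,
    one decade either side.
    """

    name = "svr"

    def __init__(self, C_grid=(0.1, 1.0, 10.0, 100.0),
                 epsilon_grid=(0.1, 0.5, 1.0, 2.0),
                 gamma_factors=(0.1, 1.0, 10.0)):
        self.C_grid = C_grid
        self.epsilon_grid = epsilon_grid
        self.gamma_factors = gamma_factors

    def fit(self, daily, features: pd.DataFrame = None):
        if features is None:
            raise ValueError("SvrForecaster requires the feature matrix")
        super().fit(daily, features)
        X = features[predictor_columns(features)]
        y = features[TARGET_COLUMN].to_numpy(dtype=float)
        X, self.dropped_ = _drop_zero_variance(X)
        self.columns_ = list(X.columns)
        Xv = X.to_numpy(dtype=float)
        n = len(Xv)
        n_val = max(1, int(round(0.2 * n)))
        Xtr, ytr = Xv[: n - n_val], y[: n - n_val]
        Xva, yva = Xv[n - n_val:], y[n - n_val:]
        scaler = StandardScaler().fit(Xtr)
        gamma0 = 1.0 / (2.0 * Xv.shape[1])
        best, best_rmse = None, np.inf
        for C in self.C_grid:
            for eps in self.epsilon_grid:
                for gf in self.gamma_factors:
                    svr = SVR(kernel="rbf", C=C, epsilon=eps,
                              gamma=gamma0 * gf)
                    svr.fit(scaler.transform(Xtr), ytr)
                    pred = svr.predict(scaler.transform(Xva))
                    rmse = float(np.sqrt(np.mean((yva - pred) ** 2)))
                    if rmse < best_rmse - 1e-12:
                        best, best_rmse = (C, eps, gamma0 * gf), rmse
        self.C_, self.epsilon_, self.gamma_ = best
        self.val_rmse_ = best_rmse
        self.scaler_ = StandardScaler().fit(Xv)
        self.model_ = SVR(kernel="rbf", C=self.C_, epsilon=self.epsilon_,
                          gamma=self.gamma_)
        self.model_.fit(self.scaler_.transform(Xv), y)
        return self

    def forecast(self, history, target_date, features_row=None) -> float:
        if features_row is None:
            raise ValueError("SvrForecaster requires features_row")
        x = np.asarray(features_row[self.columns_], dtype=float)[None, :]
        return float(self.model_.predict(self.scaler_.transform(x))[0])


def feature_importance(fitted_rf: RandomForestForecaster, *, n_repeats=5,
                       random_state=0) -> pd.DataFrame:
    """Permutation-importance ranking over all predictor columns.

    Permutes each column of the training block and measures the increase in
    squared error of the fitted forest.  Columns dropped at fit time (zero
    variance) are reported with importance 0 so the ranking always covers
    the full predictor set.  Returns a DataFrame (column, importance, rank)
    sorted descending.
    """
    from sklearn.inspection import permutation_importance

    if not hasattr(fitted_rf, "model_"):
        raise ValueError("forecaster is not fitted")
    res = permutation_importance(
        fitted_rf.model_, fitted_rf.X_train_.to_numpy(dtype=float),
        fitted_rf.y_train_, n_repeats=n_repeats, random_state=random_state,
        scoring="neg_mean_squared_error")
    rows = list(zip(fitted_rf.columns_, res.importances_mean))
    rows += [(c, 0.0) for c in fitted_rf.dropped_]
    out = pd.DataFrame(rows, columns=["column", "importance"])
    out = out.sort_values(["importance", "column"],
                          ascending=[False, True]).reset_index(drop=True)
    out["rank"] = np.arange(1, len(out) + 1)
    return out


# ---------------------------------------------------------------------------
# registry and thin functional wrappers
# ---------------------------------------------------------------------------

MODEL_REGISTRY: dict[str, type[BaseForecaster]] = {
    "naive_lw": LastWeekdayNaive,
    "naive_mw": MeanWeekNaive,
    "naive_m3w": Mean3WeeksNaive,
    "knn": KnnPatternForecaster,
    "arima": ArimaForecaster,
    "armax": ArmaxForecaster,
    "rf": RandomForestForecaster,
    "svr": SvrForecaster,
}


def make_forecaster(name: str, **params) -> BaseForecaster:
    try:
        cls = MODEL_REGISTRY[name]
    except KeyError:
        raise KeyError(f"unknown model {name!r}; available: "
                       f"{sorted(MODEL_REGISTRY)}") from None
    return cls(**params)


def naive_last_weekday(history, target_date) -> float:
    return LastWeekdayNaive().forecast(history, target_date)


def naive_mean_week(history, target_date) -> float:
    return MeanWeekNaive().forecast(history, target_date)


def naive_mean_3weeks(history, target_date) -> float:
    return Mean3WeeksNaive().forecast(history, target_date)


def knn_forecast(history, config: KnnConfig, target_date) -> float:
    config.validate()
    model = KnnPatternForecaster(p=config.p, k=config.k, loss=config.loss,
                                 weights=config.weights)
    return model.forecast(history, target_date)


def arima_forecast(history, target_date, **params) -> float:
    model = ArimaForecaster(**params)
    model.fit(history.iloc[:0])
    return model.forecast(history, target_date)


def armax_forecast(history, target_date, **params) -> float:
    model = ArmaxForecaster(**params)
    model.fit(history.iloc[:0])
    return model.forecast(history, target_date)


def _fit_predict_features(model, train_features, test_features) -> pd.Series:
    model.fit(daily=pd.DataFrame(index=train_features.index),
              features=train_features)
    out = {}
    for d, row in test_features.iterrows():
        out[d] = model.forecast(None, d, features_row=row)
    return pd.Series(out, name=model.name)


def rf_forecast(train_features, test_features, **params) -> pd.Series:
    """Fit once on the training rows, forecast every test row."""
    return _fit_predict_features(RandomForestForecaster(**params),
                                 train_features, test_features)


def svr_forecast(train_features, test_features, **params) -> pd.Series:
    """Fit once on the training rows, forecast every test row."""
    return _fit_predict_features(SvrForecaster(**params),
                                 train_features, test_features)
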