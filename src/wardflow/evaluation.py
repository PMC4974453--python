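"""Rolling one-step-ahead evaluation and forecast error metrics.

Metrics follow the standard forecast-accuracy definitions, with y the
observed and f the forecast discharge count:

* MFE  = mean(y - f)                  (bias; > 0 means under-forecasting)
* MAE  = mean(|y - f|)
* RMSE = sqrt(mean((y - f)^2))
* sMAPE = mean(200 * |y - f| / (y + f))  in percent, bounded by 200 for
  nonnegative series; a pair with y + f = 0 contributes 0 (both sides agree
  on zero, so the error is zero by convention).

The evaluator walks the test block day by day, hands every model only the
daily series strictly before the day being forecast, and scores the
resulting forecast runs, including a per-day-of-week MAE breakdown and the
MAE improvement of each model over a named naive baseline.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import forecasters as fc
from .features import TARGET_COLUMN, predictor_columns

__all__ = [
    "mfe",
    "mae",
    "rmse",
    "smape",
    "improvement_over",
    "weekday_mae",
    "EvaluationResult",
    "rolling_evaluate",
]

WEEKDAY_NAMES = {1: "Mon", 2: "Tue", 3: "Wed", 4: "Thu", 5: "Fri",
                 6: "Sat", 7: "Sun"}


def _check(y, f):
    y = np.asarray(y, dtype=float).ravel()
    f = np.asarray(f, dtype=float).ravel()
    if len(y) == 0:
        raise ValueError("empty input")
    if len(y) != len(f):
        raise ValueError(f"length mismatch: {len(y)} vs {len(f)}")
    return y, f


def mfe(y, f) -> float:
    """Mean forecast error mean(y - f); 0 for an ideal model."""
    y, f = _check(y, f)
    return float(np.mean(y - f))


def mae(y, f) -> float:
    """Mean absolute error mean(|y - f|)."""
    y, f = _check(y, f)
    return float(np.mean(np.abs(y - f)))


def rmse(y, f) -> float:
    """Root mean square error sqrt(mean((y - f)^2))."""
    y, f = _check(y, f)
    return float(np.sqrt(np.mean((y - f) ** 2)))


def smape(y, f) -> float:
    """Symmetric mean absolute percentage error, in percent.

    Pairwise 200|y - f| / (y + f); pairs with y + f = 0 contribute 0.
    For nonnegative y and f the statistic lies in [0, 200].
    """
    y, f = _check(y, f)
    denom = y + f
    num = 200.0 * np.abs(y - f)
    terms = np.where(denom == 0, 0.0, num / np.where(denom == 0, 1.0, denom))
    return float(np.mean(terms))


def improvement_over(reference_mae: float, model_mae: float) -> float:
    """Percent MAE improvement of a model over a reference baseline:
    100 * (reference - model) / reference."""
    if reference_mae <= 0:
        raise ValueError("reference MAE must be > 0")
    return 100.0 * (reference_mae - model_mae) / reference_mae


def weekday_mae(runs: pd.DataFrame) -> pd.DataFrame:
    """Per-model, per-day-of-week MAE from a long-format runs table
    (columns: date, model, actual, forecast).  Weekdays are Mon=1..Sun=7."""
    r = runs.copy()
    r["weekday"] = pd.DatetimeIndex(r["date"]).dayofweek + 1
    r["abs_err"] = (r["actual"] - r["forecast"]).abs()
    table = (r.pivot_table(index="model", columns="weekday",
                           values="abs_err", aggfunc="mean"))
    table.columns = [WEEKDAY_NAMES[c] for c in table.columns]
    return table


@dataclass
class EvaluationResult:
    """Everything a rolling evaluation produces."""

    runs: pd.DataFrame            # long format: date, model, actual, forecast
    metrics: pd.DataFrame         # per model: mfe, mae, rmse, smape, improvement
    weekday_mae: pd.DataFrame     # model x weekday
    importance: pd.DataFrame | None = None   # RF permutation ranking
    model_params: dict = field(default_factory=dict)


def rolling_evaluate(daily: pd.DataFrame, features: pd.DataFrame,
                     models: dict[str, fc.BaseForecaster] | list[str],
                     split_date, *, baseline: str = "naive_m3w",
                     importance: bool = True) -> EvaluationResult:
    """Time-separated train/test evaluation.

    Models are fit on the block up to and including ``split_date`` and then
    produce one forecast per test day in chronological order, each from the
    daily series strictly before that day (feature-based models additionally
    receive the day's predictor row, itself built only from prior data).

    ``models`` is either a list of registry names or a mapping
    name -> estimator instance.  The improvement column is relative to
    ``baseline``, which must be among the evaluated models with MAE > 0.
    """
    split = pd.Timestamp(split_date)
    if isinstance(models, (list, tuple)):
        models = {name: fc.make_forecaster(name) for name in models}
    train_daily = daily.loc[:split]
    train_features = features.loc[:split]
    test_dates = features.index[features.index > split]
    if len(train_daily) == 0 or len(test_dates) == 0:
        raise ValueError("split date leaves an empty train or test block")

    pred_cols = predictor_columns(features)
    for name, model in models.items():
        model.fit(train_daily, features=train_features)

    records = []
    for d in test_dates:
        history = daily.loc[: d - fc.DAY]
        row = features.loc[d, pred_cols]
        actual = float(features.loc[d, TARGET_COLUMN])
        for name, model in models.items():
            f = model.forecast(history, d, features_row=row)
            records.append((d, name, actual, f))
    runs = pd.DataFrame(records,
                        columns=["date", "model", "actual", "forecast"])
    fitted_params = {name: _params_snapshot(model)
                     for name, model in models.items()}

    rows = []
    for name in models:
        sub = runs[runs["model"] == name]
        rows.append({
            "model": name,
            "mfe": mfe(sub["actual"], sub["forecast"]),
            "mae": mae(sub["actual"], sub["forecast"]),
            "rmse": rmse(sub["actual"], sub["forecast"]),
            "smape": smape(sub["actual"], sub["forecast"]),
        })
    metrics = pd.DataFrame(rows).set_index("model")
    if baseline in metrics.index and metrics.loc[baseline, "mae"] > 0:
        ref = metrics.loc[baseline, "mae"]
        metrics["improvement_over_" + baseline] = [
            improvement_over(ref, m) for m in metrics["mae"]]

    imp = None
    if importance:
        rf = next((m for m in models.values()
                   if isinstance(m, fc.RandomForestForecaster)), None)
        if rf is not None:
            imp = fc.feature_importance(rf)

    return EvaluationResult(runs=runs, metrics=metrics,
                            weekday_mae=weekday_mae(runs),
                            importance=imp, model_params=fitted_params)


def _params_snapshot(model: fc.BaseForecaster) -> dict:
    snap = dict(model.get_params())
    for attr in ("config_", "order_", "max_features_", "C_", "epsilon_",
                 "gamma_"):
        if hasattr(model, attr):
            val = getattr(model, attr)
            snap[attr.rstrip("_")] = (val.__dict__ if hasattr(val, "__dict__")
                                      and not isinstance(val, (int, float))
                                      else val)
    return snap


def plot_forecasts(runs: pd.DataFrame, path=None):
    """Actual vs forecast traces over the test block (one line per model)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(11, 4))
    actual = runs.drop_duplicates("date").set_index("date")["actual"]
    ax.plot(actual.index, actual.values, color="black", lw=1.2,
            label="actual")
    for name, sub in runs.groupby("model"):
        ax.plot(sub["date"], sub["forecast"], lw=0.8, alpha=0.7, label=name)
    ax.set_ylabel("discharges/day")
    ax.legend(ncol=4, fontsize=8)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig


def plot_weekday_mae(table: pd.DataFrame, path=None):
    """Bar chart of per-day-of-week MAE by model."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(9, 4))
    table.T.plot.bar(ax=ax, width=0.85)
    ax.set_ylabel("MAE (discharges/day)")
    ax.legend(ncol=4, fontsize=8)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
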