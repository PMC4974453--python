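"""Build the 108-predictor matrix for next-day discharge forecasting.

Each row is indexed by a forecast day d; every predictor is computable from
information available at the end of day d-1, and the target is y_d, the
discharge count on day d.  The 20 ward-level predictors are calendar codes
of the forecast day (day-of-week, month — both known in advance), a loess
trend extrapolated from past same-weekday discharges, 7 admission lags,
7 discharge lags, the lag-14 and lag-21 discharges, and previous-day
occupancy.  The 88 patient-level predictors are computed over the roster at
the end of day d-1: category counts for admission type (5), referral (49),
patient class (21), age band (8) and wards-visited band (4), plus the mean
elapsed length of stay of the patients currently in the ward.

Rows exist only where every lag is available (the 22nd day of the series
onwards); category counts partition the roster, so each count family sums
to previous-day occupancy.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import ingest
from .vocab import DEFAULT_VOCAB, UNKNOWN, Vocabulary

__all__ = [
    "trend_feature",
    "patient_level_counts",
    "build_feature_matrix",
    "column_groups",
    "WARD_LEVEL_COLUMNS",
    "N_WARD_LEVEL",
    "N_PATIENT_LEVEL",
    "N_PREDICTORS",
]

N_WARD_LEVEL = 20
N_PATIENT_LEVEL = 88
N_PREDICTORS = N_WARD_LEVEL + N_PATIENT_LEVEL

TARGET_COLUMN = "target"

WARD_LEVEL_COLUMNS = (
    ["day_of_week", "month", "trend"]
    + [f"adm_lag_{i}" for i in range(1, 8)]
    + [f"dis_lag_{i}" for i in range(1, 8)]
    + ["dis_lag_14", "dis_lag_21", "occ_prev"]
)


def trend_feature(past_same_weekday_discharges, span: float = 0.75) -> float:
    """Locally weighted quadratic regression trend, extrapolated one step.

    Fits a degree-2 polynomial with tricube weights to the ordered past
    same-weekday discharge counts (indices 1..n) and evaluates it at index
    n+1 — the upcoming occurrence of that weekday.  With fewer than 5
    observations the fit is unstable and the plain mean is returned instead.
    """
    y = np.asarray(past_same_weekday_discharges, dtype=float)
    n = len(y)
    if n == 0:
        raise ValueError("trend_feature requires at least one observation")
    if n < 5:
        return float(y.mean())
    x = np.arange(1.0, n + 1.0)
    x0 = n + 1.0
    q = int(np.ceil(span * n))
    q = max(q, 4)            # a quadratic plus one dof
    q = min(q, n)
    sel = slice(n - q, n)    # the q points nearest x0 are the most recent
    xs, ys = x[sel], y[sel]
    d = np.abs(xs - x0)
    dmax = d.max()
    w = np.clip(1.0 - (d / dmax) ** 3, 0.0, None) ** 3
    w[-1] = max(w[-1], 1e-6)  # keep the newest point from zeroing out
    # np.polyfit multiplies residuals by w, so pass sqrt of tricube weights
    coeffs = np.polyfit(xs, ys, 2, w=np.sqrt(w))
    return float(np.polyval(coeffs, x0))


def _count_columns(vocab: Vocabulary) -> dict[str, list[str]]:
    return {
        "admission_type": [f"admtype_{c}" for c in vocab.admission_types],
        "referral": [f"ref_{c}" for c in vocab.referrals],
        "patient_class": [f"class_{c}" for c in vocab.patient_classes],
        "age_band": [f"age_{c}" for c in vocab.age_bands],
        "wards_visited": [f"wv_{c}" for c in vocab.wards_visited_bands],
    }


def patient_level_columns(vocab: Vocabulary = DEFAULT_VOCAB) -> list[str]:
    cols = []
    for family in _count_columns(vocab).values():
        cols.extend(family)
    cols.append("mean_elapsed_los")
    return cols


def column_groups(vocab: Vocabulary = DEFAULT_VOCAB) -> dict:
    """Machine-readable manifest: each predictor column, its family and
    whether it is ward-level or patient-level."""
    fams = _count_columns(vocab)
    groups = {
        "ward_level": {
            "seasonality": ["day_of_week", "month"],
            "trend": ["trend"],
            "admission_lags": [f"adm_lag_{i}" for i in range(1, 8)],
            "discharge_lags": ([f"dis_lag_{i}" for i in range(1, 8)]
                               + ["dis_lag_14", "dis_lag_21"]),
            "occupancy": ["occ_prev"],
        },
        "patient_level": {
            "admission_type_counts": fams["admission_type"],
            "referral_counts": fams["referral"],
            "patient_class_counts": fams["patient_class"],
            "age_band_counts": fams["age_band"],
            "wards_visited_counts": fams["wards_visited"],
            "elapsed_los": ["mean_elapsed_los"],
        },
    }
    return groups


def _attr_category(visits: pd.DataFrame, vocab: Vocabulary) -> pd.DataFrame:
    """Per-visit category labels for the five count families, validated
    against the vocabulary (UNKNOWN tolerated, counted nowhere)."""
    out = pd.DataFrame(index=visits.index)
    out["admission_type"] = visits["admission_type"]
    out["referral"] = visits["referral"]
    out["patient_class"] = visits["patient_class"]
    out["age_band"] = [vocab.age_band(a) for a in visits["age"]]
    out["wards_visited"] = [vocab.wards_visited_band(int(n))
                            for n in visits["wards_visited"]]
    allowed = {
        "admission_type": set(vocab.admission_types) | {UNKNOWN},
        "referral": set(vocab.referrals) | {UNKNOWN},
        "patient_class": set(vocab.patient_classes) | {UNKNOWN},
    }
    for col, ok in allowed.items():
        bad = set(out[col].unique()) - ok
        if bad:
            raise ValueError(
                f"{col} values outside vocabulary: {sorted(bad)[:5]}")
    return out


def patient_level_counts(roster_df: pd.DataFrame, date, *,
                         vocab: Vocabulary = DEFAULT_VOCAB,
                         los_agg: str = "mean") -> pd.Series:
    """The 88 patient-level predictors for the roster at the end of ``date``.

    87 category counts (absent categories get 0; UNKNOWN values are counted
    in no column) plus the mean (or median) elapsed LOS; an empty roster
    yields all zeros by convention.
    """
    cols = patient_level_columns(vocab)
    out = pd.Series(0.0, index=cols)
    if len(roster_df) == 0:
        return out
    cats = _attr_category(roster_df, vocab)
    fams = _count_columns(vocab)
    vocab_labels = {
        "admission_type": vocab.admission_types,
        "referral": vocab.referrals,
        "patient_class": vocab.patient_classes,
        "age_band": vocab.age_bands,
        "wards_visited": vocab.wards_visited_bands,
    }
    for attr, colnames in fams.items():
        counts = cats[attr].value_counts()
        for label, cname in zip(vocab_labels[attr], colnames):
            out[cname] = float(counts.get(label, 0))
    los = ingest.elapsed_los_days(roster_df, date)
    agg = {"mean": np.mean, "median": np.median}[los_agg]
    out["mean_elapsed_los"] = float(agg(los))
    return out


def _rolling_patient_counts(visits: pd.DataFrame, dates: pd.DatetimeIndex,
                            vocab: Vocabulary, los_agg: str) -> pd.DataFrame:
    """Patient-level counts for many roster dates at once.

    Explodes each visit into the calendar days it occupies (end-of-day
    membership, half-open [entry, exit)) and aggregates per day — identical
    to calling :func:`patient_level_counts` per date, just vectorized.
    """
    cols = patient_level_columns(vocab)
    if len(visits) == 0:
        return pd.DataFrame(0.0, index=dates, columns=cols)
    first, last = dates.min(), dates.max()
    entry = visits["ward_entry"].dt.normalize()
    exitd = visits["ward_exit"].dt.normalize()
    start = entry.clip(lower=first)
    stop = (exitd - pd.Timedelta(days=1)).clip(upper=last)
    keep = stop >= start
    if not keep.any():
        return pd.DataFrame(0.0, index=dates, columns=cols)
    v = visits[keep]
    cats = _attr_category(v, vocab)
    lengths = ((stop[keep] - start[keep]).dt.days + 1).to_numpy()
    idx = np.repeat(np.arange(len(v)), lengths)
    offsets = np.concatenate([np.arange(n) for n in lengths])
    day = (start[keep].to_numpy().repeat(lengths)
           + offsets * np.timedelta64(1, "D"))
    entry_rep = entry[keep].to_numpy().repeat(lengths)
    long = pd.DataFrame({
        "day": day,
        "elapsed": (day - entry_rep) / np.timedelta64(1, "D") + 1,
    })
    for attr in ("admission_type", "referral", "patient_class",
                 "age_band", "wards_visited"):
        long[attr] = cats[attr].to_numpy()[idx]

    out = pd.DataFrame(0.0, index=dates, columns=cols)
    fams = _count_columns(vocab)
    vocab_labels = {
        "admission_type": vocab.admission_types,
        "referral": vocab.referrals,
        "patient_class": vocab.patient_classes,
        "age_band": vocab.age_bands,
        "wards_visited": vocab.wards_visited_bands,
    }
    for attr, colnames in fams.items():
        tab = pd.crosstab(long["day"], long[attr])
        for label, cname in zip(vocab_labels[attr], colnames):
            if label in tab.columns:
                out[cname] = tab[label].reindex(dates, fill_value=0).astype(float)
    agg = {"mean": "mean", "median": "median"}[los_agg]
    los = long.groupby("day")["elapsed"].agg(agg)
    out["mean_elapsed_los"] = los.reindex(dates).fillna(0.0)
    return out


def build_feature_matrix(daily: pd.DataFrame, visits: pd.DataFrame, *,
                         vocab: Vocabulary = DEFAULT_VOCAB,
                         span: float = 0.75,
                         los_agg: str = "mean") -> pd.DataFrame:
    """Assemble the full 108-predictor matrix plus the ``target`` column.

    ``daily`` is the contiguous daily series from
    :func:`wardflow.ingest.derive_daily_series`; ``visits`` the joined visit
    records (used for the roster-based patient-level block).  Rows run from
    the 22nd series day (all lags available) to the last day.  Deterministic
    given its inputs.
    """
    if len(daily) < 23:
        raise ValueError("need at least 23 days of daily series")
    dates = daily.index
    rows = dates[21:]
    y = daily["discharges"].astype(float)
    a = daily["admissions"].astype(float)

    X = pd.DataFrame(index=rows)
    X.index.name = "date"
    X["day_of_week"] = rows.dayofweek + 1          # Mon=1..Sun=7
    X["month"] = rows.month
    # trend: loess over past same-weekday discharges, extrapolated to d
    trend = np.empty(len(rows))
    yv = y.to_numpy()
    pos = np.arange(len(dates))
    for i, d in enumerate(rows):
        p = pos[21 + i]
        past = yv[p % 7:p:7]  # same weekday, ascending, strictly before d
        trend[i] = trend_feature(past, span=span)
    X["trend"] = trend
    for lag in range(1, 8):
        X[f"adm_lag_{lag}"] = a.shift(lag).loc[rows].to_numpy()
        X[f"dis_lag_{lag}"] = y.shift(lag).loc[rows].to_numpy()
    X["dis_lag_14"] = y.shift(14).loc[rows].to_numpy()
    X["dis_lag_21"] = y.shift(21).loc[rows].to_numpy()
    X["occ_prev"] = daily["occupancy"].shift(1).loc[rows].astype(float).to_numpy()
    X = X[WARD_LEVEL_COLUMNS]

    roster_dates = rows - pd.Timedelta(days=1)
    counts = _rolling_patient_counts(visits, pd.DatetimeIndex(roster_dates),
                                     vocab, los_agg)
    counts.index = rows
    X = pd.concat([X, counts], axis=1)

    assert X.shape[1] == N_PREDICTORS
    X[TARGET_COLUMN] = y.loc[rows].to_numpy()
    return X


def predictor_columns(features: pd.DataFrame) -> list[str]:
    """All predictor columns of a built matrix (everything but the target)."""
    return [c for c in features.columns if c != TARGET_COLUMN]
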