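"""Read and validate the raw three-table extract; derive daily series.

The joined visit record carries one row per ward admission with entry/exit
timestamps and the categorical patient attributes.  From the visits we derive
the date-indexed daily series used everywhere downstream:

* ``discharges`` — visits whose ward exit falls on that calendar date,
* ``admissions`` — visits whose ward entry falls on that calendar date,
* ``occupancy``  — end-of-day census: visits with entry_date <= d < exit_date
  (half-open stay interval, so a bed is never double-counted on turnover day).

The conservation identity o_t = o_{t-1} + a_t - y_t holds exactly under
these conventions.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .vocab import UNKNOWN

__all__ = [
    "SchemaError",
    "ValidationError",
    "read_tables",
    "join_tables",
    "derive_daily_series",
    "roster",
    "elapsed_los_days",
    "write_daily_series",
    "read_daily_series",
]

REQUIRED_COLUMNS = {
    "patients": ["patient_id", "age", "gender"],
    "ward_stay": ["admission_id", "entry_time", "exit_time"],
    "admissions": ["patient_id", "admission_id", "patient_class",
                   "admission_type", "referral_source", "wards_visited"],
}

CATEGORICAL_COLUMNS = ["gender", "patient_class", "admission_type",
                       "referral_source"]


class SchemaError(ValueError):
    """A raw table is missing required columns."""


class ValidationError(ValueError):
    """One or more rows violate a record invariant."""


def read_tables(in_dir: str | Path, *, on_invalid: str = "raise"):
    """Read patients.csv / ward_stay.csv / admissions.csv from ``in_dir``
    and return joined visit records (see :func:`join_tables`)."""
    in_dir = Path(in_dir)
    frames = {}
    for name in REQUIRED_COLUMNS:
        path = in_dir / f"{name}.csv"
        if not path.exists():
            raise SchemaError(f"missing table file: {path}")
        frames[name] = pd.read_csv(path)
    return join_tables(frames["patients"], frames["ward_stay"],
                       frames["admissions"], on_invalid=on_invalid)


def join_tables(patients: pd.DataFrame, ward_stay: pd.DataFrame,
                admissions: pd.DataFrame, *,
                on_invalid: str = "raise") -> pd.DataFrame:
    """Join the three tables into one visit record per admission.

    Parameters
    ----------
    on_invalid : {"raise", "drop"}
        ``"raise"`` (default) raises :class:`ValidationError` naming the
        offending admission_ids; ``"drop"`` removes invalid rows and attaches
        the per-row report as ``visits.attrs["rejects"]``.

    Returns a DataFrame with columns: patient_id, admission_id, age, gender,
    ward_entry, ward_exit, patient_class, admission_type, referral,
    wards_visited.  Missing categorical values are mapped to ``"UNKNOWN"``
    rather than dropped (patient-level predictors are counts over the roster
    and must not silently shrink).
    """
    if on_invalid not in ("raise", "drop"):
        raise ValueError("on_invalid must be 'raise' or 'drop'")
    for name, df in (("patients", patients), ("ward_stay", ward_stay),
                     ("admissions", admissions)):
        missing = set(REQUIRED_COLUMNS[name]) - set(df.columns)
        if missing:
            raise SchemaError(f"table {name!r} missing columns {sorted(missing)}")

    visits = (admissions.merge(patients, on="patient_id", how="left")
              .merge(ward_stay[["admission_id", "entry_time", "exit_time"]],
                     on="admission_id", how="inner"))
    visits = visits.rename(columns={"entry_time": "ward_entry",
                                    "exit_time": "ward_exit",
                                    "referral_source": "referral"})
    visits["ward_entry"] = pd.to_datetime(visits["ward_entry"])
    visits["ward_exit"] = pd.to_datetime(visits["ward_exit"])
    for col in ["gender", "patient_class", "admission_type", "referral"]:
        visits[col] = visits[col].fillna(UNKNOWN)
    visits["wards_visited"] = (pd.to_numeric(visits["wards_visited"],
                                             errors="coerce")
                               .fillna(1).astype(int).clip(lower=1))
    visits["age"] = visits["age"].fillna(0).astype(float)

    bad_time = visits["ward_exit"] < visits["ward_entry"]
    bad_age = visits["age"] < 0
    bad = bad_time | bad_age
    if bad.any():
        report = pd.DataFrame({
            "admission_id": visits.loc[bad, "admission_id"],
            "reason": np.where(bad_time[bad], "ward_exit < ward_entry",
                               "negative age"),
        })
        if on_invalid == "raise":
            ids = ", ".join(report["admission_id"].astype(str))
            raise ValidationError(
                f"{len(report)} invalid visit row(s): {ids}")
        visits = visits[~bad].reset_index(drop=True)
        visits.attrs["rejects"] = report.reset_index(drop=True)
    else:
        visits.attrs["rejects"] = pd.DataFrame(
            columns=["admission_id", "reason"])

    cols = ["patient_id", "admission_id", "age", "gender", "ward_entry",
            "ward_exit", "patient_class", "admission_type", "referral",
            "wards_visited"]
    out = visits[cols].copy()
    out.attrs["rejects"] = visits.attrs["rejects"]
    return out


def derive_daily_series(visits: pd.DataFrame,
                        date_range: pd.DatetimeIndex | None = None
                        ) -> pd.DataFrame:
    """Derive the contiguous daily series (discharges, admissions, occupancy).

    ``date_range`` defaults to [first entry date, last exit date].  Days with
    no events carry zeros.  Occupancy counts visits already in the ward at
    range start, so the conservation identity holds from the second day on.
    """
    if date_range is None:
        if len(visits) == 0:
            raise ValueError("cannot infer date range from empty visits")
        date_range = pd.date_range(visits["ward_entry"].min().normalize(),
                                   visits["ward_exit"].max().normalize(),
                                   freq="D")
    if len(date_range) == 0:
        raise ValueError("empty date range")
    date_range = pd.DatetimeIndex(date_range).normalize()

    entry_day = visits["ward_entry"].dt.normalize() if len(visits) else pd.Series([], dtype="datetime64[ns]")
    exit_day = visits["ward_exit"].dt.normalize() if len(visits) else pd.Series([], dtype="datetime64[ns]")

    a = entry_day.value_counts().reindex(date_range, fill_value=0)
    y = exit_day.value_counts().reindex(date_range, fill_value=0)
    # end-of-day census: entered by end of d minus exited by end of d
    ent = np.sort(entry_day.values)
    ext = np.sort(exit_day.values)
    o = (np.searchsorted(ent, date_range.values, side="right")
         - np.searchsorted(ext, date_range.values, side="right"))
    daily = pd.DataFrame({"discharges": y.astype(int).values,
                          "admissions": a.astype(int).values,
                          "occupancy": np.asarray(o, dtype=int)},
                         index=date_range)
    daily.index.name = "date"
    return daily


def roster(visits: pd.DataFrame, date) -> pd.DataFrame:
    """Visits present in the ward at the *end* of ``date``.

    Membership rule matches occupancy exactly (half-open [entry, exit)):
    entry_date <= date < exit_date, so a patient exiting at 09:00 on D is
    absent from roster(D), and |roster(date)| == occupancy on that date.
    """
    d = pd.Timestamp(date).normalize()
    present = ((visits["ward_entry"].dt.normalize() <= d)
               & (visits["ward_exit"].dt.normalize() > d))
    return visits[present]


def elapsed_los_days(roster_df: pd.DataFrame, date) -> pd.Series:
    """Running stay length in whole days at the end of ``date`` (admission
    day counts as day 1, matching an LOS convention with no zero band)."""
    d = pd.Timestamp(date).normalize()
    return (d - roster_df["ward_entry"].dt.normalize()).dt.days + 1


def write_daily_series(daily: pd.DataFrame, path: str | Path) -> None:
    out = daily.reset_index()
    out["date"] = out["date"].dt.strftime("%Y-%m-%d")
    out.to_csv(path, index=False)


def read_daily_series(path: str | Path) -> pd.DataFrame:
    daily = pd.read_csv(path, parse_dates=["date"]).set_index("date")
    return daily
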