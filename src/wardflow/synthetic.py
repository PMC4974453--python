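"""Seeded synthetic ward-flow generator.

Emits the three raw hospital-style tables (patients, ward stay, admissions)
with the statistical structure the downstream analysis assumes:

* admissions per day are Poisson with a day-of-week and annual-sinusoid
  modulated rate;
* each patient's discharge day is drawn via a geometric-like *daily hazard*
  modulated by a weekday multiplier, so realized length of stay and discharge
  weekday are coupled — this is what produces the Friday discharge peak and
  the weekend trough (the "weekend effect") rather than an i.i.d. LOS draw;
* categorical attributes are drawn from configurable probability vectors over
  the fixed vocabularies.

The shipped :func:`default_config` targets a ward discharging a median of 8
patients per day (mean ~8.7), LOS median 3 days / mean ~4.26, over a
5-year span.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple

import numpy as np
import pandas as pd

from .vocab import DEFAULT_VOCAB, Vocabulary

__all__ = [
    "CategoryProbs",
    "SimConfig",
    "SimTables",
    "ConfigurationError",
    "default_config",
    "simulate_ward",
    "write_tables",
]

WARD_NAME = "HW5"


class ConfigurationError(ValueError):
    """Raised for an invalid simulation configuration."""


def _decaying_probs(n: int, scale: float) -> tuple[float, ...]:
    w = np.exp(-np.arange(n) / scale)
    return tuple(w / w.sum())


@dataclass(frozen=True)
class CategoryProbs:
    """Probability vectors over the categorical vocabularies (each sums to 1)."""

    admission_type: tuple[float, ...] = _decaying_probs(5, 2.0)
    referral: tuple[float, ...] = _decaying_probs(49, 10.0)
    patient_class: tuple[float, ...] = _decaying_probs(21, 5.0)
    # skewed towards the elderly: mean simulated age ~ 63
    age_band: tuple[float, ...] = (0.02, 0.05, 0.06, 0.08, 0.15, 0.25, 0.25, 0.14)
    wards_visited: tuple[float, ...] = (0.55, 0.25, 0.12, 0.08)
    gender: tuple[float, ...] = (0.452, 0.548)  # (M, F)


@dataclass(frozen=True)
class SimConfig:
    """Full parameterization of the ward-flow simulator.

    Parameters
    ----------
    n_days : number of simulated calendar days.
    start_date : first simulated day (ISO date).
    base_admission_rate : mean admissions per day before modulation.
    dow_admission_multipliers : Mon..Sun multipliers on the admission rate.
    dow_discharge_hazard_multipliers : Mon..Sun multipliers on the daily
        discharge hazard; a large Friday / small weekend value creates the
        weekend effect.
    monthly_amplitude : amplitude in [0, 1) of an annual sinusoidal
        modulation of the admission rate.
    base_discharge_hazard : baseline daily probability of discharge from the
        day after entry onwards (geometric LOS law when all multipliers are 1).
    max_los_days : hard cap; a patient still present after this many days is
        discharged (keeps the LOS law proper).
    repeat_visit_prob : probability that an admission belongs to a previously
        seen patient.
    category_probs : probability vectors for the categorical attributes.
    seed : RNG seed; identical (seed, config) gives bit-identical tables.
    """

    n_days: int = 1826
    start_date: str = "2010-01-01"
    base_admission_rate: float = 8.6
    dow_admission_multipliers: tuple[float, ...] = (
        1.097, 1.097, 1.149, 1.097, 1.045, 0.784, 0.731)
    dow_discharge_hazard_multipliers: tuple[float, ...] = (
        1.10, 1.15, 1.20, 1.30, 1.60, 0.40, 0.30)
    monthly_amplitude: float = 0.15
    base_discharge_hazard: float = 0.232
    max_los_days: int = 60
    repeat_visit_prob: float = 0.12
    category_probs: CategoryProbs = field(default_factory=CategoryProbs)
    vocab: Vocabulary = field(default_factory=lambda: DEFAULT_VOCAB)
    seed: int = 20160721

    def validate(self) -> None:
        if self.n_days < 1:
            raise ConfigurationError(f"n_days must be >= 1, got {self.n_days}")
        if self.base_admission_rate <= 0:
            raise ConfigurationError("base_admission_rate must be > 0")
        if not 0 <= self.monthly_amplitude < 1:
            raise ConfigurationError("monthly_amplitude must be in [0, 1)")
        if not 0 < self.base_discharge_hazard <= 1:
            raise ConfigurationError("base_discharge_hazard must be in (0, 1]")
        for name in ("dow_admission_multipliers",
                     "dow_discharge_hazard_multipliers"):
            m = np.asarray(getattr(self, name), dtype=float)
            if m.shape != (7,) or (m < 0).any():
                raise ConfigurationError(f"{name} must be 7 nonnegative reals")
        probs = dataclasses.asdict(self.category_probs)
        sizes = {
            "admission_type": len(self.vocab.admission_types),
            "referral": len(self.vocab.referrals),
            "patient_class": len(self.vocab.patient_classes),
            "age_band": len(self.vocab.age_bands),
            "wards_visited": len(self.vocab.wards_visited_bands),
            "gender": len(self.vocab.genders),
        }
        for name, p in probs.items():
            p = np.asarray(p, dtype=float)
            if len(p) != sizes[name]:
                raise ConfigurationError(
                    f"category_probs.{name} must have {sizes[name]} entries")
            if (p < 0).any() or abs(p.sum() - 1.0) > 1e-9:
                raise ConfigurationError(
                    f"category_probs.{name} must be a probability vector")


class SimTables(NamedTuple):
    """The three raw tables produced by the simulator."""

    patients: pd.DataFrame
    ward_stay: pd.DataFrame
    admissions: pd.DataFrame


def default_config(**overrides) -> SimConfig:
    """Shipped parameterization: 5-year span, ~8.6 admissions/day, LOS
    median 3 / mean ~4.26, Friday discharge peak and weekend trough, mild
    annual seasonality.  ``seed`` is fixed (20160721) for reproducibility."""
    return SimConfig(**overrides)


def simulate_ward(config: SimConfig | None = None) -> SimTables:
    """Simulate the ward and return the three raw tables.

    Deterministic given ``(config, config.seed)``.  Visits whose discharge
    falls after the simulated horizon are kept (their exit timestamp simply
    lies past ``n_days``), so end-of-horizon occupancy is not artificially
    drained.
    """
    config = config or default_config()
    config.validate()
    rng = np.random.default_rng(config.seed)
    vocab = config.vocab
    probs = config.category_probs

    days = pd.date_range(config.start_date, periods=config.n_days, freq="D")
    dow = days.dayofweek.to_numpy()  # Mon=0..Sun=6
    doy = days.dayofyear.to_numpy()
    adm_mult = np.asarray(config.dow_admission_multipliers, dtype=float)
    dis_mult = np.asarray(config.dow_discharge_hazard_multipliers, dtype=float)
    annual = 1.0 + config.monthly_amplitude * np.sin(
        2.0 * np.pi * (doy - 1) / 365.25)
    lam = config.base_admission_rate * adm_mult[dow] * annual
    n_adm = rng.poisson(lam)
    n_total = int(n_adm.sum())

    entry_day_idx = np.repeat(np.arange(config.n_days), n_adm)

    # LOS via the daily discharge hazard, starting the day after entry
    los = np.zeros(n_total, dtype=np.int64)
    alive = np.ones(n_total, dtype=bool)
    for j in range(1, config.max_los_days):
        wd = (dow[entry_day_idx] + j) % 7
        hazard = np.minimum(1.0, config.base_discharge_hazard * dis_mult[wd])
        newly_out = alive & (rng.random(n_total) < hazard)
        los[newly_out] = j
        alive &= ~newly_out
    los[alive] = config.max_los_days

    entry_hour = rng.integers(0, 24, size=n_total)
    exit_hour = rng.integers(0, 24, size=n_total)
    entry_time = days[entry_day_idx] + pd.to_timedelta(entry_hour, unit="h")
    exit_time = (days[entry_day_idx] + pd.to_timedelta(los, unit="D")
                 + pd.to_timedelta(exit_hour, unit="h"))

    # patient identity: a fraction of admissions are repeat visits
    repeat = rng.random(n_total) < config.repeat_visit_prob
    repeat[0] = False
    patient_no = np.cumsum(~repeat)  # new-patient counter, 1-based
    n_patients = int(patient_no[-1])
    pid_idx = np.where(
        repeat, rng.integers(1, np.maximum(patient_no, 2)), patient_no)
    patient_ids = np.array([f"P{int(i):06d}" for i in pid_idx])
    admission_ids = np.array([f"A{i:06d}" for i in range(1, n_total + 1)])

    def draw(labels, p):
        return rng.choice(np.asarray(labels, dtype=object), size=n_total,
                          p=np.asarray(p, dtype=float))

    admission_type = draw(vocab.admission_types, probs.admission_type)
    referral = draw(vocab.referrals, probs.referral)
    patient_class = draw(vocab.patient_classes, probs.patient_class)
    band_idx = rng.choice(len(vocab.age_bands), size=n_total,
                          p=np.asarray(probs.age_band, dtype=float))
    edges = np.asarray(vocab.age_band_edges, dtype=float)
    age = np.floor(edges[band_idx]
                   + rng.random(n_total) * (edges[band_idx + 1] - edges[band_idx]))
    wards_visited = 1 + rng.choice(
        len(vocab.wards_visited_bands), size=n_total,
        p=np.asarray(probs.wards_visited, dtype=float))
    gender = draw(vocab.genders, probs.gender)

    admissions = pd.DataFrame({
        "patient_id": patient_ids,
        "admission_id": admission_ids,
        "admit_time": entry_time,
        "discharge_time": exit_time,
        "patient_class": patient_class,
        "admission_type": admission_type,
        "referral_source": referral,
        "wards_visited": wards_visited,
    })
    ward_stay = pd.DataFrame({
        "admission_id": admission_ids,
        "ward": WARD_NAME,
        "bed_id": [f"B{int(b):02d}" for b in rng.integers(1, 81, size=n_total)],
        "entry_time": entry_time,
        "exit_time": exit_time,
    })
    # per-patient demographics come from that patient's first admission
    patients = (pd.DataFrame({
        "patient_id": patient_ids, "age": age.astype(int), "gender": gender})
        .drop_duplicates("patient_id", keep="first")
        .sort_values("patient_id")
        .reset_index(drop=True))
    assert len(patients) <= n_patients

    return SimTables(patients=patients, ward_stay=ward_stay,
                     admissions=admissions)


def write_tables(tables: SimTables, out_dir: str | Path) -> dict[str, Path]:
    """Write patients.csv / ward_stay.csv / admissions.csv with ISO-8601
    timestamps; returns the written paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, df in tables._asdict().items():
        df = df.copy()
        for col in df.columns:
            if pd.api.types.is_datetime64_any_dtype(df[col]):
                df[col] = df[col].dt.strftime("%Y-%m-%dT%H:%M:%S")
        path = out / f"{name}.csv"
        df.to_csv(path, index=False)
        paths[name] = path
    return paths
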