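import numpy as np
import pandas as pd
import pytest

import wardflow as wf


@pytest.fixture(scope="session")
def sim_small():
    """One 400-day simulated dataset shared across tests: (config, tables,
    visits, daily, features)."""
    cfg = wf.default_config(n_days=400)
    tables = wf.simulate_ward(cfg)
    visits = wf.ingest.join_tables(*tables)
    days = pd.date_range(cfg.start_date, periods=cfg.n_days)
    daily = wf.derive_daily_series(visits, days)
    features = wf.build_feature_matrix(daily, visits)
    return cfg, tables, visits, daily, features


@pytest.fixture(scope="session")
def sim_default_5y():
    """The shipped 5-year default simulation (used for summary-statistic
    checks that need >= 10,000 visits)."""
    cfg = wf.default_config()
    tables = wf.simulate_ward(cfg)
    return cfg, tables


def make_visits(rows):
    """Hand-built visit records from (patient_id, entry, exit[, extras])."""
    defaults = dict(age=70.0, gender="F", patient_class="CLASS_01",
                    admission_type="ADMTYPE_01", referral="REF_01",
                    wards_visited=1)
    recs = []
    for i, row in enumerate(rows):
        rec = dict(defaults, patient_id=row[0], admission_id=f"A{i:04d}",
                   ward_entry=pd.Timestamp(row[1]),
                   ward_exit=pd.Timestamp(row[2]))
        if len(row) > 3:
            rec.update(row[3])
        recs.append(rec)
    return pd.DataFrame(recs)


@pytest.fixture
def three_visits():
    return make_visits([
        ("P1", "2020-01-01 10:00", "2020-01-03 09:00"),
        ("P2", "2020-01-01 23:00", "2020-01-05 12:00"),
        ("P3", "2020-01-02 08:00", "2020-01-04 17:00"),
    ])
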