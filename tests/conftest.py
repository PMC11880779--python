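"""Shared fixtures: hand-built micro-cohorts and small simulated cohorts."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from landshap.cohort_sim import RawCohort
from landshap.config import SimConfig
from landshap.cohort_sim import simulate_cohort

PERSON_DEFAULTS = dict(
    sex="F", ethnicity="White", smoking="Never", townsend=0.0, bmi=26.0,
    alcohol=1.5, education="GCSE", fibre=13.0, processed_meat=1.0, red_meat=2.0,
    pgs=0.0, multimorbidity_score=0.0, screening_eligible=1,
    family_history_bowel=0, family_history_breast=0, family_history_lung=0,
    baseline_date="2008-06-15",
)


def make_cohort(persons, coverage=(), events=(), tests=(), registry=(),
                linkage=()) -> RawCohort:
    """Build a RawCohort from terse per-person dict specs.

    ``persons``: list of dicts with at least person_id and birth_date;
    other tables are (person_id, ...) tuples.  ``linkage`` defaults to a
    far-future pc_end for every person.
    """
    prows = []
    for p in persons:
        row = dict(PERSON_DEFAULTS)
        row.update(p)
        prows.append(row)
    pf = pd.DataFrame(prows)
    pf["birth_date"] = pd.to_datetime(pf["birth_date"])
    pf["baseline_date"] = pd.to_datetime(pf["baseline_date"])

    cov = pd.DataFrame(coverage, columns=["person_id", "start_date", "end_date"])
    for c in ("start_date", "end_date"):
        cov[c] = pd.to_datetime(cov[c]) if len(cov) else pd.to_datetime(cov[c])
    ev = pd.DataFrame(events, columns=["person_id", "date", "code"])
    ev["date"] = pd.to_datetime(ev["date"])
    bt = pd.DataFrame(tests, columns=["person_id", "date", "test_family", "abnormal"])
    bt["date"] = pd.to_datetime(bt["date"])
    reg = pd.DataFrame(registry, columns=["person_id", "date", "event_type"])
    reg["date"] = pd.to_datetime(reg["date"])
    if linkage:
        lk = pd.DataFrame(linkage, columns=["person_id", "pc_end_date"])
    else:
        lk = pd.DataFrame({"person_id": pf.person_id,
                           "pc_end_date": "2030-01-01"})
    lk["pc_end_date"] = pd.to_datetime(lk["pc_end_date"])
    return RawCohort(persons=pf, coverage=cov, clinical_events=ev,
                     blood_tests=bt, registry=reg, linkage_end=lk)


def full_coverage(person_id, start="1990-01-01", end="2025-01-01"):
    return [(person_id, start, end)]


@pytest.fixture(scope="session")
def small_sim_cohort():
    """Default-configuration simulated cohort shared by read-only tests."""
    return simulate_cohort(SimConfig(n_persons=400, seed=202))


def synthetic_survival_frame(n_rows, betas, rng, base_hazard=0.002,
                             horizon=730):
    """Simple exponential survival frame: one row per person, binary/normal
    covariates, administrative censoring at ``horizon`` days.

    ``betas``: dict column -> (kind, log_hr) with kind in {"binary","normal"}.
    Used as a fast, landmark-free test bed for the modelling layer.
    """
    cols = {}
    lp = np.zeros(n_rows)
    for name, (kind, b) in betas.items():
        x = (rng.random(n_rows) < 0.3).astype(float) if kind == "binary" \
            else rng.normal(size=n_rows)
        cols[name] = x
        lp += b * x
    t = rng.exponential(1.0 / (base_hazard * np.exp(lp)))
    event = (t <= horizon).astype(int)
    time_days = np.minimum(t, horizon)
    df = pd.DataFrame(cols)
    df["person_id"] = np.arange(n_rows)
    df["time_days"] = time_days
    df["event"] = event
    df["true_lp"] = lp
    return df
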