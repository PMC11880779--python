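"""Synthetic longitudinal cohort generator.

Emulates the structure of a linked electronic-health-record cohort: a
baseline questionnaire table, primary-care coverage intervals with gaps,
dated clinical events whose rates rise log-linearly with age, dated blood
tests with abnormal-result flags, and a cancer/death registry driven by a
proportional-hazards colorectal-cancer (CRC) process with configurable
ground-truth log hazard ratios, plus independent competing other-cancer and
death processes.

All randomness for one person comes from a single
``numpy.random.default_rng([seed, person_id])`` stream, so cohorts are
bit-identical under a fixed seed and reproducible under parallel
generation.  Dates are handled internally as integer days since 1900-01-01
and emitted as ``datetime64[ns]`` columns / ISO-8601 text.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import SimConfig

EPOCH = np.datetime64("1900-01-01")
DAYS_PER_YEAR = 365.25

ETHNICITY_LEVELS = ("White", "SE Asian", "Black", "Mixed", "Other")
ETHNICITY_PROBS = (0.952, 0.020, 0.011, 0.006, 0.011)
SMOKING_LEVELS = ("Never", "Current", "Former")
SMOKING_PROBS = (0.555, 0.104, 0.341)
EDUCATION_LEVELS = ("Higher Education", "A-level", "GCSE", "CSE",
                    "Vocational", "Professional", "None")
EDUCATION_PROBS = (0.334, 0.111, 0.212, 0.052, 0.067, 0.053, 0.171)

# hazard predictors that are person-level static numeric attributes
_STATIC_HAZARD_COLS = ("pgs", "bmi", "townsend", "multimorbidity_score")
# hazard predictors derived from abnormal blood tests
_TEST_HAZARD_STATES = {"iron_abnormal": "iron", "inflammation_abnormal": "inflammation"}

PERSON_TABLES = ("persons", "coverage", "clinical_events", "blood_tests",
                 "registry", "linkage_end")


@dataclass
class RawCohort:
    """Long-format synthetic cohort: five event-stream tables plus linkage."""

    persons: pd.DataFrame
    coverage: pd.DataFrame
    clinical_events: pd.DataFrame
    blood_tests: pd.DataFrame
    registry: pd.DataFrame
    linkage_end: pd.DataFrame

    def write_dir(self, out_dir: str) -> None:
        """Write the six tables as CSV with ISO-8601 dates."""
        os.makedirs(out_dir, exist_ok=True)
        for name in PERSON_TABLES:
            getattr(self, name).to_csv(os.path.join(out_dir, f"{name}.csv"),
                                       index=False, date_format="%Y-%m-%d")

    @classmethod
    def read_dir(cls, in_dir: str) -> "RawCohort":
        frames = {}
        date_cols = {
            "persons": ["birth_date", "baseline_date"],
            "coverage": ["start_date", "end_date"],
            "clinical_events": ["date"],
            "blood_tests": ["date"],
            "registry": ["date"],
            "linkage_end": ["pc_end_date"],
        }
        for name in PERSON_TABLES:
            # "None" is a legitimate categorical level (education); only
            # genuinely empty cells are missing
            frames[name] = pd.read_csv(os.path.join(in_dir, f"{name}.csv"),
                                       parse_dates=date_cols[name],
                                       keep_default_na=False, na_values=[""])
        return cls(**frames)


# --------------------------------------------------------------------------
# helpers

def _date_from_days(days):
    return EPOCH + np.asarray(np.round(days), dtype="int64").astype("timedelta64[D]")


def _days_from_year(year: float) -> float:
    return (year - 1900) * DAYS_PER_YEAR


def _choice(rng, levels, probs):
    return levels[int(rng.choice(len(levels), p=probs))]


def true_linear_predictor(person_state: dict, config: SimConfig) -> float:
    """Ground-truth log-hazard offset sum(log_hr_k * x_k) for one state.

    ``person_state`` must contain a numeric value for every predictor named
    in ``config.true_log_hrs``; raises ``KeyError`` otherwise.  This is the
    oracle used by parameter-recovery and discrimination tests.
    """
    total = 0.0
    for name, log_hr in config.true_log_hrs.items():
        if name not in person_state:
            raise KeyError(f"person_state is missing predictor {name!r}")
        total += log_hr * float(person_state[name])
    return total


def _classify_hazard_terms(config: SimConfig):
    """Split true_log_hrs keys into static, event-code, and blood-test terms."""
    static, events, tests = [], [], []
    for name in config.true_log_hrs:
        if name in _STATIC_HAZARD_COLS:
            static.append(name)
        elif name in config.event_rates:
            events.append(name)
        elif name in _TEST_HAZARD_STATES:
            tests.append(name)
        else:
            raise ValueError(
                f"unknown predictor {name!r} in true_log_hrs: must be one of "
                f"{_STATIC_HAZARD_COLS}, an event code, or one of "
                f"{tuple(_TEST_HAZARD_STATES)}")
    return static, events, tests


def _banded_event_times(rng, rates, slopes, start_age, end_age):
    """Poisson event ages for several codes over yearly age bands.

    Returns (code_index_array, age_days_array); rates are per person-year at
    age 60 with log-linear slopes.
    """
    lo = int(math.floor(start_age))
    hi = int(math.ceil(end_age))
    if hi <= lo:
        return np.empty(0, dtype=np.int64), np.empty(0)
    bands = np.arange(lo, hi)                       # [band, band+1)
    mid = bands + 0.5
    lam = rates[:, None] * np.exp(slopes[:, None] * (mid[None, :] - 60.0))
    # clip partial first/last band exposure
    exposure = np.minimum(bands + 1, end_age) - np.maximum(bands, start_age)
    exposure = np.clip(exposure, 0.0, 1.0)
    counts = rng.poisson(lam * exposure[None, :]).ravel()
    total = int(counts.sum())
    if total == 0:
        return np.empty(0, dtype=np.int64), np.empty(0)
    code_grid = np.repeat(np.arange(len(rates)), len(bands))
    lo_grid = np.tile(np.maximum(bands, start_age).astype(float), len(rates))
    hi_grid = np.tile(np.minimum(bands + 1, end_age).astype(float), len(rates))
    code_idx = np.repeat(code_grid, counts)
    band_lo = np.repeat(lo_grid, counts)
    band_hi = np.repeat(hi_grid, counts)
    ages = band_lo + rng.random(total) * (band_hi - band_lo)
    return code_idx.astype(np.int64), ages * DAYS_PER_YEAR


def _exposure_intervals(onsets_days: np.ndarray, persistence_days):
    """Merge onset times into [on, off) intervals of elevated hazard."""
    if len(onsets_days) == 0:
        return []
    onsets = np.sort(onsets_days)
    if persistence_days is None:
        return [(onsets[0], np.inf)]
    out = []
    cur_on = onsets[0]
    cur_off = onsets[0] + persistence_days
    for t in onsets[1:]:
        if t <= cur_off:
            cur_off = t + persistence_days
        else:
            out.append((cur_on, cur_off))
            cur_on, cur_off = t, t + persistence_days
    out.append((cur_on, cur_off))
    return out


def _piecewise_event_time(rng, t0, t1, breakpoints, hazard_fn):
    """Draw one event time on [t0, t1) for a piecewise-constant hazard.

    ``breakpoints`` are candidate change points (days); ``hazard_fn(t)``
    returns the per-day hazard on the segment starting at t.  Returns np.inf
    if no event occurs before t1.
    """
    if t1 <= t0:
        return np.inf
    cuts = np.unique(np.clip(np.asarray(breakpoints, dtype=float), t0, t1))
    grid = np.unique(np.concatenate([[t0], cuts, [t1]]))
    target = rng.exponential()
    acc = 0.0
    for a, b in zip(grid[:-1], grid[1:]):
        if b <= a:
            continue
        h = hazard_fn(a)
        seg = h * (b - a)
        if acc + seg >= target:
            return a + (target - acc) / h if h > 0 else np.inf
        acc += seg
    return np.inf


# --------------------------------------------------------------------------
# main generator

def simulate_cohort(config: SimConfig) -> RawCohort:
    """Generate a :class:`RawCohort` from ``config``; deterministic per seed."""
    config.validate()
    static_terms, event_terms, test_terms = _classify_hazard_terms(config)

    event_codes = list(config.event_rates)
    ev_rates = np.array([config.event_rates[c][0] for c in event_codes])
    ev_slopes = np.array([config.event_rates[c][1] for c in event_codes])
    fam_names = list(config.blood_test_rates)
    bt_rates = np.array([config.blood_test_rates[f][0] for f in fam_names])
    bt_slopes = np.array([config.blood_test_rates[f][1] for f in fam_names])
    bt_pabn = np.array([config.blood_test_rates[f][2] for f in fam_names])

    linkage_days = _days_from_year(config.linkage_end_year + 1) - 1  # Dec 31

    persons_rows = []
    cov_pid, cov_start, cov_end = [], [], []
    ev_pid, ev_date, ev_code = [], [], []
    bt_pid, bt_date, bt_fam, bt_abn = [], [], [], []
    reg_pid, reg_date, reg_type = [], [], []
    lk_pid, lk_end = [], []

    h0_daily = config.crc_baseline_hazard / DAYS_PER_YEAR
    pers = config.hazard_persistence_days

    for pid in range(config.n_persons):
        rng = np.random.default_rng([config.seed, pid])

        # --- static attributes (draw order is part of the contract) -------
        by0, by1 = config.birth_year_range
        birth_year = int(rng.integers(by0, by1 + 1))
        birth = _days_from_year(birth_year) + float(rng.integers(0, 365))
        sex = "M" if rng.random() < 0.473 else "F"
        ethnicity = _choice(rng, ETHNICITY_LEVELS, ETHNICITY_PROBS)
        smoking = _choice(rng, SMOKING_LEVELS, SMOKING_PROBS)
        townsend = float(rng.normal(-1.6, 2.9))
        bmi = float(rng.lognormal(math.log(27.0), 0.15))
        alcohol = float(rng.gamma(1.2, 1.8))
        education = _choice(rng, EDUCATION_LEVELS, EDUCATION_PROBS)
        fibre = float(max(rng.normal(13.7, 5.6), 0.0))
        processed_meat = float(rng.gamma(1.5, 1.2))
        red_meat = float(rng.gamma(2.0, 1.0))
        pgs = float(rng.normal())
        multimorbidity = float(rng.normal(0.0, 0.35))
        screening_eligible = int(rng.random() < 0.647)
        fh_bowel = int(rng.random() < 0.108)
        fh_breast = int(rng.random() < 0.101)
        fh_lung = int(rng.random() < 0.123)
        bl0, bl1 = config.baseline_year_range
        baseline = (_days_from_year(int(rng.integers(bl0, bl1 + 1)))
                    + float(rng.integers(0, 365)))

        miss = config.missing_rates
        smoking_out: object = smoking
        ethnicity_out: object = ethnicity
        alcohol_out: object = alcohol
        if rng.random() < miss.get("smoking", 0.0):
            smoking_out = np.nan
        if rng.random() < miss.get("ethnicity", 0.0):
            ethnicity_out = np.nan
        if rng.random() < miss.get("alcohol", 0.0):
            alcohol_out = np.nan

        # --- primary-care coverage ---------------------------------------
        ra0, ra1 = config.registration_age_range
        reg_start = birth + rng.uniform(ra0, ra1) * DAYS_PER_YEAR
        pe0, pe1 = config.pc_end_year_range
        pc_end = _days_from_year(int(rng.integers(pe0, pe1 + 1))) + float(rng.integers(0, 365))
        pc_end = max(pc_end, reg_start + DAYS_PER_YEAR)
        span_years = (pc_end - reg_start) / DAYS_PER_YEAR
        n_gaps = int(rng.poisson(config.coverage_gap_rate * span_years))
        gap_start = np.sort(reg_start + rng.random(n_gaps) * (pc_end - reg_start))
        gap_len = rng.exponential(config.coverage_gap_mean_days, n_gaps)
        intervals = []
        cursor = reg_start
        for gs, gl in zip(gap_start, gap_len):
            ge = min(gs + gl, pc_end)
            if gs > cursor:
                intervals.append((cursor, gs))
            cursor = max(cursor, ge)
        if pc_end > cursor:
            intervals.append((cursor, pc_end))

        # --- clinical events & blood tests --------------------------------
        age_end = (linkage_days - birth) / DAYS_PER_YEAR
        code_idx, ev_ages = _banded_event_times(
            rng, ev_rates, ev_slopes, config.event_start_age, age_end)
        fam_idx, bt_ages = _banded_event_times(
            rng, bt_rates, bt_slopes, config.event_start_age, age_end)
        abn = rng.random(len(bt_ages)) < bt_pabn[fam_idx]

        # --- competing terminal processes ---------------------------------
        t0 = birth + config.sim_start_age * DAYS_PER_YEAR
        death_t = (t0 + rng.exponential(DAYS_PER_YEAR / config.death_rate)
                   if config.death_rate > 0 else np.inf)
        other_t = (t0 + rng.exponential(DAYS_PER_YEAR / config.other_cancer_rate)
                   if config.other_cancer_rate > 0 else np.inf)

        # --- CRC: piecewise-constant proportional hazard -------------------
        static_state = {"pgs": pgs, "bmi": bmi, "townsend": townsend,
                        "multimorbidity_score": multimorbidity}
        static_lp = sum(config.true_log_hrs[k] * static_state[k] for k in static_terms)

        exposures = {}  # name -> list of (on, off) in absolute days
        for name in event_terms:
            ci = event_codes.index(name)
            onsets = birth + ev_ages[code_idx == ci]
            exposures[name] = _exposure_intervals(onsets, pers)
        for name in test_terms:
            fi = fam_names.index(_TEST_HAZARD_STATES[name])
            onsets = birth + bt_ages[(fam_idx == fi) & abn]
            exposures[name] = _exposure_intervals(onsets, pers)

        breakpoints = [t for ivs in exposures.values() for iv in ivs
                       for t in iv if np.isfinite(t)]
        horizon = min(death_t, other_t, linkage_days)
        if config.crc_hazard_age_slope != 0.0:
            yrs = np.arange(math.ceil((t0 - birth) / DAYS_PER_YEAR),
                            math.ceil((horizon - birth) / DAYS_PER_YEAR))
            breakpoints.extend((birth + yrs * DAYS_PER_YEAR).tolist())

        def crc_hazard(t: float) -> float:
            lp = static_lp
            for name, ivs in exposures.items():
                for on, off in ivs:
                    if on <= t < off:
                        lp += config.true_log_hrs[name]
                        break
            age = (t - birth) / DAYS_PER_YEAR
            base = h0_daily * math.exp(config.crc_hazard_age_slope * (age - 60.0))
            return base * math.exp(lp)

        crc_t = _piecewise_event_time(rng, t0, horizon, breakpoints, crc_hazard)

        nmsc_times = []
        if config.nmsc_rate > 0:
            t = t0
            nm_end = min(death_t, linkage_days)
            while True:
                t = t + rng.exponential(DAYS_PER_YEAR / config.nmsc_rate)
                if t >= nm_end:
                    break
                nmsc_times.append(t)

        # --- resolve registry ---------------------------------------------
        first_cancer = min(crc_t, other_t)
        end_of_record = min(death_t, linkage_days)
        if first_cancer <= end_of_record and np.isfinite(first_cancer):
            reg_pid.append(pid)
            reg_date.append(first_cancer)
            reg_type.append("crc" if crc_t <= other_t else "other_cancer")
        for t in nmsc_times:
            reg_pid.append(pid)
            reg_date.append(t)
            reg_type.append("nmsc")
        if death_t <= linkage_days:
            reg_pid.append(pid)
            reg_date.append(death_t)
            reg_type.append("death")

        # events/tests only while the person is alive and linked
        keep_until = min(death_t, linkage_days)
        ev_abs = birth + ev_ages
        mask = ev_abs <= keep_until
        ev_pid.extend([pid] * int(mask.sum()))
        ev_date.extend(ev_abs[mask].tolist())
        ev_code.extend([event_codes[i] for i in code_idx[mask]])
        bt_abs = birth + bt_ages
        mask = bt_abs <= keep_until
        bt_pid.extend([pid] * int(mask.sum()))
        bt_date.extend(bt_abs[mask].tolist())
        bt_fam.extend([fam_names[i] for i in fam_idx[mask]])
        bt_abn.extend(abn[mask].astype(int).tolist())

        for s, e in intervals:
            e = min(e, keep_until)
            if e > s:
                cov_pid.append(pid)
                cov_start.append(s)
                cov_end.append(e)
        lk_pid.append(pid)
        lk_end.append(min(pc_end, keep_until))

        persons_rows.append((pid, sex, birth, baseline, ethnicity_out, smoking_out,
                             townsend, bmi, alcohol_out, education, fibre,
                             processed_meat, red_meat, pgs, multimorbidity,
                             screening_eligible, fh_bowel, fh_breast, fh_lung))

    persons = pd.DataFrame(persons_rows, columns=[
        "person_id", "sex", "birth_date", "baseline_date", "ethnicity", "smoking",
        "townsend", "bmi", "alcohol", "education", "fibre", "processed_meat",
        "red_meat", "pgs", "multimorbidity_score", "screening_eligible",
        "family_history_bowel", "family_history_breast", "family_history_lung"])
    persons["birth_date"] = _date_from_days(persons["birth_date"])
    persons["baseline_date"] = _date_from_days(persons["baseline_date"])

    coverage = pd.DataFrame({"person_id": cov_pid,
                             "start_date": _date_from_days(cov_start),
                             "end_date": _date_from_days(cov_end)})
    clinical_events = pd.DataFrame({"person_id": ev_pid,
                                    "date": _date_from_days(ev_date),
                                    "code": ev_code})
    blood_tests = pd.DataFrame({"person_id": bt_pid,
                                "date": _date_from_days(bt_date),
                                "test_family": bt_fam,
                                "abnormal": bt_abn})
    registry = pd.DataFrame({"person_id": reg_pid,
                             "date": _date_from_days(reg_date),
                             "event_type": reg_type})
    linkage_end = pd.DataFrame({"person_id": lk_pid,
                                "pc_end_date": _date_from_days(lk_end)})

    for df in (clinical_events, blood_tests, registry):
        df.sort_values(["person_id", "date"], inplace=True, kind="mergesort")
        df.reset_index(drop=True, inplace=True)
    coverage.sort_values(["person_id", "start_date"], inplace=True, kind="mergesort")
    coverage.reset_index(drop=True, inplace=True)

    return RawCohort(persons=persons, coverage=coverage,
                     clinical_events=clinical_events, blood_tests=blood_tests,
                     registry=registry, linkage_end=linkage_end)
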