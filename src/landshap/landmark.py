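"""Super-landmark dataset construction.

The cohort is restructured into landmark-age datasets: at each landmark age
(40, 41, ..., 74 by default) a person enters on the first day of the month
in which they reach that age (the *index date*) if they are alive, have at
least 6 months (183 days) of continuous primary-care coverage — runs with
no gap longer than 90 days — inside the preceding two years, and have no
prior cancer diagnosis other than non-melanoma skin cancer (NMSC).
Follow-up from each index date runs to the earliest of: CRC diagnosis (the
event), any other non-NMSC cancer, death, two years after the end of
primary-care availability, or two years (730 days) after the index date.
The per-age datasets are stacked into one "super-landmark" dataset in which
a person may appear once per eligible age.

Conventions (degenerate cases the source rules leave open):

* a gap of exactly ``max_gap_days`` days does **not** break continuity;
* run length is counted inclusively (start and end days both covered);
* the predictor lookback window is half-open, ``[index - L, index)``;
* leap-day birthdays anniversary on 1 March;
* "most recent" coverage run = the run with the latest end date among runs
  intersecting the two-year lookback window;
* a CRC diagnosis dated exactly on the index date counts as an outcome
  event at time 1 day, not as a prior cancer.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort_sim import RawCohort

DEFAULT_AGES = tuple(range(40, 75))
LOOKBACK_DAYS = 730
MIN_COVERAGE_DAYS = 183  # "6 months of continuous records"
MAX_GAP_DAYS = 90
HORIZON_DAYS = 730

CENSOR_REASONS = ("crc", "other_cancer", "death", "pc_end_plus_2y", "admin_730")


@dataclass
class CoverageRun:
    person_id: int
    start_date: pd.Timestamp
    end_date: pd.Timestamp


@dataclass
class SuperLandmarkDataset:
    """Stacked landmark rows, one per (person, landmark age)."""

    rows: pd.DataFrame
    ages_included: tuple = field(default_factory=tuple)

    def __len__(self) -> int:
        return len(self.rows)

    def write(self, path) -> None:
        self.rows.to_csv(path, index=False, date_format="%Y-%m-%d")


# --------------------------------------------------------------------------
# elementary operations

def coverage_runs(intervals, max_gap_days: int = MAX_GAP_DAYS):
    """Merge raw coverage intervals into continuous runs.

    Two consecutive intervals belong to the same run when the gap between
    the end of one and the start of the next is at most ``max_gap_days``
    (a gap of exactly ``max_gap_days`` does not break continuity).
    Returns ``[(start, end), ...]`` sorted by start.
    """
    ivs = [(pd.Timestamp(s), pd.Timestamp(e)) for s, e in intervals]
    for s, e in ivs:
        if e < s:
            raise ValueError(f"coverage interval with end < start: ({s}, {e})")
    if not ivs:
        return []
    ivs.sort()
    runs = [list(ivs[0])]
    for s, e in ivs[1:]:
        if (s - runs[-1][1]).days <= max_gap_days:
            runs[-1][1] = max(runs[-1][1], e)
        else:
            runs.append([s, e])
    return [tuple(r) for r in runs]


def index_date(birth_date, landmark_age: int) -> pd.Timestamp:
    """First day of the month in which ``birth_date + landmark_age`` years falls.

    Leap-day birthdays anniversary on 1 March in non-leap years.
    """
    if not 40 <= landmark_age <= 74:
        raise ValueError("landmark_age must be in 40..74")
    b = pd.Timestamp(birth_date)
    year = b.year + landmark_age
    month, day = b.month, b.day
    if month == 2 and day == 29 and not _is_leap(year):
        month = 3
    return pd.Timestamp(year=year, month=month, day=1)


def _is_leap(year: int) -> bool:
    return year % 4 == 0 and (year % 100 != 0 or year % 400 == 0)


def _index_dates_vec(birth_dates: pd.Series, landmark_age: int) -> pd.Series:
    """Vectorised :func:`index_date` over a birth-date series."""
    y = birth_dates.dt.year + landmark_age
    m = birth_dates.dt.month.to_numpy().copy()
    leap_roll = (m == 2) & (birth_dates.dt.day.to_numpy() == 29) & \
        ~((y % 4 == 0) & ((y % 100 != 0) | (y % 400 == 0))).to_numpy()
    m[leap_roll] = 3
    return pd.to_datetime({"year": y, "month": m, "day": np.ones(len(y), dtype=int)})


# --------------------------------------------------------------------------
# per-person views used by eligibility and outcomes

def _person_summaries(cohort: RawCohort) -> pd.DataFrame:
    """Per-person first-cancer / death / pc-end summary."""
    reg = cohort.registry
    non_nmsc = reg[reg.event_type.isin(["crc", "other_cancer"])]
    first_cancer = non_nmsc.groupby("person_id")["date"].min()
    first_crc = reg[reg.event_type == "crc"].groupby("person_id")["date"].min()
    first_other = reg[reg.event_type == "other_cancer"].groupby("person_id")["date"].min()
    death = reg[reg.event_type == "death"].groupby("person_id")["date"].min()
    out = cohort.persons[["person_id", "birth_date"]].copy()
    out = out.merge(cohort.linkage_end, on="person_id", how="left")
    out["first_cancer"] = out.person_id.map(first_cancer)
    out["first_crc"] = out.person_id.map(first_crc)
    out["first_other"] = out.person_id.map(first_other)
    out["death"] = out.person_id.map(death)
    return out


def _merged_runs_frame(cohort: RawCohort, max_gap_days: int) -> pd.DataFrame:
    """All persons' merged coverage runs as a flat frame (vectorised)."""
    cov = cohort.coverage.sort_values(["person_id", "start_date"], kind="mergesort")
    if cov.empty:
        return pd.DataFrame(columns=["person_id", "run_start", "run_end"])
    if (cov.end_date < cov.start_date).any():
        raise ValueError("coverage interval with end < start")
    prev_end = cov.groupby("person_id")["end_date"].cummax().groupby(
        cov.person_id).shift()
    new_run = ((cov.start_date - prev_end).dt.days > max_gap_days) | prev_end.isna()
    run_id = new_run.cumsum()
    runs = cov.groupby(run_id).agg(person_id=("person_id", "first"),
                                   run_start=("start_date", "min"),
                                   run_end=("end_date", "max"))
    return runs.reset_index(drop=True)


def is_eligible(person_id: int, landmark_age: int, cohort: RawCohort,
                max_gap_days: int = MAX_GAP_DAYS,
                min_coverage_days: int = MIN_COVERAGE_DAYS,
                require_coverage_to_index: bool = False):
    """Eligibility of one person at one landmark age.

    Returns ``(flag, reason)`` where reason is the first failed criterion
    among ``alive``, ``coverage``, ``prior_cancer`` (or ``"eligible"``).
    """
    persons = cohort.persons
    if person_id not in set(persons.person_id):
        raise KeyError(f"person_id {person_id!r} not in cohort")
    summ = _person_summaries(cohort)
    row = summ[summ.person_id == person_id].iloc[0]
    idx = index_date(row.birth_date, landmark_age)
    if pd.notna(row.death) and row.death < idx:
        return False, "alive"
    runs = coverage_runs(
        cohort.coverage[cohort.coverage.person_id == person_id]
        [["start_date", "end_date"]].itertuples(index=False, name=None),
        max_gap_days)
    if not _coverage_ok(runs, idx, min_coverage_days, require_coverage_to_index):
        return False, "coverage"
    if pd.notna(row.first_cancer) and row.first_cancer < idx:
        return False, "prior_cancer"
    return True, "eligible"


def _coverage_ok(runs, idx, min_coverage_days, require_coverage_to_index):
    win_lo = idx - pd.Timedelta(days=LOOKBACK_DAYS)
    win_hi = idx - pd.Timedelta(days=1)  # window is [idx-730, idx)
    best = None
    for s, e in runs:
        if e >= win_lo and s <= win_hi:
            if best is None or e > best[1]:
                best = (s, e)
    if best is None:
        return False
    s, e = best
    covered = (min(e, win_hi) - max(s, win_lo)).days + 1
    if covered < min_coverage_days:
        return False
    if require_coverage_to_index and e < win_hi:
        return False
    return True


def outcome_at(person_id: int, idx, cohort: RawCohort):
    """Outcome tuple ``(event, time_days, censor_reason)`` for one index date."""
    summ = _person_summaries(cohort)
    row = summ[summ.person_id == person_id].iloc[0]
    return _resolve_outcome(pd.Timestamp(idx), row.first_crc, row.first_other,
                            row.death, row.pc_end_date)


def _resolve_outcome(idx, first_crc, first_other, death, pc_end):
    cands = []
    if pd.notna(first_crc) and first_crc >= idx:
        t = max((first_crc - idx).days, 1)  # same-day CRC counts at day 1
        cands.append((t, 0, 1, "crc"))
    if pd.notna(first_other) and first_other >= idx:
        t = max((first_other - idx).days, 1)
        cands.append((t, 1, 0, "other_cancer"))
    if pd.notna(death) and death >= idx:
        cands.append((max((death - idx).days, 1), 2, 0, "death"))
    if pd.notna(pc_end):
        cands.append((max((pc_end - idx).days + HORIZON_DAYS, 1), 3, 0, "pc_end_plus_2y"))
    cands.append((HORIZON_DAYS, 4, 0, "admin_730"))
    cands = [c for c in cands if c[0] <= HORIZON_DAYS] or [(HORIZON_DAYS, 4, 0, "admin_730")]
    t, _prio, event, reason = min(cands)
    return event, t, reason


# --------------------------------------------------------------------------
# stacked construction (vectorised)

def build_super_landmark(cohort: RawCohort, ages=DEFAULT_AGES,
                         max_gap_days: int = MAX_GAP_DAYS,
                         min_coverage_days: int = MIN_COVERAGE_DAYS,
                         require_coverage_to_index: bool = False,
                         codebook=None,
                         missing_policy: str = "drop") -> SuperLandmarkDataset:
    """Build the stacked super-landmark dataset.

    One row per (eligible person, landmark age) with index date, outcome and
    — when ``codebook`` is not ``None`` (default: the standard codebook) —
    the derived predictor columns, after applying the missing-data policy
    (``"drop"`` = complete case except smoking/ethnicity, ``"keep"`` = no
    filtering).
    """
    if cohort.persons.empty:
        raise ValueError("empty cohort")
    ages = tuple(ages)
    summ = _person_summaries(cohort)
    runs = _merged_runs_frame(cohort, max_gap_days)

    pieces = []
    for age in ages:
        idx = _index_dates_vec(summ.birth_date, age)
        cand = pd.DataFrame({"person_id": summ.person_id, "landmark_age": age,
                             "index_date": idx.to_numpy(),
                             "first_crc": summ.first_crc.to_numpy(),
                             "first_other": summ.first_other.to_numpy(),
                             "death": summ.death.to_numpy(),
                             "pc_end_date": summ.pc_end_date.to_numpy(),
                             "first_cancer": summ.first_cancer.to_numpy()})
        alive = cand.death.isna() | (cand.death >= cand.index_date)
        no_prior = cand.first_cancer.isna() | (cand.first_cancer >= cand.index_date)
        cand = cand[alive & no_prior]
        if cand.empty:
            continue
        # coverage: most recent run intersecting [index-730, index)
        m = cand[["person_id", "index_date"]].merge(runs, on="person_id", how="inner")
        win_lo = m.index_date - pd.Timedelta(days=LOOKBACK_DAYS)
        win_hi = m.index_date - pd.Timedelta(days=1)
        m = m[(m.run_end >= win_lo) & (m.run_start <= win_hi)]
        if m.empty:
            continue
        m = m.sort_values("run_end", kind="mergesort").groupby("person_id").tail(1)
        win_lo = m.index_date - pd.Timedelta(days=LOOKBACK_DAYS)
        win_hi = m.index_date - pd.Timedelta(days=1)
        covered = ((np.minimum(m.run_end, win_hi) - np.maximum(m.run_start, win_lo))
                   .dt.days + 1)
        ok = covered >= min_coverage_days
        if require_coverage_to_index:
            ok &= m.run_end >= win_hi
        eligible_ids = m.loc[ok, "person_id"]
        cand = cand[cand.person_id.isin(set(eligible_ids))]
        if cand.empty:
            continue
        pieces.append(cand.drop(columns=["first_cancer"]))

    if not pieces:
        return SuperLandmarkDataset(rows=_empty_rows(), ages_included=ages)
    rows = pd.concat(pieces, ignore_index=True)

    # outcomes, vectorised over rows
    day = pd.Timedelta(days=1)
    t_crc = (rows.first_crc - rows.index_date) / day
    t_crc = np.where(rows.first_crc.notna() & (t_crc >= 0), np.maximum(t_crc, 1), np.inf)
    t_oth = (rows.first_other - rows.index_date) / day
    t_oth = np.where(rows.first_other.notna() & (t_oth >= 0), np.maximum(t_oth, 1), np.inf)
    t_dth = (rows.death - rows.index_date) / day
    t_dth = np.where(rows.death.notna() & (t_dth >= 0), np.maximum(t_dth, 1), np.inf)
    t_pc = (rows.pc_end_date - rows.index_date) / day + HORIZON_DAYS
    t_pc = np.where(rows.pc_end_date.notna(), np.maximum(t_pc, 1), np.inf)
    t_adm = np.full(len(rows), float(HORIZON_DAYS))

    times = np.column_stack([t_crc, t_oth, t_dth, t_pc, t_adm])
    which = np.argmin(times, axis=1)  # argmin ties resolve in priority order
    tmin = times[np.arange(len(rows)), which]
    over = tmin > HORIZON_DAYS
    which[over] = 4
    tmin[over] = HORIZON_DAYS

    out = rows[["person_id", "landmark_age", "index_date"]].copy()
    out["event"] = (which == 0).astype(int)
    out["time_days"] = tmin.astype(int)
    out["censor_reason"] = np.array(CENSOR_REASONS, dtype=object)[which]
    out = out.sort_values(["landmark_age", "person_id"], kind="mergesort").reset_index(drop=True)

    if codebook is not False:
        from .predictors import attach_predictors, apply_missing_policy_frame, default_codebook
        cb = codebook if codebook is not None else default_codebook()
        out = attach_predictors(out, cohort, cb)
        if missing_policy == "drop":
            out = apply_missing_policy_frame(out, cb)
    dup = out.duplicated(["person_id", "landmark_age"])
    if dup.any():
        raise AssertionError("duplicate (person_id, landmark_age) rows")
    return SuperLandmarkDataset(rows=out, ages_included=ages)


def _empty_rows() -> pd.DataFrame:
    return pd.DataFrame(columns=["person_id", "landmark_age", "index_date",
                                 "event", "time_days", "censor_reason"])
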