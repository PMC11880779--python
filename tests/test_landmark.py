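"""Landmark construction: coverage-run merging, index dates, eligibility,
outcome/censoring resolution, and stacking."""

import numpy as np
import pandas as pd
import pytest

from landshap.cohort_sim import RawCohort
from landshap.landmark import (build_super_landmark, coverage_runs, index_date,
                               is_eligible, outcome_at)

from conftest import make_cohort, full_coverage


class TestCoverageRuns:
    def test_empty_input(self):
        assert coverage_runs([]) == []

    def test_gap_of_exactly_90_days_does_not_break_continuity(self):
        runs = coverage_runs([("2010-01-01", "2010-03-01"),
                              ("2010-05-30", "2010-12-01")])
        assert runs == [(pd.Timestamp("2010-01-01"), pd.Timestamp("2010-12-01"))]

    def test_gap_of_91_days_breaks_continuity(self):
        # 2010-03-01 -> 2010-05-31 is 91 days
        runs = coverage_runs([("2010-01-01", "2010-03-01"),
                              ("2010-05-31", "2010-12-01")])
        assert len(runs) == 2

    def test_unordered_and_overlapping_intervals_merge(self):
        runs = coverage_runs([("2011-06-01", "2011-09-01"),
                              ("2010-01-01", "2010-06-01"),
                              ("2010-05-01", "2010-08-01")])
        assert runs == [(pd.Timestamp("2010-01-01"), pd.Timestamp("2010-08-01")),
                        (pd.Timestamp("2011-06-01"), pd.Timestamp("2011-09-01"))]

    def test_invalid_interval_raises(self):
        with pytest.raises(ValueError):
            coverage_runs([("2010-06-01", "2010-01-01")])


class TestIndexDate:
    @pytest.mark.parametrize("birth,age,expected", [
        ("1950-07-15", 60, "2010-07-01"),
        ("1950-07-01", 60, "2010-07-01"),
        ("1952-02-29", 41, "1993-03-01"),  # leap-day anniversary -> 1 March
        ("1952-02-29", 44, "1996-02-01"),  # leap target year: stays February
        ("1950-12-31", 40, "1990-12-01"),
    ])
    def test_first_of_anniversary_month(self, birth, age, expected):
        assert index_date(birth, age) == pd.Timestamp(expected)

    def test_age_out_of_range_raises(self):
        with pytest.raises(ValueError):
            index_date("1950-01-01", 39)

    def test_vectorised_matches_scalar(self):
        births = pd.Series(pd.to_datetime(
            ["1950-07-15", "1952-02-29", "1948-01-01", "1960-02-28"]))
        from landshap.landmark import _index_dates_vec
        for age in (40, 41, 55, 74):
            vec = _index_dates_vec(births, age)
            for b, v in zip(births, vec):
                assert index_date(b, age) == v


def person_with(registry=(), coverage=None, birth="1950-03-10"):
    cov = coverage if coverage is not None else full_coverage(0)
    return make_cohort([dict(person_id=0, birth_date=birth)],
                       coverage=cov, registry=registry)


class TestEligibility:
    def test_prior_nmsc_does_not_exclude(self):
        c = person_with(registry=[(0, "2000-05-01", "nmsc")])
        flag, reason = is_eligible(0, 55, c)
        assert flag and reason == "eligible"

    def test_prior_crc_excludes(self):
        c = person_with(registry=[(0, "2000-05-01", "crc")])
        flag, reason = is_eligible(0, 55, c)
        assert not flag and reason == "prior_cancer"

    def test_short_coverage_run_excludes(self):
        # 150 covered days inside the 2-year lookback window
        c = person_with(coverage=[(0, "2009-06-01", "2009-10-28")])
        flag, reason = is_eligible(0, 60, c)  # index 2010-03-01
        assert not flag and reason == "coverage"

    def test_exactly_183_day_run_is_sufficient(self):
        # 2009-06-01 .. 2009-11-30 inclusive = 183 days
        c = person_with(coverage=[(0, "2009-06-01", "2009-11-30")])
        flag, _ = is_eligible(0, 60, c)
        assert flag

    def test_dead_before_index_excludes(self):
        c = person_with(registry=[(0, "2004-01-01", "death")])
        flag, reason = is_eligible(0, 55, c)
        assert not flag and reason == "alive"

    def test_unknown_person_raises(self):
        with pytest.raises(KeyError):
            is_eligible(99, 55, person_with())


class TestOutcome:
    def test_crc_within_window_is_event(self):
        c = person_with(registry=[(0, "2011-04-05", "crc")])
        # index 2010-03-01; CRC at +400 days
        assert outcome_at(0, "2010-03-01", c) == (1, 400, "crc")

    def test_other_cancer_censors_before_crc(self):
        c = person_with(registry=[(0, "2010-12-26", "other_cancer"),
                                  (0, "2011-07-14", "crc")])
        assert outcome_at(0, "2010-03-01", c) == (0, 300, "other_cancer")

    def test_admin_censoring_at_730(self):
        c = person_with()
        assert outcome_at(0, "2010-03-01", c) == (0, 730, "admin_730")

    def test_pc_end_censoring(self):
        # records end 155 days before the index date: censored at
        # pc_end + 730 = index + 575
        c = make_cohort([dict(person_id=0, birth_date="1950-03-10")],
                        coverage=full_coverage(0),
                        linkage=[(0, "2009-09-27")])
        assert outcome_at(0, "2010-03-01", c) == (0, 575, "pc_end_plus_2y")

    def test_death_censors(self):
        c = person_with(registry=[(0, "2010-05-01", "death")])
        assert outcome_at(0, "2010-03-01", c) == (0, 61, "death")

    def test_same_day_crc_counts_as_event_at_day_one(self):
        c = person_with(registry=[(0, "2010-03-01", "crc")])
        assert outcome_at(0, "2010-03-01", c) == (1, 1, "crc")

    def test_nmsc_is_ignored_for_censoring(self):
        c = person_with(registry=[(0, "2010-06-01", "nmsc")])
        assert outcome_at(0, "2010-03-01", c) == (0, 730, "admin_730")


class TestBuildSuperLandmark:
    def test_coverage_window_limits_ages(self):
        # the run gives >=183 days inside the 2-year lookback only for
        # landmark ages 60..65 (age 59's window holds just 59 covered days;
        # age 66's window starts after the run ends)
        c = make_cohort([dict(person_id=0, birth_date="1950-03-10")],
                        coverage=[(0, "2009-01-01", "2013-12-31")],
                        linkage=[(0, "2013-12-31")])
        ds = build_super_landmark(c, ages=range(40, 75), codebook=False)
        assert sorted(ds.rows.landmark_age) == [60, 61, 62, 63, 64, 65]

    def test_crc_midway_gives_events_then_exclusion(self):
        # CRC at age 62.5 (1950-03-10 + 62.5y ~ 2012-09-08)
        c = make_cohort([dict(person_id=0, birth_date="1950-03-10")],
                        coverage=full_coverage(0),
                        registry=[(0, "2012-09-08", "crc")])
        ds = build_super_landmark(c, ages=range(58, 70), codebook=False)
        rows = ds.rows.set_index("landmark_age")
        assert sorted(rows.index) == [58, 59, 60, 61, 62]
        assert rows.loc[61, "event"] == 1 and rows.loc[62, "event"] == 1
        assert rows.loc[60, "event"] == 0  # CRC beyond 730d of 2010-03-01
        assert rows.loc[58, "censor_reason"] == "admin_730"

    def test_empty_ages_gives_empty_dataset(self):
        c = person_with()
        ds = build_super_landmark(c, ages=(), codebook=False)
        assert len(ds) == 0

    def test_empty_cohort_raises(self):
        c = person_with()
        c.persons = c.persons.iloc[0:0]
        with pytest.raises(ValueError):
            build_super_landmark(c, codebook=False)

    def test_rows_unique_and_consistent(self, small_sim_cohort):
        ds = build_super_landmark(small_sim_cohort, ages=range(55, 70),
                                  codebook=False)
        rows = ds.rows
        assert not rows.duplicated(["person_id", "landmark_age"]).any()
        assert ((rows.time_days > 0) & (rows.time_days <= 730)).all()
        assert ((rows.event == 1) == (rows.censor_reason == "crc")).all()
        assert rows.index_date.dt.day.eq(1).all()

    def test_no_row_after_death_or_prior_cancer(self, small_sim_cohort):
        ds = build_super_landmark(small_sim_cohort, ages=range(45, 75),
                                  codebook=False)
        reg = small_sim_cohort.registry
        death = reg[reg.event_type == "death"].set_index("person_id").date
        cancer = reg[reg.event_type.isin(["crc", "other_cancer"])] \
            .groupby("person_id").date.min()
        rows = ds.rows
        d = rows.person_id.map(death)
        assert not (d.notna() & (rows.index_date > d)).any()
        fc = rows.person_id.map(cancer)
        assert not (fc.notna() & (fc < rows.index_date)).any()

    def test_outcome_times_match_brute_force(self, small_sim_cohort):
        """Row time equals the independent minimum over the five censoring
        candidates recomputed directly from the raw tables."""
        ds = build_super_landmark(small_sim_cohort, ages=range(58, 64),
                                  codebook=False)
        reg = small_sim_cohort.registry
        lk = small_sim_cohort.linkage_end.set_index("person_id").pc_end_date
        for row in ds.rows.sample(min(len(ds.rows), 150), random_state=0).itertuples():
            r = reg[reg.person_id == row.person_id]
            cands = [(730, 0, "admin_730")]
            pc = lk.loc[row.person_id]
            cands.append((max((pc - row.index_date).days + 730, 1), 0,
                          "pc_end_plus_2y"))
            for typ, ev in (("crc", 1), ("other_cancer", 0), ("death", 0)):
                dates = r.loc[r.event_type == typ, "date"]
                dates = dates[dates >= row.index_date]
                if len(dates):
                    cands.append((max((dates.min() - row.index_date).days, 1),
                                  ev, typ))
            t, ev, _ = min((t, -e, reason) for t, e, reason in cands)
            assert row.time_days == min(t, 730)
            if t <= 730:
                assert row.event == -ev

    def test_removing_coverage_gaps_only_adds_rows(self, small_sim_cohort):
        ds = build_super_landmark(small_sim_cohort, ages=range(50, 70),
                                  codebook=False)
        cov = small_sim_cohort.coverage
        solid = cov.groupby("person_id").agg(start_date=("start_date", "min"),
                                             end_date=("end_date", "max")).reset_index()
        c2 = RawCohort(persons=small_sim_cohort.persons, coverage=solid,
                       clinical_events=small_sim_cohort.clinical_events,
                       blood_tests=small_sim_cohort.blood_tests,
                       registry=small_sim_cohort.registry,
                       linkage_end=small_sim_cohort.linkage_end)
        ds2 = build_super_landmark(c2, ages=range(50, 70), codebook=False)
        before = set(map(tuple, ds.rows[["person_id", "landmark_age"]].to_numpy()))
        after = set(map(tuple, ds2.rows[["person_id", "landmark_age"]].to_numpy()))
        assert before <= after
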