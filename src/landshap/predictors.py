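"""Predictor derivation at index dates.

Predictors are organised into six sets — core demographics, polygenic score
(PGS), presenting symptoms, medical history, common blood tests, and other
lifestyle factors — described declaratively by a :class:`PredictorCodebook`.
Event-sourced binaries are 1 iff at least one matching coded event falls in
the half-open lookback window ``[index - L, index)`` (``L = "ever"`` uses
the full prior history); baseline-sourced values are copied time-fixed from
the questionnaire table; blood tests contribute a measured/abnormal pair of
indicators per test family.

Missing-data policy: missing smoking status or ethnicity becomes an
explicit ``"Missing"`` category; any other missing baseline value drops the
row (complete-case).  Event-sourced predictors are never missing — absence
of a code means 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort_sim import RawCohort

SET_NAMES = ("core", "pgs", "symptoms", "medical_history", "blood_tests", "lifestyle")

SYMPTOM_LOOKBACK = 730
COLONOSCOPY_LOOKBACK = 3650  # "in last 10 years"


@dataclass(frozen=True)
class CodebookEntry:
    name: str
    set_name: str            # one of SET_NAMES
    source: str              # baseline | events | tests | derived
    lookback_days: object = None   # int days, "ever", or None for baseline/derived
    encoding: str = "binary"       # binary | continuous | categorical
    levels: tuple = ()             # categorical levels, first = reference
    code: str = None               # event code (events source)
    family: str = None             # test family (tests source)
    flavour: str = None            # "measured"/"abnormal" for tests source


@dataclass
class PredictorCodebook:
    entries: list

    def __post_init__(self):
        names = [e.name for e in self.entries]
        if len(names) != len(set(names)):
            raise ValueError("duplicate predictor names in codebook")

    def names(self, set_name: str | None = None) -> list:
        return [e.name for e in self.entries
                if set_name is None or e.set_name == set_name]

    def entry(self, name: str) -> CodebookEntry:
        for e in self.entries:
            if e.name == name:
                return e
        raise KeyError(name)

    def set_map(self) -> dict:
        """Mapping set name -> list of predictor names."""
        return {s: self.names(s) for s in SET_NAMES}


def default_codebook() -> PredictorCodebook:
    """Standard codebook: 8 core + 1 PGS + 16 symptoms + 12 history + 4 bloods
    + 5 lifestyle predictors.

    Five symptom names and one history name are configurable placeholders
    kept so that set sizes match the usual candidate counts; override the
    codebook to rename or re-source them.
    """
    E = CodebookEntry
    entries = [
        # core (8)
        E("age_at_index", "core", "derived", encoding="continuous"),
        E("sex", "core", "baseline", encoding="categorical", levels=("F", "M")),
        E("birth_year", "core", "derived", encoding="continuous"),
        E("bmi", "core", "baseline", encoding="continuous"),
        E("ethnicity", "core", "baseline", encoding="categorical",
          levels=("White", "SE Asian", "Black", "Mixed", "Other", "Missing")),
        E("smoking", "core", "baseline", encoding="categorical",
          levels=("Never", "Current", "Former", "Missing")),
        E("townsend", "core", "baseline", encoding="continuous"),
        E("baseline_age", "core", "derived", encoding="continuous"),
        # polygenic score
        E("pgs", "pgs", "baseline", encoding="continuous"),
        # symptoms (16), two-year window
        *[E(name, "symptoms", "events", SYMPTOM_LOOKBACK, code=code)
          for name, code in [
              ("abdominal_bloating", "abdominal_bloating"),
              ("abdominal_pain", "abdominal_pain"),
              ("change_in_bowel_habits", "change_in_bowel_habits"),
              ("constipation", "constipation"),
              ("diarrhoea", "diarrhoea"),
              ("diverticular_disease", "diverticular_disease"),
              ("fatigue", "fatigue"),
              ("haemorrhoids", "haemorrhoids"),
              ("ibs", "ibs"),
              ("rectal_bleed", "rectal_bleed"),
              ("stomach_disorders", "stomach_disorders"),
              ("symptom_extra_1", "symptom_extra_1"),
              ("symptom_extra_2", "symptom_extra_2"),
              ("symptom_extra_3", "symptom_extra_3"),
              ("symptom_extra_4", "symptom_extra_4"),
              ("symptom_extra_5", "symptom_extra_5"),
          ]],
        # medical history (12)
        E("colonoscopy_10y", "medical_history", "events", COLONOSCOPY_LOOKBACK,
          code="colonoscopy"),
        E("aspirin", "medical_history", "events", 730, code="aspirin"),
        E("nsaids", "medical_history", "events", 730, code="nsaids"),
        E("diabetes_t2_ever", "medical_history", "events", "ever", code="diabetes_t2"),
        E("gallbladder_ever", "medical_history", "events", "ever", code="gallbladder"),
        E("ibd_ever", "medical_history", "events", "ever", code="ibd"),
        E("family_history_bowel", "medical_history", "baseline"),
        E("family_history_breast", "medical_history", "baseline"),
        E("family_history_lung", "medical_history", "baseline"),
        E("screening_eligible", "medical_history", "baseline"),
        E("multimorbidity_score", "medical_history", "baseline", encoding="continuous"),
        E("history_extra_1", "medical_history", "events", 730, code="history_extra_1"),
        # blood tests (4): measured/abnormal per family, two-year window
        E("inflammation_measured", "blood_tests", "tests", 730,
          family="inflammation", flavour="measured"),
        E("inflammation_abnormal", "blood_tests", "tests", 730,
          family="inflammation", flavour="abnormal"),
        E("iron_measured", "blood_tests", "tests", 730,
          family="iron", flavour="measured"),
        E("iron_abnormal", "blood_tests", "tests", 730,
          family="iron", flavour="abnormal"),
        # lifestyle (5)
        E("alcohol", "lifestyle", "baseline", encoding="continuous"),
        E("education", "lifestyle", "baseline", encoding="categorical",
          levels=("Higher Education", "A-level", "GCSE", "CSE",
                  "Vocational", "Professional", "None")),
        E("fibre", "lifestyle", "baseline", encoding="continuous"),
        E("processed_meat", "lifestyle", "baseline", encoding="continuous"),
        E("red_meat", "lifestyle", "baseline", encoding="continuous"),
    ]
    return PredictorCodebook(entries)


def ever_codebook(names_and_codes) -> PredictorCodebook:
    """Small codebook of 'ever' event binaries plus pgs; used for scenarios
    with permanently elevated hazards."""
    entries = [CodebookEntry("pgs", "pgs", "baseline", encoding="continuous")]
    for name, source, key in names_and_codes:
        if source == "events":
            entries.append(CodebookEntry(name, "symptoms", "events", "ever", code=key))
        else:
            entries.append(CodebookEntry(name, "blood_tests", "tests", "ever",
                                         family=key, flavour="abnormal"))
    return PredictorCodebook(entries)


@dataclass
class PredictorVector:
    values: dict
    missing_flags: dict
    drop: bool = False


# --------------------------------------------------------------------------
# bulk derivation

def _window_indicator(rows: pd.DataFrame, events: pd.DataFrame,
                      lookback) -> pd.Series:
    """1 iff >=1 event in [index - lookback, index) per (person, landmark_age)."""
    key = ["person_id", "landmark_age"]
    out = pd.Series(0, index=pd.MultiIndex.from_frame(rows[key]), dtype=np.int8)
    if events.empty:
        return out
    m = rows[key + ["index_date"]].merge(events, on="person_id", how="inner")
    in_win = m.date < m.index_date
    if lookback != "ever":
        in_win &= m.date >= m.index_date - pd.Timedelta(days=int(lookback))
    hits = m.loc[in_win, key].drop_duplicates()
    out.loc[pd.MultiIndex.from_frame(hits)] = 1
    return out


def attach_predictors(rows: pd.DataFrame, cohort: RawCohort,
                      codebook: PredictorCodebook) -> pd.DataFrame:
    """Derive every codebook predictor for each (person, landmark age) row."""
    out = rows.copy()
    persons = cohort.persons.set_index("person_id")
    events = cohort.clinical_events
    tests = cohort.blood_tests
    known_codes = {e.code for e in codebook.entries if e.source == "events"}
    unknown = sorted(set(events.code.unique()) - known_codes)
    if unknown:
        warnings.warn(f"ignoring event codes with no codebook entry: {unknown}")

    for e in codebook.entries:
        if e.source == "baseline":
            out[e.name] = out.person_id.map(persons[e.name])
        elif e.source == "derived":
            if e.name == "age_at_index":
                out[e.name] = out.landmark_age.astype(float)
            elif e.name == "birth_year":
                out[e.name] = out.person_id.map(persons.birth_date.dt.year).astype(float)
            elif e.name == "baseline_age":
                ages = ((persons.baseline_date - persons.birth_date).dt.days / 365.25)
                out[e.name] = out.person_id.map(ages)
            else:
                raise ValueError(f"unknown derived predictor {e.name!r}")
        elif e.source == "events":
            ev = events[events.code == e.code]
            ind = _window_indicator(out, ev[["person_id", "date"]], e.lookback_days)
            out[e.name] = ind.to_numpy()
        elif e.source == "tests":
            fam = tests[tests.test_family == e.family]
            if e.flavour == "abnormal":
                fam = fam[fam.abnormal.astype(bool)]
            ind = _window_indicator(out, fam[["person_id", "date"]], e.lookback_days)
            out[e.name] = ind.to_numpy()
        else:
            raise ValueError(f"unknown source {e.source!r}")
    return out


def derive_vector(person_id: int, index_dt, codebook: PredictorCodebook,
                  cohort: RawCohort, landmark_age: int | None = None) -> PredictorVector:
    """Predictor vector for one person at one index date (pure function)."""
    idx = pd.Timestamp(index_dt)
    if landmark_age is None:
        birth = cohort.persons.set_index("person_id").birth_date.loc[person_id]
        landmark_age = int((idx - birth).days // 365.25)
    row = pd.DataFrame({"person_id": [person_id], "landmark_age": [landmark_age],
                        "index_date": [idx]})
    derived = attach_predictors(row, cohort, codebook).iloc[0]
    values = {e.name: derived[e.name] for e in codebook.entries}
    missing = {k: (pd.isna(v)) for k, v in values.items()}
    return PredictorVector(values=values, missing_flags=missing)


def blood_test_indicators(tests: pd.DataFrame, index_dt,
                          lookback_days: int = 730) -> tuple:
    """(inflammation_measured, inflammation_abnormal, iron_measured,
    iron_abnormal) for one person's test table at one index date."""
    idx = pd.Timestamp(index_dt)
    lo = idx - pd.Timedelta(days=lookback_days)
    if (tests.abnormal.notna() & tests.test_family.isna()).any():
        raise ValueError("abnormal flag without test family label")
    win = tests[(tests.date >= lo) & (tests.date < idx)]
    out = []
    for fam in ("inflammation", "iron"):
        f = win[win.test_family == fam]
        out.append(int(len(f) > 0))
        out.append(int(f.abnormal.astype(bool).any()))
    return tuple(out)


# --------------------------------------------------------------------------
# missing-data policy

CATEGORY_MISSING_OK = ("smoking", "ethnicity")


def apply_missing_policy(vector: PredictorVector,
                         codebook: PredictorCodebook) -> PredictorVector:
    """Missing smoking/ethnicity -> level "Missing"; any other missing
    baseline value marks the vector for complete-case dropping."""
    values = dict(vector.values)
    flags = dict(vector.missing_flags)
    drop = False
    for e in codebook.entries:
        if not flags.get(e.name, False):
            continue
        if e.name in CATEGORY_MISSING_OK:
            values[e.name] = "Missing"
            flags[e.name] = False
        elif e.source in ("baseline", "derived"):
            drop = True
    return PredictorVector(values=values, missing_flags=flags, drop=drop)


def apply_missing_policy_frame(df: pd.DataFrame,
                               codebook: PredictorCodebook) -> pd.DataFrame:
    """Frame-level missing policy (same rules as :func:`apply_missing_policy`)."""
    out = df.copy()
    drop_mask = np.zeros(len(out), dtype=bool)
    for e in codebook.entries:
        if e.name not in out.columns:
            continue
        na = out[e.name].isna()
        if not na.any():
            continue
        if e.name in CATEGORY_MISSING_OK:
            out[e.name] = out[e.name].where(~na, "Missing")
        elif e.source in ("baseline", "derived"):
            drop_mask |= na.to_numpy()
    return out[~drop_mask].reset_index(drop=True)


# --------------------------------------------------------------------------
# design encoding

def encode_design(df: pd.DataFrame, codebook: PredictorCodebook,
                  names=None) -> tuple[pd.DataFrame, dict]:
    """Numeric design columns for modelling.

    Categoricals become reference-coded 0/1 indicators (reference = first
    listed level).  Returns ``(frame_with_design_columns, mapping)`` where
    mapping sends each predictor name to its design column list.
    """
    names = list(names) if names is not None else codebook.names()
    out = df.copy()
    mapping = {}
    for name in names:
        e = codebook.entry(name)
        if e.encoding == "categorical":
            cols = []
            for level in e.levels[1:]:
                col = f"{name}__{_slug(level)}"
                out[col] = (df[name] == level).astype(float)
                cols.append(col)
            mapping[name] = cols
        else:
            out[name] = pd.to_numeric(df[name])
            mapping[name] = [name]
    return out, mapping


def _slug(level: str) -> str:
    return str(level).lower().replace(" ", "_").replace("-", "_")


def design_set_map(codebook: PredictorCodebook, mapping: dict) -> dict:
    """Set name -> design columns, via the encode_design mapping."""
    return {s: [c for n in names if n in mapping for c in mapping[n]]
            for s, names in codebook.set_map().items() if names}


# --------------------------------------------------------------------------
# symptomatic subcohort

def select_symptom_criteria(dataset: pd.DataFrame, codebook: PredictorCodebook,
                            duration_col: str = "time_days",
                            event_col: str = "event") -> list:
    """AIC-based bidirectional stepwise Cox selection over the 16 symptom
    binaries; returns the selected symptom names."""
    from .survival_model import stepwise_aic
    symptoms = codebook.names("symptoms")
    if dataset[event_col].sum() == 0:
        raise ValueError("no events in dataset")
    return stepwise_aic(dataset, symptoms, duration_col=duration_col,
                        event_col=event_col)


def symptomatic_subcohort(dataset: pd.DataFrame, criteria,
                          mode: str = "selected",
                          codebook: PredictorCodebook | None = None) -> pd.DataFrame:
    """Rows with at least one criterion symptom recorded in the window.

    ``mode="selected"`` uses ``criteria``; ``mode="any_except_fatigue"``
    uses every symptom in the codebook except fatigue.
    """
    if mode == "any_except_fatigue":
        cb = codebook if codebook is not None else default_codebook()
        criteria = [s for s in cb.names("symptoms") if s != "fatigue"]
    elif mode == "selected":
        criteria = list(criteria)
        if not criteria:
            raise ValueError("empty criteria in selected mode")
    else:
        raise ValueError(f"unknown mode {mode!r}")
    mask = dataset[criteria].astype(float).sum(axis=1) > 0
    if not mask.any():
        warnings.warn("symptomatic subcohort is empty")
    return dataset[mask].reset_index(drop=True)
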