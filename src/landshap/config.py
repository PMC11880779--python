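"""Simulation configuration.

:class:`SimConfig` holds every parameter of the synthetic-cohort generator:
demographic ranges, primary-care coverage behaviour, age-dependent clinical
event rates, blood-test rates, and the ground-truth proportional-hazards
model for the colorectal-cancer (CRC) outcome plus competing other-cancer
and death processes.

Event rates are per person-year on the log-linear age model

    rate(age) = rate * exp(slope * (age - 60))

so ``rate`` is the rate at age 60 and ``slope`` makes symptom and test
rates rise with age.  Defaults are order-of-magnitude choices that
reproduce typical two-year prevalences seen in UK primary-care cohorts
(e.g. new-onset constipation ~17% over two years); they are configuration,
not ground truth.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import yaml

# (rate/person-year at age 60, log-linear slope per year of age)
DEFAULT_EVENT_RATES: dict[str, tuple[float, float]] = {
    # symptoms
    "constipation": (0.092, 0.02),
    "diarrhoea": (0.083, 0.02),
    "abdominal_pain": (0.077, 0.01),
    "haemorrhoids": (0.054, 0.01),
    "fatigue": (0.045, 0.01),
    "rectal_bleed": (0.021, 0.02),
    "diverticular_disease": (0.021, 0.03),
    "stomach_disorders": (0.021, 0.01),
    "ibs": (0.013, 0.0),
    "change_in_bowel_habits": (0.012, 0.02),
    "abdominal_bloating": (0.010, 0.01),
    "symptom_extra_1": (0.010, 0.0),
    "symptom_extra_2": (0.010, 0.0),
    "symptom_extra_3": (0.010, 0.0),
    "symptom_extra_4": (0.010, 0.0),
    "symptom_extra_5": (0.010, 0.0),
    # medical history (event-sourced)
    "colonoscopy": (0.027, 0.02),
    "nsaids": (0.080, 0.01),
    "aspirin": (0.025, 0.03),
    "diabetes_t2": (0.0035, 0.02),
    "gallbladder": (0.0014, 0.01),
    "ibd": (0.0008, 0.0),
    "history_extra_1": (0.005, 0.0),
}

# family: (tests/person-year at age 60, slope, P(abnormal result))
DEFAULT_BLOOD_TEST_RATES: dict[str, tuple[float, float, float]] = {
    "inflammation": (0.94, 0.02, 0.15),
    "iron": (0.90, 0.02, 0.05),
}

# ground-truth log hazard ratios for the simulated CRC process
DEFAULT_TRUE_LOG_HRS: dict[str, float] = {
    "pgs": 0.3364722366212129,        # log 1.4 per SD
    "iron_abnormal": 1.3609765531356006,  # log 3.9
    "rectal_bleed": 0.9932517730102834,   # log 2.7
}


@dataclass
class SimConfig:
    """Parameters of the synthetic longitudinal cohort generator."""

    n_persons: int = 1000
    seed: int = 0
    birth_year_range: tuple[int, int] = (1935, 1970)
    baseline_year_range: tuple[int, int] = (2006, 2010)
    linkage_end_year: int = 2020
    pc_end_year_range: tuple[int, int] = (2015, 2018)
    registration_age_range: tuple[float, float] = (25.0, 40.0)
    coverage_gap_rate: float = 0.10          # gaps per person-year of registration
    coverage_gap_mean_days: float = 60.0     # exponential mean gap length
    event_rates: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_EVENT_RATES))
    blood_test_rates: dict[str, tuple[float, float, float]] = field(
        default_factory=lambda: dict(DEFAULT_BLOOD_TEST_RATES))
    true_log_hrs: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_TRUE_LOG_HRS))
    crc_baseline_hazard: float = 0.003       # events/person-year at covariates 0
    crc_hazard_age_slope: float = 0.0        # log-linear age slope on CRC baseline
    # None => an exposure, once acquired, elevates hazard permanently;
    # an integer D => the exposure state is "any onset in the last D days".
    hazard_persistence_days: int | None = 730
    other_cancer_rate: float = 0.010
    death_rate: float = 0.012
    nmsc_rate: float = 0.003
    missing_rates: dict[str, float] = field(
        default_factory=lambda: {"smoking": 0.003, "ethnicity": 0.003, "alcohol": 0.01})
    sim_start_age: float = 40.0              # cancer & death clocks start here
    event_start_age: float = 25.0            # clinical-event history starts here

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.n_persons < 1:
            raise ValueError("n_persons must be >= 1")
        for name, (rate, _slope) in self.event_rates.items():
            if rate < 0:
                raise ValueError(f"negative event rate for {name!r}")
        for fam, (rate, _slope, p) in self.blood_test_rates.items():
            if rate < 0 or not 0 <= p <= 1:
                raise ValueError(f"invalid blood-test parameters for {fam!r}")
        for val in (self.coverage_gap_rate, self.crc_baseline_hazard,
                    self.other_cancer_rate, self.death_rate, self.nmsc_rate):
            if val < 0:
                raise ValueError("rates must be >= 0")
        if self.pc_end_year_range[1] > self.linkage_end_year - 2:
            # registry must remain linked for the full 2-year horizon after the
            # end of primary-care availability, else outcomes are unobservable
            raise ValueError(
                "pc_end_year_range must end at least 2 years before linkage_end_year")

    # ----- serialization -------------------------------------------------

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(_plainify(self.to_dict()), fh, sort_keys=False)

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown SimConfig keys: {sorted(unknown)}")
        d = dict(d)
        for key in ("birth_year_range", "baseline_year_range",
                    "pc_end_year_range", "registration_age_range"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        for key in ("event_rates",):
            if key in d:
                d[key] = {k: tuple(v) for k, v in d[key].items()}
        if "blood_test_rates" in d:
            d["blood_test_rates"] = {k: tuple(v) for k, v in d["blood_test_rates"].items()}
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def _plainify(obj):
    """Recursively convert tuples to lists so YAML stays plain."""
    if isinstance(obj, dict):
        return {k: _plainify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plainify(v) for v in obj]
    return obj
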