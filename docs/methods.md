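# Methods

This note documents the models, conventions and numerical choices behind
`landshap`, what the synthetic-data generator does and does not emulate,
and the problem sizes the test suite and `scripts/acceptance.py` use.

## The super-landmark dataset

A landmark analysis predicts an event over a fixed horizon using only
information available at the landmark time.  Here the landmark times are
integer ages 40–74; a person's index date at age *a* is the first day of
the month containing their *a*-th birthday (leap-day birthdays anniversary
on 1 March — a deterministic convention for a case the calendar leaves
open).  Eligibility at an index date requires:

1. **alive** — no death date before the index date;
2. **coverage** — among the merged primary-care coverage runs (raw
   intervals joined when separated by ≤90 days; a gap of exactly 90 days
   does *not* break a run, reading "no gaps of more than 90 days"
   strictly), the run with the latest end intersecting the two-year
   window `[index − 730 d, index)` must cover ≥183 consecutive days of
   that window.  183 days is the unambiguous day-count reading of "six
   months".  By default the run need only fall inside the window; a
   `require_coverage_to_index` flag additionally demands that it extend to
   the index date.
3. **no prior cancer** — no registry cancer other than non-melanoma skin
   cancer (NMSC) strictly before the index date.  A CRC diagnosis dated
   exactly on the index date is treated as an outcome event at time 1 day
   rather than a prior cancer — the least destructive reading of a
   same-day degenerate case.

Follow-up from each index date ends at the earliest of: first CRC (event),
first other non-NMSC cancer, death, `pc_end + 730 d` (two years after the
end of primary-care availability), or 730 days.  Ties resolve in that
priority order.  Per-age datasets are stacked; a person appears once per
eligible age.

All predictor lookback windows are half-open `[index − L, index)`: an
event on the index date itself is future, not history.

## Predictors

Six sets: core (8: age at index, sex, birth year, BMI, ethnicity, smoking,
Townsend deprivation, age at baseline assessment), polygenic score (1,
standardised, entered per SD), symptoms (16 two-year binaries), medical
history (12: event-sourced binaries with item-specific windows — 10 years
for colonoscopy, two years for medication use, full history for chronic
diagnoses — plus questionnaire-sourced family histories, screening
eligibility and a multimorbidity score), blood tests (4:
measured/abnormal indicator pairs for inflammation and iron families, so
"abnormal ⇒ measured" by construction), and lifestyle (5).  Five symptom
names and one history name are configurable placeholders: they keep the
set sizes at their conventional candidate counts while the exact extra
items remain a user decision; the codebook is fully overridable.

The eighth core predictor is age at baseline assessment; with age at
index, birth year and baseline age, any two determine the third up to
months, but they are kept as separate candidates and the collinearity
check guards degenerate encodings.

Missing data: smoking and ethnicity get an explicit "Missing" level; any
other missing baseline value drops the row (complete case).  Event-sourced
predictors are never missing — absence of a code is 0.  Categorical
variables are reference-coded at model time (reference = first listed
level).

## Survival modelling

Cox proportional hazards on days since index (horizon 730), Efron ties
(month-start index dates make day-level ties heavy), cluster-robust
sandwich standard errors grouped on person (the same person recurs across
landmark ages).  Fitting is delegated to lifelines with coefficient
precision 1e-7 and at most 100 Newton steps.  Degenerate designs
(constant or collinear columns, zero events) are rejected before fitting.
lifelines reports the clustered sandwich only as per-term standard
errors; `CoxFit` therefore carries those (all downstream code consumes)
together with the naive inverse-information covariance matrix.

Stepwise selection is AIC-based and bidirectional, starting from the full
candidate model (`start="empty"` is available and is what the acceptance
script uses at desk scale, where the selected model is far smaller than
the candidate list); the single best add/drop move is applied until no
move lowers AIC, ties breaking in candidate order, so selection is
deterministic given the data and candidate order.  The null model's
partial likelihood is computed in closed form (all risk scores equal).
No terms are protected by default; a `protect` argument exists.

Absolute risk at 730 days is `1 − S₀(730)^exp(lp)` with the Breslow
baseline from the training data, centred on training means (a row at the
training mean receives exactly the baseline risk).

## Discrimination, bootstrap, Shapley

Harrell's C uses the strict pair rule: pair (i, j) is comparable iff
`t_i < t_j` and i had the event; tied risk scores count ½.  Pairs tied on
time are not comparable under this rule (some implementations additionally
count event-vs-censored pairs at tied times; the exhaustive-enumeration
oracle in the tests pins the behaviour).

Bootstrap replicates resample persons with replacement for training and
test on the out-of-bag persons (≈ e⁻¹ ≈ 36.8% of persons), which
guarantees ID-disjoint train/test splits with stable test size.  For each
replicate and each of the 64 predictor-set subsets, a Cox model is fitted
on the train rows and C computed on the test rows; `v(∅) = 0.5`.
Stepwise selection is run once on the full dataset and frozen; subset
models use the selected terms intersected with the subset's columns
(re-selection inside every one of the 64 × B fits is available as
`selection="per_fit"` but computationally disproportionate).  Indicator
columns that are constant within a train fold carry no information there
and are dropped from that fit; a sub-fit that still fails is recorded as
missing and its whole replicate is excluded from the decomposition.

Shapley values are exact (|N| = 6): the subset-weight formula, checked
against full 720-ordering permutation enumeration.  φ and the percentage
contributions `100·φ_j/(v_full − 0.5)` are computed *within* each
replicate and then summarised (mean point estimate, percentile 2.5/97.5
CIs); decomposing the replicate-mean grid instead would have no valid
interval.  Percentages are normalised by the above-chance gain
`v_full − 0.5`, not by `v_full`, so they sum to 100 and may be negative
for sets that degrade out-of-bag discrimination.  Efficiency
`Σφ = v(full) − 0.5` is asserted per replicate.

Calibration: deciles of predicted risk; observed risk is the
Kaplan–Meier complement at 730 days within each decile; collapsed
quantile edges (mass ties) merge bins with a warning.

## The synthetic cohort generator

The generator emulates the *structure* the pipeline assumes — not any
real population.  Per person (one RNG stream per `(seed, person_id)`, so
cohorts are bit-identical under a seed and reproducible under parallel
generation): baseline demographics and lifestyle from simple parametric
distributions with Table-like prevalences; a standardised polygenic
score; primary-care registration from a uniform age 25–40 to a per-person
records end (default 2015–2018), interrupted by Poisson gaps (0.1/year,
exponential mean 60 days); dated clinical events per code from yearly-band
Poisson processes with log-linear age slopes (e.g. new-onset constipation
0.092/year at 60, matching a ~17% two-year prevalence); blood tests per
family with Bernoulli abnormal flags.  Abnormality is simulated directly
as a flag; analyte thresholds are out of scope.

The CRC outcome is a piecewise-constant proportional-hazards process:
hazard = baseline × exp(Σ log-HR × current state), with default true
hazard ratios PGS 1.4 per SD, iron-deficiency anaemia (abnormal iron
test) 3.9, rectal bleeding 2.7.  Exposure states update at event onsets
and expiries; persistence is configurable — the default
`hazard_persistence_days=730` mirrors the two-year predictor window, and
`None` makes an exposure permanent once acquired.  Competing other-cancer
and death processes are independent constant-rate exponentials resolved
by earliest date; NMSC events are recorded but never terminal.  The
registry keeps the first cancer, at most one death, and any NMSC events;
primary-care records end at least two years before the registry linkage
end so every index date's two-year outcome window is fully observed.

**What passing tests do and do not show.**  The generator draws states
from the same model family the pipeline fits, with clean missingness and
no measurement error, coding heterogeneity, informative coverage gaps, or
age-varying baseline CRC hazard (a config slope exists, default 0).
Passing recovery and calibration tests therefore validates the *pipeline
machinery*, not transportability to real EHR data.

**Landmark attenuation (why recovery scenarios use persistent
exposures).**  With windowed exposures, the landmark model freezes the
covariate at index while the true hazard state can expire mid-follow-up;
the fitted landmark coefficient is then an attenuated, horizon-specific
average (e.g. a true HR of 3.9 fits near 2.4–3.1) — an inherent feature of
landmarking, not a defect.  Parameter-recovery and calibration checks
therefore use scenarios in which the model is well-specified: permanent
exposure states with matching "ever" lookbacks and low onset rates
(0.01/year), or a purely static continuous predictor.  The windowed
default is still exercised for direction and magnitude in the worked
example and module tests.

## Problem sizes and numerical choices

* Recovery: 20 000 persons, landmark ages 58–64 (~46 000 rows, ~900
  events); each log-HR within 3 robust SEs of truth.
* Null-CI coverage: 200 cohorts of 1 000 persons, ages 60–62 (~34 events
  each; replicates with <20 events are skipped as too sparse for a Wald
  interval); coverage required in [90%, 99%].
* Dummy-set check: 5 000 persons, ages 60–62, one signal set (iron, HR
  3.9 — baseline hazard 0.02/year for event yield) and five pure-noise
  event sets, B = 50: noise φ CIs cover 0, signal φ CI does not.
* Calibration: 20 000 persons, PGS-only model; decile slope 1 ± 0.15
  computed in-sample (out-of-sample decile slopes at this scale inherit
  ~2σ coefficient noise amplified in the extreme deciles and do not test
  the machinery); the miscalibration-direction check (doubled true
  baseline → observed > predicted in every decile) *is* out-of-cohort.
* Determinism: the full pipeline (500 persons, 3 sets, B = 20) is
  bit-identical under a fixed seed.
* Convergence: lifelines precision 1e-7, ≤100 steps; Shapley efficiency
  tolerance 1e-12; percentile CIs by linear interpolation.

`scripts/acceptance.py` runs the recovery analysis at 10 000 persons and
the six-set analysis (stepwise + 64-subset grid + Shapley + calibration)
at 2 500 persons with B = 25, with the baseline hazard raised to
0.02/year so the scaled-down cohort yields enough events for stable
subset fits.

## Known limitations

* Clinical vocabularies are symbolic codes, not Read/SNOMED; code-list
  curation is out of scope.
* The symptomatic-subcohort definition and sensitivity mode
  (`any_except_fatigue`) operate on the derived symptom binaries only.
* No time-varying coefficients or within-follow-up covariate updates;
  PH diagnostics are limited to fit warnings.
* Penalised selection (e.g. group lasso) is not implemented.
* The full robust covariance matrix is not exposed (per-term robust SEs
  are); joint Wald tests across terms would need the naive matrix or an
  external sandwich implementation.
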