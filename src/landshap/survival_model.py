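"""Cox proportional-hazards modelling on the stacked landmark dataset.

The same person appears at several landmark ages, so rows are correlated
within person; standard errors therefore use the cluster-robust sandwich
estimator grouped on ``person_id``.  Ties are handled with Efron's method
(month-start index dates make day-level ties heavy).  Variable selection is
AIC-based bidirectional stepwise search starting from the full candidate
model, deterministic given the candidate order.

Fitting delegates to :class:`lifelines.CoxPHFitter` (Newton, coefficient
precision 1e-7, at most 100 steps); this module owns the contracts —
degenerate-input detection, the AIC identity, the stepwise search, and
baseline-hazard risk prediction at a fixed horizon.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from lifelines.exceptions import ConvergenceError

DEFAULT_FIT_OPTIONS = {"precision": 1e-7, "max_steps": 100}


@dataclass
class CoxFit:
    """A fitted Cox model plus the summaries the pipeline consumes.

    ``se`` holds the cluster-robust (sandwich) standard errors when the fit
    was clustered, otherwise the naive inverse-information ones;
    ``naive_cov`` is always the inverse-information covariance matrix.
    """

    coefficients: pd.Series            # term -> log hazard ratio
    se: pd.Series                      # robust (clustered) or naive SEs
    naive_cov: pd.DataFrame
    robust: bool
    log_partial_likelihood: float
    aic: float
    n_rows: int
    n_events: int
    terms: list
    model: CoxPHFitter = field(repr=False)
    max_duration: float = 0.0

    @property
    def hazard_ratios(self) -> pd.Series:
        return np.exp(self.coefficients)

    def standard_errors(self) -> pd.Series:
        return self.se

    def confidence_intervals(self, alpha: float = 0.05) -> pd.DataFrame:
        from scipy.stats import norm
        z = norm.ppf(1 - alpha / 2)
        se = self.standard_errors()
        return pd.DataFrame({"lower": self.coefficients - z * se,
                             "upper": self.coefficients + z * se})

    def summary_frame(self) -> pd.DataFrame:
        """Term, HR and robust 95% CI on the hazard-ratio scale."""
        ci = self.confidence_intervals()
        return pd.DataFrame({
            "term": self.terms,
            "hr": np.exp(self.coefficients.to_numpy()),
            "hr_lower": np.exp(ci.lower.to_numpy()),
            "hr_upper": np.exp(ci.upper.to_numpy()),
        })


def _check_design(X: pd.DataFrame) -> None:
    nun = X.nunique()
    constant = list(nun[nun <= 1].index)
    if constant:
        raise ValueError(f"constant terms in design: {constant}")
    arr = X.to_numpy(dtype=float)
    centred = arr - arr.mean(axis=0)
    if np.linalg.matrix_rank(centred) < arr.shape[1]:
        raise ValueError("collinear terms in design")


def fit_cox(dataset: pd.DataFrame, terms, duration_col: str = "time_days",
            event_col: str = "event", cluster: str | None = "person_id",
            fit_options: dict | None = None) -> CoxFit:
    """Fit a Cox PH model (Efron ties) and return a :class:`CoxFit`.

    With ``cluster`` set (default ``person_id``) the covariance is the
    cluster-robust sandwich estimator; ``cluster=None`` gives the naive
    inverse-information covariance.
    """
    terms = list(terms)
    if not terms:
        raise ValueError("no terms to fit")
    n_events = int(dataset[event_col].sum())
    if n_events < 1:
        raise ValueError("zero events in dataset")
    _check_design(dataset[terms])

    cols = terms + [duration_col, event_col]
    if cluster is not None:
        cols.append(cluster)
    cph = CoxPHFitter()
    kwargs = {"duration_col": duration_col, "event_col": event_col,
              "fit_options": dict(DEFAULT_FIT_OPTIONS, **(fit_options or {})),
              "show_progress": False}
    if cluster is not None:
        kwargs["cluster_col"] = cluster
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cph.fit(dataset[cols], **kwargs)

    beta = cph.params_.copy()
    ll = float(cph.log_likelihood_)
    aic = -2.0 * ll + 2.0 * len(terms)
    return CoxFit(coefficients=beta,
                  se=cph.standard_errors_.copy(),
                  naive_cov=cph.variance_matrix_.copy(),
                  robust=cluster is not None,
                  log_partial_likelihood=ll,
                  aic=aic,
                  n_rows=len(dataset),
                  n_events=n_events,
                  terms=terms,
                  model=cph,
                  max_duration=float(dataset[duration_col].max()))


def null_log_partial_likelihood(durations, events) -> float:
    """Efron partial log-likelihood of the covariate-free model (beta = 0).

    With all risk scores equal, the Efron denominator for the l-th tied
    event at a time with d events and n at risk is (n - l), so the
    contribution of each tie group is -sum_{l<d} log(n - l).
    """
    t = np.asarray(durations, dtype=float)
    e = np.asarray(events, dtype=int)
    order = np.argsort(-t, kind="mergesort")
    t, e = t[order], e[order]
    ll = 0.0
    n = len(t)
    i = 0
    while i < n:
        j = i
        while j < n and t[j] == t[i]:
            j += 1
        d = int(e[i:j].sum())
        at_risk = j  # times sorted descending: rows 0..j-1 have time >= t[i]
        for l in range(d):
            ll -= np.log(at_risk - l)
        i = j
    return ll


def stepwise_aic(dataset: pd.DataFrame, candidates, direction: str = "both",
                 duration_col: str = "time_days", event_col: str = "event",
                 start: str = "full", protect=()) -> list:
    """AIC-based bidirectional stepwise Cox selection.

    Starting from the full candidate model (``start="empty"`` starts from
    none), repeatedly applies the single add/drop move that most decreases
    the AIC until no move improves it.  Ties break in candidate order;
    non-convergent sub-fits are skipped with a warning.  Returns the
    selected terms in candidate order.
    """
    candidates = list(candidates)
    if not candidates:
        raise ValueError("candidates must be non-empty")
    protect = set(protect)

    null_aic = -2.0 * null_log_partial_likelihood(
        dataset[duration_col], dataset[event_col])

    def model_aic(terms):
        if not terms:
            return null_aic
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                return fit_cox(dataset, terms, duration_col, event_col,
                               cluster=None).aic
        except (ConvergenceError, ValueError, np.linalg.LinAlgError) as exc:
            warnings.warn(f"stepwise sub-fit failed for {terms}: {exc}")
            return np.inf

    current = list(candidates) if start == "full" else []
    current_aic = model_aic(current)
    if not np.isfinite(current_aic):
        raise ValueError("initial stepwise model did not converge")

    while True:
        best_move, best_aic = None, current_aic
        moves = []
        if direction in ("both", "backward"):
            moves += [("drop", t) for t in current if t not in protect]
        if direction in ("both", "forward"):
            moves += [("add", t) for t in candidates if t not in current]
        for kind, term in moves:
            trial = ([t for t in current if t != term] if kind == "drop"
                     else current + [term])
            trial_aic = model_aic(trial)
            if trial_aic < best_aic - 1e-10:
                best_move, best_aic = (kind, term), trial_aic
        if best_move is None:
            break
        kind, term = best_move
        current = ([t for t in current if t != term] if kind == "drop"
                   else current + [term])
        current_aic = best_aic
    return [t for t in candidates if t in current]


def predict_risk(fit: CoxFit, rows: pd.DataFrame,
                 horizon_days: int = 730) -> np.ndarray:
    """Absolute event risk 1 - S(horizon | x) per row.

    Uses the Breslow baseline survival from the training data; lifelines
    centres the linear predictor on the training means, so a row at the
    training mean receives exactly the baseline risk.
    """
    if horizon_days > fit.max_duration:
        raise ValueError(
            f"horizon {horizon_days} beyond observed follow-up {fit.max_duration}")
    surv = fit.model.predict_survival_function(rows[fit.terms],
                                               times=[horizon_days])
    return 1.0 - surv.iloc[0].to_numpy()
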