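"""Discrimination and calibration of the landmark models.

Validation uses person-level bootstrapping: each replicate samples persons
with replacement to form the training multiset and tests on the out-of-bag
persons, so no individual contributes to both sides.  For every replicate
and every subset of the six predictor sets, a Cox model is fitted on the
training rows and Harrell's C-index is computed on the held-out rows; the
resulting replicate-by-subset grid feeds the Shapley decomposition.

Harrell's C here uses the strict pair rule: a pair (i, j) is comparable iff
t_i < t_j and row i had the event; concordant pairs score 1, tied risk
scores 0.5, discordant 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter

from .survival_model import fit_cox

DEFAULT_B = 200


def harrells_c(scores, time_days, events) -> float:
    """Harrell's concordance index of risk scores against censored outcomes.

    Comparable pairs are those where the shorter time ends in an event;
    higher score with shorter time counts as concordant, equal scores count
    half.  Raises ``ValueError`` when no pair is comparable.
    """
    s = np.asarray(scores, dtype=float)
    t = np.asarray(time_days, dtype=float)
    e = np.asarray(events)
    if not (len(s) == len(t) == len(e)):
        raise ValueError("scores, time_days, events must have equal length")
    if not np.isin(e, (0, 1)).all():
        raise ValueError("events must be 0/1")
    e = e.astype(bool)
    num = 0.0
    n_comp = 0
    for i in np.flatnonzero(e):
        later = t > t[i]
        n = int(later.sum())
        if n == 0:
            continue
        n_comp += n
        num += (s[later] < s[i]).sum() + 0.5 * (s[later] == s[i]).sum()
    if n_comp == 0:
        raise ValueError("no comparable pairs")
    return num / n_comp


def bootstrap_partition(person_ids, rng, max_tries: int = 100):
    """With-replacement person resample; returns (train multiset, oob test set).

    Train ids are sampled with replacement (same size as the id pool); test
    ids are the persons never sampled, guaranteeing ID-disjoint splits.  A
    degenerate empty test set triggers a warned resample.
    """
    ids = np.unique(np.asarray(person_ids))
    if len(ids) < 2:
        raise ValueError("need at least 2 distinct person ids")
    for _ in range(max_tries):
        train = rng.choice(ids, size=len(ids), replace=True)
        test = np.setdiff1d(ids, train)
        if len(test) > 0:
            return train, test
        warnings.warn("empty out-of-bag test set; resampling")
    raise RuntimeError("could not obtain a non-empty out-of-bag set")


def all_subsets(players) -> list:
    """Subsets of ``players`` in canonical bitmask order (index i sets bit i)."""
    players = tuple(players)
    return [tuple(p for i, p in enumerate(players) if mask >> i & 1)
            for mask in range(2 ** len(players))]


@dataclass
class CombinationGrid:
    """C-index for every (bootstrap replicate, predictor-set subset)."""

    players: tuple
    B: int
    values: pd.DataFrame  # columns: replicate, mask, c
    v_empty: float = 0.5

    def value_array(self, replicate: int) -> np.ndarray:
        """C-indices of one replicate indexed by subset bitmask."""
        sub = self.values[self.values.replicate == replicate]
        out = np.full(2 ** len(self.players), np.nan)
        out[sub["mask"].to_numpy()] = sub["c"].to_numpy()
        return out

    def to_long_frame(self) -> pd.DataFrame:
        names = [" + ".join(s) if s else "(none)" for s in all_subsets(self.players)]
        out = self.values.copy()
        out["subset"] = out["mask"].map(dict(enumerate(names)))
        return out[["replicate", "mask", "subset", "c"]]

    def mean_c_table(self) -> pd.DataFrame:
        """Replicate-mean C per subset (the combination table of the report)."""
        longf = self.to_long_frame()
        g = longf.groupby(["mask", "subset"], sort=True)["c"]
        out = g.agg(mean_c="mean",
                    ci_lower=lambda v: np.nanpercentile(v, 2.5),
                    ci_upper=lambda v: np.nanpercentile(v, 97.5)).reset_index()
        return out


def combination_grid(dataset: pd.DataFrame, set_map: dict, B: int = DEFAULT_B,
                     rng=None, selected_terms=None,
                     duration_col: str = "time_days", event_col: str = "event",
                     id_col: str = "person_id", v_empty: float = 0.5,
                     selection: str = "frozen",
                     stepwise_candidates=None) -> CombinationGrid:
    """Person-bootstrap C-index grid over all predictor-set combinations.

    ``set_map`` maps each predictor set to its numeric design columns.
    ``selected_terms`` restricts every subset's term union to a frozen
    stepwise-selected list (``selection="frozen"``, the default analysis
    mode); ``selection="per_fit"`` re-runs stepwise selection inside every
    train fold over ``stepwise_candidates`` intersected with the subset.
    Failed sub-fits are recorded as NaN and excluded from summaries.
    """
    if rng is None:
        rng = np.random.default_rng()
    players = tuple(set_map)
    subsets = all_subsets(players)
    selected = set(selected_terms) if selected_terms is not None else None

    groups = dataset.groupby(id_col).indices  # positional row indices per person
    ids = np.unique(dataset[id_col].to_numpy())

    records = []
    for b in range(B):
        train_ids, test_ids = bootstrap_partition(ids, rng)
        train_idx = np.concatenate([groups[i] for i in train_ids])
        test_idx = np.concatenate([groups[i] for i in test_ids])
        train = dataset.iloc[train_idx]
        test = dataset.iloc[test_idx]
        for mask, subset in enumerate(subsets):
            if not subset:
                records.append((b, mask, v_empty))
                continue
            terms = [c for s in subset for c in set_map[s]]
            if selection == "per_fit":
                from .survival_model import stepwise_aic
                cand = [t for t in (stepwise_candidates or terms) if t in terms]
                try:
                    terms = stepwise_aic(train, cand, duration_col=duration_col,
                                         event_col=event_col)
                except Exception:
                    terms = []
            elif selected is not None:
                terms = [t for t in terms if t in selected]
            # rare indicator columns can be constant within a train fold;
            # they carry no information there and are dropped from that fit
            terms = [t for t in terms if train[t].nunique() > 1]
            if not terms:
                records.append((b, mask, v_empty))
                continue
            try:
                fit = fit_cox(train, terms, duration_col, event_col, cluster=None)
                lp = test[terms].to_numpy(dtype=float) @ fit.coefficients.to_numpy()
                c = harrells_c(lp, test[duration_col], test[event_col])
            except Exception as exc:  # recorded missing, excluded downstream
                warnings.warn(f"grid fit failed (b={b}, subset={subset}): {exc}")
                c = np.nan
            records.append((b, mask, c))
    values = pd.DataFrame(records, columns=["replicate", "mask", "c"])
    return CombinationGrid(players=players, B=B, values=values, v_empty=v_empty)


# --------------------------------------------------------------------------
# calibration

@dataclass
class CalibrationTable:
    table: pd.DataFrame  # decile, n, n_events, mean_predicted, observed


def calibration_deciles(fit, test_rows: pd.DataFrame, horizon_days: int = 730,
                        n_bins: int = 10, duration_col: str = "time_days",
                        event_col: str = "event") -> CalibrationTable:
    """Observed (Kaplan-Meier complement) vs mean predicted risk by decile.

    Deciles partition the test rows by predicted risk; bins that cannot be
    formed because of mass ties are merged (with a warning), matching the
    usual decile-plot construction.
    """
    from .survival_model import predict_risk

    risk = predict_risk(fit, test_rows, horizon_days)
    try:
        bins = np.asarray(pd.qcut(risk, n_bins, labels=False,
                                  duplicates="drop"), dtype=float)
    except ValueError:
        bins = np.full(len(risk), np.nan)
    n_distinct = np.unique(bins[~np.isnan(bins)]).size
    if n_distinct < 2:
        # mass ties collapsed the quantile edges entirely
        warnings.warn("predicted risks nearly constant: single calibration bin")
        bins = np.zeros(len(risk))
    elif n_distinct < n_bins:
        warnings.warn("tied predicted risks: merged adjacent deciles")

    recs = []
    for dec in np.unique(bins):
        sel = bins == dec
        km = KaplanMeierFitter()
        km.fit(test_rows.loc[sel, duration_col], test_rows.loc[sel, event_col])
        observed = 1.0 - float(
            km.survival_function_at_times(horizon_days).iloc[0])
        recs.append((int(dec) + 1, int(sel.sum()),
                     int(test_rows.loc[sel, event_col].sum()),
                     float(risk[sel].mean()), observed))
    return CalibrationTable(table=pd.DataFrame(
        recs, columns=["decile", "n", "n_events", "mean_predicted", "observed"]))
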