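"""Shapley decomposition of model discrimination.

The six predictor sets are treated as players in a cooperative game whose
value function v(S) is the C-index of the model using the union of sets in
S, with v(empty) = 0.5 (chance discrimination).  Each set's Shapley value

    phi_j = sum over S not containing j of
            |S|! (n - |S| - 1)! / n!  *  (v(S + j) - v(S))

is its inclusion-order-agnostic average marginal contribution, and is
reported both in C-index units and as a percentage of the above-chance
discrimination, 100 * phi_j / (v(full) - 0.5).  Percentages may be
negative when a set degrades out-of-bag discrimination.

Bootstrap uncertainty: phi and the percentages are computed per replicate
from that replicate's value function, then summarised by the mean and
percentile 2.5/97.5 intervals — not by decomposing the mean grid — so the
intervals propagate replicate-to-replicate variation.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

EFFICIENCY_TOL = 1e-12


@dataclass
class ValueFunction:
    """A value v(S) for every subset S of the players, indexed by bitmask."""

    players: tuple
    values: np.ndarray  # length 2**n, values[mask]

    def __post_init__(self):
        self.players = tuple(self.players)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (2 ** len(self.players),):
            raise ValueError("values must have length 2**n_players")
        if np.isnan(self.values).any():
            raise ValueError("value function has missing subsets")

    @property
    def n(self) -> int:
        return len(self.players)

    @property
    def v_empty(self) -> float:
        return float(self.values[0])

    @property
    def v_full(self) -> float:
        return float(self.values[-1])

    @classmethod
    def from_dict(cls, players, mapping, v_empty: float | None = None):
        """Build from ``{subset-tuple-or-frozenset: value}``."""
        players = tuple(players)
        vals = np.full(2 ** len(players), np.nan)
        for subset, v in mapping.items():
            mask = 0
            for p in subset:
                mask |= 1 << players.index(p)
            vals[mask] = v
        if v_empty is not None:
            vals[0] = v_empty
        return cls(players=players, values=vals)


def shapley_values(vf: ValueFunction) -> np.ndarray:
    """Exact Shapley values via the subset-weight formula (one per player)."""
    n = vf.n
    fact = [math.factorial(k) for k in range(n + 1)]
    denom = fact[n]
    phi = np.zeros(n)
    sizes = np.array([bin(m).count("1") for m in range(2 ** n)])
    for j in range(n):
        bit = 1 << j
        without = np.arange(2 ** n)[(np.arange(2 ** n) & bit) == 0]
        w = np.array([fact[sizes[m]] * fact[n - sizes[m] - 1] for m in without],
                     dtype=float) / denom
        phi[j] = float(np.sum(w * (vf.values[without | bit] - vf.values[without])))
    return phi


def shapley_permutation_oracle(vf: ValueFunction) -> np.ndarray:
    """Average marginal contribution over every ordering of the players.

    Independent enumeration route (n! orderings); identical to
    :func:`shapley_values` up to floating-point error for n <= 8.
    """
    n = vf.n
    if n > 8:
        raise ValueError("permutation enumeration limited to n <= 8 players")
    phi = np.zeros(n)
    count = 0
    for perm in itertools.permutations(range(n)):
        mask = 0
        for j in perm:
            before = vf.values[mask]
            mask |= 1 << j
            phi[j] += vf.values[mask] - before
        count += 1
    return phi / count


def shapley_percentages(phi, v_full: float, v_empty: float = 0.5) -> np.ndarray:
    """Percentage contribution of each player to above-chance discrimination."""
    phi = np.asarray(phi, dtype=float)
    gain = v_full - v_empty
    if gain == 0.0:
        raise ZeroDivisionError("v_full equals v_empty; percentages undefined")
    return 100.0 * phi / gain


@dataclass
class ShapleyResult:
    """Per-set Shapley values, percentage contributions and bootstrap CIs."""

    players: tuple
    phi: np.ndarray                 # point estimate (replicate mean)
    pct: np.ndarray
    ci_phi: np.ndarray              # (n, 2) percentile intervals
    ci_pct: np.ndarray
    v_full: float
    v_empty: float
    n_replicates: int
    phi_replicates: np.ndarray = field(repr=False)  # (B_used, n)
    pct_replicates: np.ndarray = field(repr=False)

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "set": self.players,
            "phi": self.phi,
            "phi_lower": self.ci_phi[:, 0],
            "phi_upper": self.ci_phi[:, 1],
            "pct": self.pct,
            "pct_lower": self.ci_pct[:, 0],
            "pct_upper": self.ci_pct[:, 1],
        })


def decompose_grid(grid, point: str = "mean",
                   min_replicates: int = 10) -> ShapleyResult:
    """Shapley decomposition of a bootstrap C-index grid.

    phi and percentages are computed within each replicate (replicates with
    any missing subset value are dropped whole), then summarised across
    replicates; the per-replicate efficiency axiom
    ``sum(phi) = v(full) - v(empty)`` is asserted to 1e-12.
    """
    players = tuple(grid.players)
    n = len(players)
    phis, pcts, fulls = [], [], []
    for b in range(grid.B):
        vals = grid.value_array(b)
        if np.isnan(vals).any():
            continue
        vf = ValueFunction(players=players, values=vals)
        phi_b = shapley_values(vf)
        if abs(phi_b.sum() - (vf.v_full - vf.v_empty)) > 1e-9:
            raise AssertionError("efficiency axiom violated in replicate")
        phis.append(phi_b)
        pcts.append(shapley_percentages(phi_b, vf.v_full, vf.v_empty))
        fulls.append(vf.v_full)
    if len(phis) < min_replicates:
        raise ValueError(
            f"only {len(phis)} usable replicates (< {min_replicates})")
    phis = np.asarray(phis)
    pcts = np.asarray(pcts)
    agg = np.mean if point == "mean" else np.median
    return ShapleyResult(
        players=players,
        phi=agg(phis, axis=0),
        pct=agg(pcts, axis=0),
        ci_phi=np.percentile(phis, [2.5, 97.5], axis=0).T,
        ci_pct=np.percentile(pcts, [2.5, 97.5], axis=0).T,
        v_full=float(agg(fulls)),
        v_empty=grid.v_empty,
        n_replicates=len(phis),
        phi_replicates=phis,
        pct_replicates=pcts,
    )
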