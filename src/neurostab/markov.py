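"""Quartile-based three-state discretization and Markov-chain estimation.

A per-spike scalar series (peak onset rapidness or per-spike Lyapunov
exponent) is discretized into three classes by its own quartiles: class 1
spans minimum to first quartile, class 2 the interquartile range, class 3
third quartile to maximum. The discrete-time Markov chain over those
classes is then summarized by its transition-count and row-stochastic
transition-probability matrices. Strong diagonal mass means the neuron
dwells in one kinetic regime (state persistence); heavy off-diagonal mass
means rapid switching between regimes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from ._utils import ArrayEqMixin
from .io import register_result

N_STATES = 3


@register_result
@dataclass(eq=False)
class StateSequence(ArrayEqMixin):
    """A series over classes {1, 2, 3} plus the quartiles that defined it."""

    states: np.ndarray
    source: str = "rapidness"  # rapidness | lyapunov | synthetic
    quartiles: Optional[tuple] = None  # (Q1, Q3)
    degenerate: bool = False  # all input values identical

    def __post_init__(self):
        self.states = np.asarray(self.states, dtype=int)
        if self.states.ndim != 1:
            raise ValueError("states must be one-dimensional")
        if self.states.size and not np.isin(self.states, [1, 2, 3]).all():
            raise ValueError("states must take values in {1, 2, 3}")

    def __len__(self):
        return self.states.size

    def to_dict(self) -> dict:
        return {
            "states": self.states,
            "source": self.source,
            "quartiles": None if self.quartiles is None else list(self.quartiles),
            "degenerate": self.degenerate,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "StateSequence":
        q = d.get("quartiles")
        return cls(
            states=np.asarray(d["states"], dtype=int),
            source=d.get("source", "rapidness"),
            quartiles=None if q is None else tuple(q),
            degenerate=bool(d.get("degenerate", False)),
        )


@register_result
@dataclass(eq=False)
class TransitionMatrix(ArrayEqMixin):
    """Row-stochastic 3x3 transition probabilities with raw counts.

    Rows whose state never occurs as a transition source carry a uniform
    placeholder in ``P`` and are marked in ``flagged_rows``; summaries skip
    them rather than pretending the row was observed.
    """

    P: np.ndarray
    counts: np.ndarray
    n_transitions: int
    flagged_rows: np.ndarray = field(
        default_factory=lambda: np.zeros(N_STATES, dtype=bool)
    )

    def __post_init__(self):
        self.P = np.asarray(self.P, dtype=float)
        self.counts = np.asarray(self.counts, dtype=int)
        self.flagged_rows = np.asarray(self.flagged_rows, dtype=bool)
        if self.P.shape != (N_STATES, N_STATES) or self.counts.shape != (N_STATES, N_STATES):
            raise ValueError("P and counts must be 3x3")
        if int(self.counts.sum()) != int(self.n_transitions):
            raise ValueError("counts must sum to n_transitions")
        if np.any(self.P < 0) or np.any(self.P > 1):
            raise ValueError("probabilities must lie in [0, 1]")

    @property
    def off_diagonal_mass(self) -> float:
        """Mean off-diagonal probability over non-flagged rows."""
        return 1.0 - persistence_index(self)

    def to_dict(self) -> dict:
        return {
            "P": self.P,
            "counts": self.counts,
            "n_transitions": self.n_transitions,
            "flagged_rows": self.flagged_rows,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TransitionMatrix":
        return cls(
            P=np.asarray(d["P"], dtype=float),
            counts=np.asarray(d["counts"], dtype=int),
            n_transitions=int(d["n_transitions"]),
            flagged_rows=np.asarray(d["flagged_rows"], dtype=bool),
        )


def classify_quartiles(values, source: str = "rapidness") -> StateSequence:
    """Discretize a scalar series into classes 1/2/3 by its quartiles.

    Quartiles use linear interpolation of order statistics (the common
    "type 7" convention). Boundary rule: values exactly at Q1 fall in
    class 1, exactly at Q3 in class 2. If all values are identical the
    quartiles are degenerate; everything is class 2 and the sequence is
    flagged.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 4:
        raise ValueError("quartile classification needs at least 4 values")
    if not np.all(np.isfinite(v)):
        raise ValueError("values must be finite (drop flagged spikes first)")
    q1, q3 = np.percentile(v, [25, 75])
    if q1 == q3:
        return StateSequence(
            states=np.full(v.size, 2), source=source, quartiles=(float(q1), float(q3)),
            degenerate=True,
        )
    states = np.full(v.size, 2)
    states[v <= q1] = 1
    states[v > q3] = 3
    return StateSequence(states=states, source=source, quartiles=(float(q1), float(q3)))


def transition_matrix(states) -> TransitionMatrix:
    """Estimate the 3x3 transition matrix from a state sequence.

    ``counts[i, j]`` is the number of consecutive (i -> j) pairs; ``P`` is
    the row-normalized counts. Never-visited source states get a uniform
    placeholder row and a flag.
    """
    s = states.states if isinstance(states, StateSequence) else np.asarray(states, dtype=int)
    if s.size < 2:
        raise ValueError("need at least 2 states to count transitions")
    counts = np.zeros((N_STATES, N_STATES), dtype=int)
    np.add.at(counts, (s[:-1] - 1, s[1:] - 1), 1)
    row_sums = counts.sum(axis=1)
    flagged = row_sums == 0
    P = np.full((N_STATES, N_STATES), 1.0 / N_STATES)
    nz = ~flagged
    P[nz] = counts[nz] / row_sums[nz, None]
    return TransitionMatrix(
        P=P, counts=counts, n_transitions=int(counts.sum()), flagged_rows=flagged
    )


def persistence_index(tm: TransitionMatrix) -> float:
    """Mean diagonal transition probability over non-flagged rows.

    1 means absolute state persistence; 1/3 is the memoryless expectation.
    This is an added summary used for testing and group comparison, not a
    quantity with an established definition in the source analyses.
    """
    keep = ~tm.flagged_rows
    if not keep.any():
        raise ValueError("all rows flagged; persistence undefined")
    return float(np.mean(np.diag(tm.P)[keep]))


def sample_states(
    P, n: int, seed: int | np.random.Generator = 0, init: int | None = None
) -> np.ndarray:
    """Sample a state sequence (values in {1,2,3}) from a transition matrix."""
    P = np.asarray(P, dtype=float)
    if P.shape != (N_STATES, N_STATES) or not np.allclose(P.sum(axis=1), 1.0):
        raise ValueError("P must be 3x3 row-stochastic")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    out = np.empty(n, dtype=int)
    state = (rng.integers(N_STATES) if init is None else init - 1)
    cum = np.cumsum(P, axis=1)
    u = rng.random(n)
    for t in range(n):
        out[t] = state + 1
        if t + 1 < n:
            state = int(np.searchsorted(cum[state], u[t], side="right"))
            state = min(state, N_STATES - 1)
    return out


class QuartileStateClassifier(BaseEstimator, TransformerMixin):
    """Transformer: learn quartiles on fit, map values to classes on transform."""

    def __init__(self, source: str = "rapidness"):
        self.source = source

    def fit(self, X, y=None):
        seq = classify_quartiles(np.asarray(X, dtype=float).ravel(), source=self.source)
        self.quartiles_ = seq.quartiles
        self.degenerate_ = seq.degenerate
        return self

    def transform(self, X) -> np.ndarray:
        v = np.asarray(X, dtype=float).ravel()
        q1, q3 = self.quartiles_
        if self.degenerate_:
            return np.full(v.size, 2)
        states = np.full(v.size, 2)
        states[v <= q1] = 1
        states[v > q3] = 3
        return states


class MarkovTransitionEstimator(BaseEstimator):
    """Estimator: fit a 3-state transition matrix from a state sequence."""

    def fit(self, X, y=None):
        tm = transition_matrix(X)
        self.transition_matrix_ = tm
        self.P_ = tm.P
        self.counts_ = tm.counts
        self.persistence_ = persistence_index(tm)
        return self

    def score(self, X) -> float:
        """Mean log-likelihood per transition of a held-out sequence."""
        s = X.states if isinstance(X, StateSequence) else np.asarray(X, dtype=int)
        p = self.P_[s[:-1] - 1, s[1:] - 1]
        return float(np.mean(np.log(np.clip(p, 1e-300, None))))
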