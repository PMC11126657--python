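"""Markov-chain estimation and projection of land-cover class areas.

A first-order Markov chain over M cover classes is calibrated from the
cross-tabulation of two dates: p_ij = n_ij / n_i., so each row of the
transition-probability matrix sums to one. Projection of the class-area
vector N over k equal calibration steps is N' = Nᵀ Pᵏ, which conserves
total area. Per-transition cell demands for the allocation engines are the
projected off-diagonal flows rounded by the largest-remainder method so
that every row's demands plus persistence add back to the class count.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "TransitionCountMatrix",
    "TransitionProbMatrix",
    "StateVector",
    "estimate_transition_probs",
    "project_state",
    "transition_demand",
    "largest_remainder_round",
]


@dataclass
class TransitionCountMatrix:
    """M×M cell (or area-unit) counts between two dates; rows = earlier class."""

    class_order: list[int]
    counts: np.ndarray
    epoch: tuple[str, str] | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        m = len(self.class_order)
        if self.counts.shape != (m, m):
            raise ValueError("counts must be square over the class order")
        if np.any(self.counts < 0):
            raise ValueError("transition counts must be non-negative")

    @property
    def total(self) -> float:
        return float(self.counts.sum())

    @property
    def row_totals(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def col_totals(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.class_order, columns=self.class_order)

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index_label="from\\to")

    @classmethod
    def from_csv(cls, path: str | Path) -> "TransitionCountMatrix":
        df = pd.read_csv(path, index_col=0)
        codes = [int(c) for c in df.index]
        if codes != [int(c) for c in df.columns]:
            raise ValueError("row and column class labels differ")
        return cls(class_order=codes, counts=df.to_numpy())


@dataclass
class TransitionProbMatrix:
    """Row-stochastic M×M transition probabilities over one calibration step."""

    class_order: list[int]
    P: np.ndarray
    step_years: float = 15.0
    identity_rows: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        self.P = np.asarray(self.P, dtype=np.float64)
        m = len(self.class_order)
        if self.P.shape != (m, m):
            raise ValueError("P must be square over the class order")
        if np.any(self.P < -1e-12) or np.any(self.P > 1 + 1e-12):
            raise ValueError("probabilities must lie in [0, 1]")
        rows = self.P.sum(axis=1)
        if not np.allclose(rows, 1.0, atol=1e-9):
            raise ValueError(f"rows must sum to 1; got {rows}")

    def prob(self, from_code: int, to_code: int) -> float:
        i = self.class_order.index(from_code)
        j = self.class_order.index(to_code)
        return float(self.P[i, j])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.P, index=self.class_order, columns=self.class_order)

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index_label="from\\to")


@dataclass
class StateVector:
    """Class areas or cell counts, ordered like the transition matrix."""

    class_order: list[int]
    N: np.ndarray

    def __post_init__(self) -> None:
        self.N = np.asarray(self.N, dtype=np.float64)
        if self.N.shape != (len(self.class_order),):
            raise ValueError("state vector length must match class order")
        if np.any(self.N < 0):
            raise ValueError("state vector entries must be non-negative")

    @property
    def total(self) -> float:
        return float(self.N.sum())


def estimate_transition_probs(ct: TransitionCountMatrix, step_years: float = 15.0) -> TransitionProbMatrix:
    """Maximum-likelihood row-normalization of a transition count matrix.

    Empty classes (zero row total) receive an identity row — they persist by
    definition — and are flagged on the result.
    """
    counts = np.asarray(ct.counts, dtype=np.float64)
    row_totals = counts.sum(axis=1)
    P = np.zeros_like(counts)
    identity_rows = []
    for i, total in enumerate(row_totals):
        if total > 0:
            P[i] = counts[i] / total
        else:
            P[i, i] = 1.0
            identity_rows.append(ct.class_order[i])
    return TransitionProbMatrix(
        class_order=list(ct.class_order),
        P=P,
        step_years=step_years,
        identity_rows=tuple(identity_rows),
    )


def project_state(N: StateVector, P: TransitionProbMatrix, steps: int = 1) -> StateVector:
    """Project the class-area vector ``steps`` calibration intervals forward."""
    if steps < 0:
        raise ValueError("steps must be non-negative")
    if N.class_order != P.class_order:
        raise ValueError("state vector and transition matrix class orders differ")
    out = N.N @ np.linalg.matrix_power(P.P, steps)
    return StateVector(class_order=list(N.class_order), N=out)


def largest_remainder_round(targets: np.ndarray, total: int) -> np.ndarray:
    """Round non-negative targets to integers summing exactly to ``total``."""
    targets = np.asarray(targets, dtype=np.float64)
    if targets.sum() <= 0:
        out = np.zeros(len(targets), dtype=np.int64)
        out[0] = total if len(targets) else 0
        return out
    scaled = targets * (total / targets.sum())
    floors = np.floor(scaled).astype(np.int64)
    short = total - int(floors.sum())
    remainders = scaled - floors
    order = np.argsort(-remainders, kind="stable")
    floors[order[:short]] += 1
    return floors


def transition_demand(
    P: TransitionProbMatrix,
    map_t,
    enabled: list[tuple[int, int]],
) -> dict[tuple[int, int], int]:
    """Cell demand per enabled transition: round(p_ij · n_i), with the rounding
    residual of each row absorbed by persistence so row totals are conserved."""
    counts = map_t.class_counts(P.class_order)
    demands: dict[tuple[int, int], int] = {}
    by_from: dict[int, list[tuple[int, int]]] = {}
    for pair in enabled:
        f, t = pair
        if f == t:
            raise ValueError("enabled transitions must have from != to")
        if f not in P.class_order or t not in P.class_order:
            raise ValueError(f"transition {pair} references unknown class codes")
        by_from.setdefault(f, []).append(pair)
    for f, pairs in by_from.items():
        n_i = counts.get(f, 0)
        probs = np.array([P.prob(f, t) for _, t in pairs])
        persist = max(0.0, 1.0 - probs.sum())
        alloc = largest_remainder_round(np.append(probs, persist), n_i)
        for pair, p, d in zip(pairs, probs, alloc[:-1]):
            if p == 0 and d == 0:
                warnings.warn(f"transition {pair} enabled but has zero calibrated probability", stacklevel=2)
            demands[pair] = int(d)
    for pair in enabled:
        demands.setdefault(pair, 0)
    return demands
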