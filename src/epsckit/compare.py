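"""Optimal event assignment between detectors and missed-rate summaries.

Two detectors' event sets ``a`` and ``b`` are compared on peak times.  The
thresholded distance matrix keeps only pairs closer than a maximum
assignable distance gamma::

    C_ij = |a_i - b_j|   if |a_i - b_j| <= gamma
           infeasible    otherwise

An optimal one-to-one matching minimizes the total assigned distance while
matching as many feasible pairs as possible (events keep being assigned as
long as both sides still have assignable ones).  The fraction of a
reference detector's events left unmatched is its missed rate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .events import EventSet

__all__ = [
    "AssignmentResult",
    "distance_matrix",
    "assign_events",
    "match_event_sets",
    "missed_rate",
    "missed_rate_matrix",
    "precision_recall_f1",
    "DEFAULT_GAMMA_S",
]

DEFAULT_GAMMA_S = 2e-3  # 2 ms default maximum assignable peak distance


@dataclass
class AssignmentResult:
    """Outcome of one optimal event assignment."""

    gamma: float
    cost: np.ndarray          # |a| x |b| distances, inf where > gamma
    X: np.ndarray             # boolean matching matrix
    pairs: list[tuple[int, int]]
    unmatched_a: list[int]
    unmatched_b: list[int]

    @property
    def total_cost(self) -> float:
        return float(sum(self.cost[i, j] for i, j in self.pairs))

    @property
    def n_matched(self) -> int:
        return len(self.pairs)


def distance_matrix(a: np.ndarray | EventSet, b: np.ndarray | EventSet,
                    gamma: float = DEFAULT_GAMMA_S) -> np.ndarray:
    """Thresholded |a_i - b_j| peak-time distance matrix (inf beyond gamma)."""
    if not gamma > 0:
        raise ValueError("gamma must be positive")
    ta = a.peak_times if isinstance(a, EventSet) else np.asarray(a, dtype=float)
    tb = b.peak_times if isinstance(b, EventSet) else np.asarray(b, dtype=float)
    C = np.abs(ta[:, None] - tb[None, :])
    C[C > gamma] = np.inf
    return C


def assign_events(cost: np.ndarray, gamma: float = DEFAULT_GAMMA_S) -> AssignmentResult:
    """Optimal one-to-one matching over the feasible entries of ``cost``.

    Maximum feasible cardinality first, minimum total distance second: the
    rectangular assignment is solved with a large finite surrogate cost for
    infeasible pairs, and surrogate assignments are removed afterwards, so
    an unassignable event can never crowd out genuine matches.
    """
    cost = np.asarray(cost, dtype=float)
    n_a, n_b = cost.shape
    if n_a == 0 or n_b == 0:
        return AssignmentResult(
            gamma, cost, np.zeros((n_a, n_b), bool), [],
            list(range(n_a)), list(range(n_b)),
        )
    feasible = np.isfinite(cost)
    # surrogate larger than any achievable total feasible cost
    big = (cost[feasible].max() if feasible.any() else 1.0) * (min(n_a, n_b) + 1) + 1.0
    surrogate = np.where(feasible, cost, big)
    rows, cols = linear_sum_assignment(surrogate)
    pairs = [(int(i), int(j)) for i, j in zip(rows, cols) if feasible[i, j]]
    X = np.zeros((n_a, n_b), dtype=bool)
    for i, j in pairs:
        X[i, j] = True
    matched_a = {i for i, _ in pairs}
    matched_b = {j for _, j in pairs}
    return AssignmentResult(
        gamma, cost, X, pairs,
        [i for i in range(n_a) if i not in matched_a],
        [j for j in range(n_b) if j not in matched_b],
    )


def match_event_sets(a: EventSet | np.ndarray, b: EventSet | np.ndarray,
                     gamma: float = DEFAULT_GAMMA_S) -> AssignmentResult:
    """Distance matrix + optimal assignment in one call."""
    return assign_events(distance_matrix(a, b, gamma), gamma)


def missed_rate(a: EventSet | np.ndarray, reference: EventSet | np.ndarray,
                gamma: float = DEFAULT_GAMMA_S) -> float:
    """Fraction of ``reference`` events with no assigned partner in ``a``."""
    res = match_event_sets(a, reference, gamma)
    n_ref = res.cost.shape[1]
    if n_ref == 0:
        return 0.0
    return len(res.unmatched_b) / n_ref


def missed_rate_matrix(event_sets: dict[str, EventSet | np.ndarray],
                       gamma: float = DEFAULT_GAMMA_S) -> pd.DataFrame:
    """All ordered detector pairs: rows = algorithm, columns = reference."""
    if len(event_sets) < 2:
        raise ValueError("need at least two detectors")
    names = list(event_sets)
    mat = pd.DataFrame(0.0, index=names, columns=names)
    for alg in names:
        for ref in names:
            if alg == ref:
                continue
            mat.loc[alg, ref] = missed_rate(event_sets[alg], event_sets[ref], gamma)
    return mat


def precision_recall_f1(detected: EventSet | np.ndarray,
                        truth: EventSet | np.ndarray,
                        gamma: float = DEFAULT_GAMMA_S) -> dict[str, float]:
    """Event-level precision/recall/F1 of ``detected`` against ground truth."""
    res = match_event_sets(detected, truth, gamma)
    n_det, n_true = res.cost.shape
    tp = res.n_matched
    precision = tp / n_det if n_det else 0.0
    recall = tp / n_true if n_true else 0.0
    f1 = (2 * precision * recall / (precision + recall)) if (precision + recall) else 0.0
    return {"precision": precision, "recall": recall, "f1": f1,
            "n_detected": n_det, "n_true": n_true, "n_matched": tp}
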