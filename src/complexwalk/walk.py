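"""The random walk with restart and the derived complex scores.

The walker starts on the query disease and at every step either restarts
there (probability gamma) or moves to a neighbour chosen in proportion to
the row-normalized edge weights:

    q(t+1) = (1 - gamma) * T^T q(t) + gamma * q(0)

Iteration stops once the L2 norm of q(t+1) - q(t) drops to the tolerance
epsilon (default 1e-5).  The steady-state mass sitting on complex nodes is
renormalized into scores

    s_i = q_inf[l + m + i] / sum_i q_inf[l + m + i]

and candidates are ranked in nonincreasing score order.  Because
(1 - gamma) * T^T is a contraction for gamma > 0, the fixed point is the
unique solution of (I - (1 - gamma) T^T) q = gamma q(0); a direct dense
solver for that system is exposed as an independent oracle for small
networks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.stats import rankdata

from .errors import ConvergenceError, ParameterError, ScoringError
from .network import HeterogeneousNetwork, TransitionMatrix

DEFAULT_GAMMA = 0.5
DEFAULT_EPSILON = 1e-5
DEFAULT_MAX_ITER = 10_000


@dataclass
class RestartVector:
    """Initial distribution: all mass on the query node."""

    q0: np.ndarray
    query_index: int

    @classmethod
    def for_query(cls, size: int, query_index: int) -> "RestartVector":
        if not 0 <= query_index < size:
            raise ParameterError("query index out of range")
        q0 = np.zeros(size)
        q0[query_index] = 1.0
        return cls(q0, query_index)


@dataclass
class WalkResult:
    q_inf: np.ndarray
    iterations: int
    final_delta: float
    scores: dict[str, float]
    parameters: dict


def walk(
    T: TransitionMatrix,
    q0: RestartVector | np.ndarray,
    gamma: float = DEFAULT_GAMMA,
    epsilon: float = DEFAULT_EPSILON,
    max_iter: int = DEFAULT_MAX_ITER,
) -> tuple[np.ndarray, int, float]:
    """Iterate the restart walk to steady state.

    Returns ``(q_inf, iterations, final_delta)``.  Raises
    :class:`ConvergenceError` if the L2 change is still above *epsilon*
    after *max_iter* iterations.
    """
    if not 0 < gamma <= 1:
        raise ParameterError("gamma must lie in (0, 1]")
    if epsilon <= 0:
        raise ParameterError("epsilon must be positive")
    if max_iter < 1:
        raise ParameterError("max_iter must be >= 1")
    start = q0.q0 if isinstance(q0, RestartVector) else np.asarray(q0, dtype=float)
    TT = T.T.transpose().tocsr()  # transpose of the transition matrix
    q = start.copy()
    for it in range(1, max_iter + 1):
        q_next = (1.0 - gamma) * (TT @ q) + gamma * start
        delta = float(np.linalg.norm(q_next - q))
        q = q_next
        if delta <= epsilon:
            return q, it, delta
    raise ConvergenceError(max_iter, delta, epsilon)


def solve_walk_direct(
    T: TransitionMatrix, q0: RestartVector | np.ndarray, gamma: float
) -> np.ndarray:
    """Closed-form steady state gamma * (I - (1-gamma) T^T)^-1 q0.

    Dense linear solve; intended as a testing oracle and as an exact
    alternative for networks small enough to densify (a few thousand
    nodes).
    """
    if not 0 < gamma <= 1:
        raise ParameterError("gamma must lie in (0, 1]")
    start = q0.q0 if isinstance(q0, RestartVector) else np.asarray(q0, dtype=float)
    n = start.size
    M = np.eye(n) - (1.0 - gamma) * T.T.transpose().toarray()
    return gamma * np.linalg.solve(M, start)


def score_complexes(
    q_inf: np.ndarray, network: HeterogeneousNetwork
) -> dict[str, float]:
    """Normalized complex scores s_i from the steady-state vector.

    Raises :class:`ScoringError` when no mass reached the complex layer
    (e.g. gamma = 1, or the query is disconnected from every complex).
    """
    mass = np.asarray(q_inf[network.complex_slice()], dtype=float)
    if mass.size == 0:
        raise ScoringError("network has no complex nodes")
    if np.any(mass < 0) or not np.all(np.isfinite(mass)):
        raise ScoringError("steady-state complex mass must be finite and >= 0")
    total = float(mass.sum())
    if total <= 0:
        raise ScoringError(
            "no steady-state mass on the complex layer: query disconnected"
        )
    return {
        cid: float(v / total) for cid, v in zip(network.complex_ids, mass)
    }


def rank(scores: dict[str, float]) -> pd.DataFrame:
    """Rank candidates in nonincreasing score order.

    Returns a frame with columns ``rank`` (display position 1..n, ties
    broken by complex id), ``complex_id``, ``score``, ``midrank`` (tied
    scores receive the mean of the positions they span) and ``tie``.
    """
    ids = sorted(scores)
    vals = np.array([scores[c] for c in ids], dtype=float)
    if not np.all(np.isfinite(vals)):
        raise ScoringError("scores must be finite")
    order = sorted(range(len(ids)), key=lambda i: (-vals[i], ids[i]))
    midranks = rankdata(-vals, method="average")
    counts = pd.Series(vals).value_counts()
    rows = [
        {
            "rank": pos + 1,
            "complex_id": ids[i],
            "score": float(vals[i]),
            "midrank": float(midranks[i]),
            "tie": bool(counts[vals[i]] > 1),
        }
        for pos, i in enumerate(order)
    ]
    return pd.DataFrame(
        rows, columns=["rank", "complex_id", "score", "midrank", "tie"]
    )


def naive_scores(
    protein_mass: dict[str, float], members: dict[str, list[str]]
) -> dict[str, float]:
    """Baseline aggregation: a complex scores the SUM of its members' mass.

    A protein shared by several complexes contributes its full mass to each
    of them (no splitting), which is exactly what distinguishes this
    baseline from the three-layer walk, where outgoing protein mass is
    divided among the complexes it belongs to.  Complexes with no scored
    member get 0.
    """
    return {
        c: float(sum(protein_mass.get(p, 0.0) for p in ps))
        for c, ps in members.items()
    }
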