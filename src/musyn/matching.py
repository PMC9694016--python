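"""Model-order selection and cross-condition synergy matching.

Builds reconstruction R-squared curves over factorization orders, picks
the smallest order whose R-squared clears a threshold (0.80 / 0.85 / 0.90
are the conventional levels), and matches two synergy sets by cosine
similarity computed on the muscle loads common to both conditions, with
the shared subset rescaled to unit norm first.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import linear_sum_assignment

from .nmf import SynergyDecomposition, nmf_factorize

__all__ = [
    "R2Curve",
    "MatchReport",
    "r2_curve",
    "select_order",
    "cosine_similarity",
    "subset_unit_norm",
    "match_synergies",
]


@dataclass
class R2Curve:
    """Best-of-restarts R-squared as a function of factorization order."""

    orders: list[int]
    r2_values: list[float]
    decompositions: dict[int, SynergyDecomposition] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.orders) != len(self.r2_values):
            raise ValueError("orders and r2_values must have equal length")

    def to_dict(self) -> dict:
        return {"orders": list(self.orders), "r2_values": [float(v) for v in self.r2_values]}


@dataclass
class MatchReport:
    """One-to-one pairing of two synergy sets with per-pair similarities.

    ``pairs`` holds ``(index_A, index_B)`` tuples for the matched columns;
    ``unmatched_B`` lists columns of the larger set left without a partner
    (the additional synergies).  Pairs whose shared-subset loads were all
    zero are excluded from scoring and listed in ``excluded_pairs``.
    """

    pairs: list[tuple[int, int]]
    similarities: list[float]
    unmatched_A: list[int]
    unmatched_B: list[int]
    excluded_pairs: list[tuple[int, int]]

    @property
    def mean_similarity(self) -> float:
        return float(np.mean(self.similarities)) if self.similarities else float("nan")

    @property
    def sd_similarity(self) -> float:
        return float(np.std(self.similarities, ddof=1)) if len(self.similarities) > 1 else 0.0

    def to_dict(self) -> dict:
        return {
            "pairs": [list(p) for p in self.pairs],
            "similarities": [float(s) for s in self.similarities],
            "mean_similarity": self.mean_similarity,
            "sd_similarity": self.sd_similarity,
            "unmatched_A": self.unmatched_A,
            "unmatched_B": self.unmatched_B,
            "excluded_pairs": [list(p) for p in self.excluded_pairs],
        }


def r2_curve(
    V: np.ndarray,
    max_order: int | None = None,
    restarts: int = 200,
    max_iter: int = 1000,
    tol: float = 1e-6,
    seed: int = 0,
    stop_at: float | None = None,
    keep_decompositions: bool = True,
) -> R2Curve:
    """Extract synergies at orders 1..max_order and collect the best
    R-squared per order.

    ``max_order`` defaults to the number of muscles.  When ``stop_at`` is
    given, the sweep stops early once the curve reaches that level, which
    is sufficient for threshold-based order selection at or below it.
    Deterministic given the master ``seed`` (each order reuses the same
    restart streams).
    """
    V = np.asarray(V, dtype=float)
    N = V.shape[0]
    if max_order is None:
        max_order = N
    if not 1 <= max_order <= N:
        raise ValueError(f"max_order={max_order} must be in 1..{N}")

    orders: list[int] = []
    values: list[float] = []
    decomps: dict[int, SynergyDecomposition] = {}
    for s in range(1, max_order + 1):
        dec = nmf_factorize(V, s, restarts=restarts, max_iter=max_iter, tol=tol, seed=seed)
        orders.append(s)
        values.append(dec.r2)
        if keep_decompositions:
            decomps[s] = dec
        if stop_at is not None and dec.r2 >= stop_at:
            break
    return R2Curve(orders=orders, r2_values=values, decompositions=decomps)


def select_order(curve: R2Curve, threshold: float) -> tuple[int, bool]:
    """Smallest order whose R-squared reaches ``threshold``.

    Returns ``(order, reached)``.  When the curve never reaches the
    threshold, the highest computed order is returned with
    ``reached=False`` rather than guessing.
    """
    if not 0 < threshold < 1:
        raise ValueError("threshold must be in (0, 1)")
    if not curve.orders:
        raise ValueError("empty R2 curve")
    for s, r2 in zip(curve.orders, curve.r2_values):
        if r2 >= threshold:
            return s, True
    return curve.orders[-1], False


def cosine_similarity(a: np.ndarray, b: np.ndarray) -> float:
    """Cosine of the angle between two nonnegative load vectors, in [0, 1]."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0.0 or nb == 0.0:
        raise ValueError("cosine similarity undefined for a zero vector")
    return float(np.dot(a, b) / (na * nb))


def subset_unit_norm(w: np.ndarray, idx: Sequence[int]) -> np.ndarray:
    """Restrict a synergy to the shared muscles and rescale to unit norm.

    Raises if the restriction is all zero (similarity undefined there).
    """
    w = np.asarray(w, dtype=float)
    idx = np.asarray(idx, dtype=int)
    if idx.size == 0:
        raise ValueError("shared-muscle index set is empty")
    sub = w[idx]
    n = np.linalg.norm(sub)
    if n == 0.0:
        raise ValueError("synergy has all-zero loads on the shared muscles")
    return sub / n


def match_synergies(
    W_A: np.ndarray,
    W_B: np.ndarray,
    shared_idx_A: Sequence[int] | None = None,
    shared_idx_B: Sequence[int] | None = None,
) -> MatchReport:
    """Pair the columns of two synergy matrices by cosine similarity on
    the shared muscles.

    Similarities are computed between subset-renormalized columns (each
    column restricted to its condition's shared-muscle rows and rescaled
    to unit norm).  Pairing is the optimal one-to-one assignment that
    maximizes total similarity (Hungarian algorithm); leftover columns of
    the larger set are reported as additional synergies.  Columns whose
    shared-subset loads are all zero are excluded from the assignment and
    reported, not scored as zero.
    """
    W_A = np.atleast_2d(np.asarray(W_A, dtype=float))
    W_B = np.atleast_2d(np.asarray(W_B, dtype=float))
    if shared_idx_A is None:
        shared_idx_A = np.arange(W_A.shape[0])
    if shared_idx_B is None:
        shared_idx_B = np.arange(W_B.shape[0])
    shared_idx_A = np.asarray(shared_idx_A, dtype=int)
    shared_idx_B = np.asarray(shared_idx_B, dtype=int)
    if shared_idx_A.size != shared_idx_B.size:
        raise ValueError(
            f"shared index sets differ in size: {shared_idx_A.size} vs {shared_idx_B.size}"
        )

    def _subsets(W: np.ndarray, idx: np.ndarray) -> tuple[list[np.ndarray | None], list[int]]:
        cols: list[np.ndarray | None] = []
        degenerate: list[int] = []
        for j in range(W.shape[1]):
            sub = W[idx, j]
            if np.linalg.norm(sub) == 0.0:
                cols.append(None)
                degenerate.append(j)
            else:
                cols.append(sub / np.linalg.norm(sub))
        return cols, degenerate

    cols_A, degen_A = _subsets(W_A, shared_idx_A)
    cols_B, degen_B = _subsets(W_B, shared_idx_B)
    valid_A = [j for j in range(W_A.shape[1]) if j not in degen_A]
    valid_B = [j for j in range(W_B.shape[1]) if j not in degen_B]

    sim = np.zeros((len(valid_A), len(valid_B)))
    for i, ja in enumerate(valid_A):
        for k, jb in enumerate(valid_B):
            sim[i, k] = float(np.dot(cols_A[ja], cols_B[jb]))

    if sim.size:
        rows, cols = linear_sum_assignment(sim, maximize=True)
    else:
        rows, cols = np.array([], dtype=int), np.array([], dtype=int)

    pairs = [(valid_A[i], valid_B[k]) for i, k in zip(rows, cols)]
    sims = [float(sim[i, k]) for i, k in zip(rows, cols)]
    matched_A = {p[0] for p in pairs}
    matched_B = {p[1] for p in pairs}
    unmatched_A = [j for j in range(W_A.shape[1]) if j not in matched_A and j not in degen_A]
    unmatched_B = [j for j in range(W_B.shape[1]) if j not in matched_B and j not in degen_B]
    excluded = [(j, -1) for j in degen_A] + [(-1, j) for j in degen_B]
    return MatchReport(
        pairs=pairs, similarities=sims,
        unmatched_A=unmatched_A, unmatched_B=unmatched_B,
        excluded_pairs=excluded,
    )
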