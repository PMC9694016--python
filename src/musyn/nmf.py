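"""Spatial-synergy extraction by non-negative matrix factorization.

The model approximates a pooled nonnegative activation matrix
``V`` (M muscles x K*T samples) as ``W @ C`` with ``W >= 0`` (M x S muscle
loads) and ``C >= 0`` (S x K*T temporal coefficients).  Factorization uses
the classical multiplicative updates for the squared Frobenius loss, run
from many random initializations; the restart with the highest
reconstruction R-squared is kept.  Spatial synergies are reported with unit
Euclidean norm, with the norms folded into the temporal coefficients so the
reconstruction is unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np

__all__ = [
    "SynergyDecomposition",
    "DegenerateDataError",
    "r_squared",
    "normalize_decomposition",
    "nmf_factorize",
]

#: guard added to update denominators to avoid division by zero
_EPS = 1e-12


class DegenerateDataError(ValueError):
    """Raised when a quantity is undefined for the given data (e.g. the
    R-squared of a matrix with zero variance)."""


@dataclass
class SynergyDecomposition:
    """Result of a best-of-restarts NMF factorization.

    ``W`` columns are unit Euclidean norm (all-zero columns are left as-is
    and listed in ``zero_columns``); ``C`` carries the amplitude.  ``r2``
    is the reconstruction R-squared of the best restart.
    """

    W: np.ndarray
    C: np.ndarray
    order: int
    r2: float
    restarts_used: int
    best_restart_seed: int
    iterations: int = 0
    converged: bool = True
    zero_columns: list[int] = field(default_factory=list)

    def reconstruction(self) -> np.ndarray:
        return self.W @ self.C

    def to_dict(self) -> dict:
        return {
            "W": self.W.tolist(),
            "C": self.C.tolist(),
            "order": self.order,
            "r2": self.r2,
            "restarts_used": self.restarts_used,
            "best_restart_seed": self.best_restart_seed,
            "iterations": self.iterations,
            "converged": self.converged,
            "zero_columns": self.zero_columns,
        }


def r_squared(
    V: np.ndarray,
    V_hat: np.ndarray,
    mean: Literal["row", "global"] = "row",
) -> float:
    """Reconstruction R-squared, ``1 - SSE/SST``.

    SSE is the sum of squared residuals ``(V - V_hat)**2``.  SST is the sum
    of squared deviations of ``V`` from its mean vector: with
    ``mean="row"`` (default) each muscle is compared to its own mean across
    all samples; ``mean="global"`` uses the single scalar mean of the whole
    matrix.

    Raises
    ------
    DegenerateDataError
        If SST is zero (constant data), where the score is undefined.
    """
    V = np.asarray(V, dtype=float)
    V_hat = np.asarray(V_hat, dtype=float)
    if V.shape != V_hat.shape:
        raise ValueError(f"shape mismatch: {V.shape} vs {V_hat.shape}")
    sse = float(np.sum((V - V_hat) ** 2))
    if mean == "row":
        centered = V - V.mean(axis=-1, keepdims=True)
    elif mean == "global":
        centered = V - V.mean()
    else:
        raise ValueError(f"unknown mean convention {mean!r}")
    sst = float(np.sum(centered**2))
    if sst == 0.0:
        raise DegenerateDataError("SST is zero: R-squared undefined for constant data")
    return 1.0 - sse / sst


def normalize_decomposition(
    W: np.ndarray, C: np.ndarray
) -> tuple[np.ndarray, np.ndarray, list[int]]:
    """Rescale each synergy to unit Euclidean norm, folding the norm into
    its temporal coefficient row so that ``W @ C`` is unchanged.

    All-zero columns cannot be normalized; they are left untouched and
    their indices returned.
    """
    W = np.asarray(W, dtype=float)
    C = np.asarray(C, dtype=float)
    norms = np.linalg.norm(W, axis=0)
    zero_cols = [int(i) for i in np.flatnonzero(norms == 0.0)]
    safe = np.where(norms == 0.0, 1.0, norms)
    return W / safe, C * safe[:, None], zero_cols


def _multiplicative_nmf(
    V: np.ndarray,
    S: int,
    rng: np.random.Generator,
    max_iter: int,
    tol: float,
    track_objective: bool = False,
) -> tuple[np.ndarray, np.ndarray, int, bool, list[float]]:
    """One NMF run with Lee-Seung multiplicative updates for the squared
    Frobenius loss, from an entrywise uniform random positive init.

    Stops when the relative change of the squared error between sweeps is
    below ``tol`` or after ``max_iter`` sweeps.  Returns (W, C, n_iter,
    converged, objective_trace); the trace is filled only when requested.
    """
    M, N = V.shape
    scale = np.sqrt(max(V.mean(), _EPS) / S)
    W = rng.uniform(0.1, 1.0, size=(M, S)) * scale
    C = rng.uniform(0.1, 1.0, size=(S, N)) * scale

    trace: list[float] = []
    prev_err = np.inf
    n_iter = 0
    converged = False
    for n_iter in range(1, max_iter + 1):
        # C <- C * (W^T V) / (W^T W C)
        C *= (W.T @ V) / (W.T @ W @ C + _EPS)
        # W <- W * (V C^T) / (W C C^T)
        CCt = C @ C.T
        W *= (V @ C.T) / (W @ CCt + _EPS)
        err = float(np.sum((V - W @ C) ** 2))
        if track_objective:
            trace.append(err)
        if prev_err < np.inf:
            denom = prev_err if prev_err > 0 else _EPS
            if abs(prev_err - err) / denom < tol:
                converged = True
                prev_err = err
                break
        prev_err = err
    return W, C, n_iter, converged, trace


def nmf_factorize(
    V: np.ndarray,
    S: int,
    restarts: int = 200,
    max_iter: int = 1000,
    tol: float = 1e-6,
    seed: int = 0,
    r2_mean: Literal["row", "global"] = "row",
) -> SynergyDecomposition:
    """Factorize a pooled activation matrix into ``S`` spatial synergies.

    The multiplicative-update algorithm is restarted ``restarts`` times
    from independent random initializations (restart index folded into the
    seed) and the restart with the highest reconstruction R-squared wins;
    ties break to the lowest restart index.  The returned ``W`` has
    unit-norm columns with the norms moved into ``C``.

    Parameters
    ----------
    V:
        Nonnegative matrix, M muscles x N samples.
    S:
        Factorization order, ``1 <= S <= M``.
    restarts:
        Number of random restarts (200 by default, which is ample to
        escape local minima on pooled reaching data; reduce for quick runs).
    seed:
        Master seed; every restart derives its own stream from it.
    """
    V = np.asarray(V, dtype=float)
    if V.ndim != 2:
        raise ValueError("V must be a 2-D matrix")
    M = V.shape[0]
    if not 1 <= S <= M:
        raise ValueError(f"order S={S} must satisfy 1 <= S <= M={M}")
    if np.any(V < 0):
        raise ValueError("V must be nonnegative")
    if restarts < 1:
        raise ValueError("restarts must be >= 1")
    if not np.any(V):
        raise DegenerateDataError("V is all zeros: factorization degenerate (SST = 0)")

    best: SynergyDecomposition | None = None
    for r in range(restarts):
        rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence([seed, r])))
        W, C, n_iter, converged, _ = _multiplicative_nmf(V, S, rng, max_iter, tol)
        r2 = r_squared(V, W @ C, mean=r2_mean)
        if best is None or r2 > best.r2 + 0.0:  # strict: ties keep earliest restart
            W_unit, C_resc, zero_cols = normalize_decomposition(W, C)
            best = SynergyDecomposition(
                W=W_unit, C=C_resc, order=S, r2=r2,
                restarts_used=restarts, best_restart_seed=r,
                iterations=n_iter, converged=converged, zero_columns=zero_cols,
            )
    assert best is not None
    return best
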