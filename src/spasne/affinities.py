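"""Pairwise-similarity matrices compared by the embedding loss terms.

Five matrices are involved:

* ``P``  — local Gaussian-kernel affinities of the expression vectors,
  with per-point bandwidths calibrated to a target perplexity and then
  symmetrized,
* ``Q``  — Student-t affinities of the embedding points,
* ``P_hat`` — distance-proportional ("global") affinities of expression,
* ``Q_hat`` — distance-proportional affinities of the embedding,
* ``S_hat`` — distance-proportional affinities of the spatial positions.

Each is symmetric, zero-diagonal, nonnegative, with off-diagonal entries
summing to 1, so any pair can be compared by a KL divergence. The global
matrices weight pairs *directly* by ``1 + squared distance``, which makes
them sensitive to large-scale structure — the opposite regime from the
local Gaussian/Student-t kernels.

All computations are exact and dense, O(N^2) in memory and time.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.spatial.distance import pdist, squareform

__all__ = [
    "EPS",
    "SpatialCoords",
    "AffinitySet",
    "EmbeddingAffinities",
    "conditional_affinities",
    "symmetrize",
    "student_t_affinities",
    "global_affinities",
    "kl_divergence",
    "squared_distances",
    "scale_coords",
]

# floor applied to affinity entries before logs/divisions
EPS = 1e-12


@dataclass
class SpatialCoords:
    """Cells x 2 image coordinates, arbitrary length units.

    Row order must match the expression matrix the coordinates accompany.
    """

    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] != 2:
            raise ValueError("spatial coordinates must be cells x 2")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("spatial coordinates contain non-finite entries")


@dataclass
class AffinitySet:
    """The input-side affinity matrices of one embedding problem."""

    P: np.ndarray
    P_hat: np.ndarray
    S_hat: Optional[np.ndarray]
    sigmas: np.ndarray


@dataclass
class EmbeddingAffinities:
    """Embedding-side affinities recomputed from the current layout."""

    Q: np.ndarray
    Q_hat: np.ndarray


def squared_distances(V: np.ndarray) -> np.ndarray:
    """Dense matrix of pairwise squared Euclidean distances."""
    V = np.asarray(V, dtype=float)
    if not np.all(np.isfinite(V)):
        raise ValueError("non-finite coordinates")
    return squareform(pdist(V, metric="sqeuclidean"))


def scale_coords(Z: np.ndarray) -> np.ndarray:
    """Center coordinates and scale to unit root-mean-square radius.

    The distance-proportional affinities are not scale-invariant, so raw
    pixel/micron units would silently set the strength of the spatial
    term. Rescaling to unit RMS radius makes the spatial weight ``beta``
    comparable across platforms.
    """
    Z = np.asarray(Z, dtype=float)
    Zc = Z - Z.mean(axis=0)
    rms = np.sqrt(np.mean(np.sum(Zc**2, axis=1)))
    if rms == 0:
        return Zc
    return Zc / rms


def _row_entropy_bits(p: np.ndarray) -> float:
    nz = p[p > 0]
    return float(-np.sum(nz * np.log2(nz)))


def conditional_affinities(
    X: np.ndarray,
    perplexity: float = 50.0,
    tol: float = 1e-5,
    max_iter: int = 50,
) -> tuple[np.ndarray, np.ndarray]:
    """Row-stochastic Gaussian affinities at a fixed perplexity.

    For each point ``i`` the conditional distribution over ``j != i`` is
    ``p_{j|i} ∝ exp(-||x_i - x_j||^2 / (2 sigma_i^2))`` with ``sigma_i``
    found by binary search so that ``2^H(p_{.|i}) = perplexity`` (Shannon
    entropy in bits). The bracket on the precision ``1/(2 sigma_i^2)`` is
    expanded geometrically before bisection.

    Returns
    -------
    P_cond : ndarray (N, N)
        Rows sum to 1, zero diagonal.
    sigmas : ndarray (N,)
        Calibrated per-point bandwidths.
    """
    X = np.asarray(X, dtype=float)
    N = X.shape[0]
    if N < 3:
        raise ValueError("need at least 3 points")
    if not (1.0 < perplexity < N):
        raise ValueError(f"perplexity must be in (1, N={N}), got {perplexity}")
    D = squared_distances(X)
    target = np.log2(perplexity)
    P = np.zeros((N, N))
    sigmas = np.empty(N)
    for i in range(N):
        d = np.delete(D[i], i)
        beta, lo, hi = 1.0, 0.0, np.inf
        p = np.empty_like(d)
        for _ in range(max_iter):
            # shift by the min distance for numerical stability
            w = np.exp(-(d - d.min()) * beta)
            p = w / w.sum()
            H = _row_entropy_bits(p)
            if abs(H - target) < tol:
                break
            if H > target:  # too flat -> narrow the kernel
                lo = beta
                beta = beta * 2.0 if not np.isfinite(hi) else (lo + hi) / 2.0
            else:
                hi = beta
                beta = beta / 2.0 if lo == 0.0 else (lo + hi) / 2.0
        P[i, np.arange(N) != i] = p
        sigmas[i] = np.sqrt(1.0 / (2.0 * beta))
    return P, sigmas


def symmetrize(P_cond: np.ndarray) -> np.ndarray:
    """Joint affinities ``p_ij = (p_{i|j} + p_{j|i}) / (2N)``.

    Total off-diagonal mass is exactly 1 when every row of the input sums
    to 1.
    """
    P_cond = np.asarray(P_cond, dtype=float)
    if P_cond.ndim != 2 or P_cond.shape[0] != P_cond.shape[1]:
        raise ValueError("conditional affinity matrix must be square")
    N = P_cond.shape[0]
    return (P_cond + P_cond.T) / (2.0 * N)


def student_t_affinities(Y: np.ndarray) -> np.ndarray:
    """Normalized Student-t (1 df) kernel ``q_ij ∝ (1 + ||y_i-y_j||^2)^-1``."""
    D = squared_distances(Y)
    W = 1.0 / (1.0 + D)
    np.fill_diagonal(W, 0.0)
    return W / W.sum()


def global_affinities(V: np.ndarray) -> np.ndarray:
    """Distance-proportional affinities ``∝ 1 + ||v_i - v_j||^2``.

    Larger distance means larger affinity — direct, not inverse,
    weighting — so the KL term built on these matrices responds to
    large-scale distance variations. Self-pairs carry no structure: the
    diagonal is zeroed and normalization runs over ``i != j``.
    """
    D = squared_distances(V)
    W = 1.0 + D
    np.fill_diagonal(W, 0.0)
    return W / W.sum()


def kl_divergence(A: np.ndarray, B: np.ndarray) -> float:
    """``sum_ij a_ij log(a_ij / b_ij)`` with zero-mass terms dropped.

    ``B`` entries are floored at :data:`EPS` before the division to avoid
    infinities. Nonnegative whenever both arguments sum to 1 (Gibbs'
    inequality).
    """
    A = np.asarray(A, dtype=float)
    B = np.asarray(B, dtype=float)
    if A.shape != B.shape:
        raise ValueError(f"shape mismatch: {A.shape} vs {B.shape}")
    mask = A > 0
    a = A[mask]
    b = np.maximum(B[mask], EPS)
    return float(np.sum(a * np.log(a / b)))
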