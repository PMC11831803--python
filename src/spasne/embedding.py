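"""Spatially resolved t-SNE: three-term KL loss and its gradient descent.

The embedding minimizes

    L_total = L_t + alpha * L_g + beta * L_s

where ``L_t = KL(P || Q)`` is the classic t-SNE local loss, ``L_g =
KL(P_hat || Q_hat)`` pulls the embedding's large-scale distances toward
those of expression space, and ``L_s = KL(S_hat || Q_hat)`` toward those
of the tissue image. The gradient with respect to each embedding point
has the closed form

    4 * sum_j [ (p_ij - q_ij) - alpha (p̂_ij - q̂_ij) - beta (ŝ_ij - q̂_ij) ]
            * (y_i - y_j) / (1 + ||y_i - y_j||^2)

which reduces to the plain t-SNE gradient when both weights are zero.

Optimization follows the reference t-SNE schedule: momentum gradient
descent with adaptive per-coordinate gains, early exaggeration of the
local affinities, and a fixed iteration budget as the only stopping rule.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from typing import Optional, Union

import numpy as np

from .affinities import (
    AffinitySet,
    SpatialCoords,
    conditional_affinities,
    global_affinities,
    kl_divergence,
    scale_coords,
    squared_distances,
    student_t_affinities,
    symmetrize,
)
from .preprocess import ExpressionMatrix, reduce_pca

__all__ = [
    "EmbedConfig",
    "LossBreakdown",
    "EmbeddingResult",
    "initialize_embedding",
    "spasne_gradient",
    "spasne_loss",
    "spasne_embed",
    "tsne_embed",
]

logger = logging.getLogger("spasne")

# default loss weights: (alpha, beta) with / without spatial information
DEFAULT_WEIGHTS_SPATIAL = (10.0, 5.0)
DEFAULT_WEIGHTS_NO_SPATIAL = (5.0, 0.0)


@dataclass
class EmbedConfig:
    """Configuration of one embedding run.

    ``alpha`` weights the global expression loss and ``beta`` the spatial
    loss; left as ``None`` they resolve to (10, 5) when spatial
    coordinates are supplied and (5, 0) otherwise. The optimizer fields
    follow the reference t-SNE lineage: learning rate 200, momentum 0.5
    switching to 0.8 at iteration 250, and x12 early exaggeration of the
    local affinities for the first 250 iterations.
    """

    alpha: Optional[float] = None
    beta: Optional[float] = None
    perplexity: float = 50.0
    max_iter: int = 1000
    out_dim: int = 2
    seed: int = 0
    init_dim: int = 50
    learning_rate: float = 200.0
    momentum_early: float = 0.5
    momentum_late: float = 0.8
    momentum_switch_iter: int = 250
    exaggeration_factor: float = 12.0
    exaggeration_iters: int = 250
    init_scale: float = 1e-4
    init_jitter: float = 1e-4
    scale_spatial: bool = True
    record_every: int = 50

    def __post_init__(self) -> None:
        if self.alpha is not None and self.alpha < 0:
            raise ValueError("alpha must be nonnegative")
        if self.beta is not None and self.beta < 0:
            raise ValueError("beta must be nonnegative")
        if self.perplexity <= 0:
            raise ValueError("perplexity must be positive")
        if self.max_iter < 1:
            raise ValueError("max_iter must be positive")
        if self.out_dim not in (2, 3):
            raise ValueError("out_dim must be 2 or 3")


@dataclass
class LossBreakdown:
    """Loss components at one recorded iteration.

    ``L_total = L_t + alpha*L_g + beta*L_s`` (an absent spatial term
    contributes zero).
    """

    L_t: float
    L_g: float
    L_s: Optional[float]
    L_total: float
    iteration: int = 0

    def to_dict(self) -> dict:
        return {
            "iteration": self.iteration,
            "L_t": self.L_t,
            "L_g": self.L_g,
            "L_s": self.L_s,
            "L_total": self.L_total,
        }


@dataclass
class EmbeddingResult:
    """A finished embedding with its optimization record."""

    Y: np.ndarray
    loss_history: list = field(default_factory=list)
    config: Optional[EmbedConfig] = None
    converged: bool = False


ArrayLike = Union[np.ndarray, ExpressionMatrix]


def _values(X: ArrayLike) -> np.ndarray:
    if isinstance(X, ExpressionMatrix):
        return X.values
    return np.asarray(X, dtype=float)


def _coord_values(Z) -> np.ndarray:
    if isinstance(Z, SpatialCoords):
        return Z.values
    return np.asarray(Z, dtype=float)


def initialize_embedding(X: ArrayLike, cfg: EmbedConfig) -> np.ndarray:
    """Initial layout from a truncated principal-component decomposition.

    The top ``init_dim`` PC scores of X are computed (clipped to the rank
    bound), the first ``out_dim`` columns are kept and rescaled so the
    leading column has standard deviation ``init_scale`` (1e-4 by
    default, the usual t-SNE starting magnitude; scaling by the leading
    column keeps the scores' aspect ratio). Seeded Gaussian jitter of
    scale ``init_jitter`` is then added so that repeated runs with
    distinct seeds explore distinct optima. Deterministic given
    (X, seed).
    """
    Xv = _values(X)
    n, p = Xv.shape
    rng = np.random.default_rng(cfg.seed)
    k = min(cfg.init_dim, n, p)
    m = ExpressionMatrix(Xv)
    scores = reduce_pca(m, k).values[:, : cfg.out_dim]
    if scores.shape[1] < cfg.out_dim:
        logger.warning(
            "rank %d below out_dim %d; padding initialization with noise",
            scores.shape[1],
            cfg.out_dim,
        )
        pad = rng.normal(0.0, 1.0, size=(n, cfg.out_dim - scores.shape[1]))
        scores = np.hstack([scores, pad])
    sd0 = scores[:, 0].std()
    Y0 = scores / (sd0 if sd0 > 0 else 1.0) * cfg.init_scale
    if cfg.init_jitter > 0:
        Y0 = Y0 + rng.normal(0.0, cfg.init_jitter, size=Y0.shape)
    return Y0


def _embedding_kernels(Y: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Return (W, Q, Q_hat) with W the zero-diagonal Student-t kernel."""
    D = squared_distances(Y)
    W = 1.0 / (1.0 + D)
    np.fill_diagonal(W, 0.0)
    Q = W / W.sum()
    G = 1.0 + D
    np.fill_diagonal(G, 0.0)
    Q_hat = G / G.sum()
    return W, Q, Q_hat


def spasne_loss(
    P: np.ndarray,
    P_hat: np.ndarray,
    S_hat: Optional[np.ndarray],
    Y: np.ndarray,
    alpha: float,
    beta: float,
    iteration: int = 0,
) -> LossBreakdown:
    """Evaluate the three loss components at the current layout."""
    _, Q, Q_hat = _embedding_kernels(Y)
    L_t = kl_divergence(P, Q)
    L_g = kl_divergence(P_hat, Q_hat)
    if S_hat is not None:
        L_s: Optional[float] = kl_divergence(S_hat, Q_hat)
        total = L_t + alpha * L_g + beta * L_s
    else:
        L_s = None
        total = L_t + alpha * L_g
    return LossBreakdown(L_t, L_g, L_s, total, iteration)


def spasne_gradient(
    P: np.ndarray,
    P_hat: np.ndarray,
    S_hat: Optional[np.ndarray],
    Y: np.ndarray,
    alpha: float,
    beta: float,
) -> np.ndarray:
    """Closed-form gradient of the total loss with respect to Y.

    ``Q`` and ``Q_hat`` are recomputed from the current layout. With
    ``alpha = beta = 0`` this is exactly the t-SNE gradient.
    """
    Y = np.asarray(Y, dtype=float)
    N = Y.shape[0]
    for name, M in (("P", P), ("P_hat", P_hat), ("S_hat", S_hat)):
        if M is not None and M.shape != (N, N):
            raise ValueError(f"{name} has shape {M.shape}, expected {(N, N)}")
    if beta != 0.0 and S_hat is None:
        raise ValueError("beta > 0 requires the spatial affinity matrix")
    W, Q, Q_hat = _embedding_kernels(Y)
    M = (P - Q) - alpha * (P_hat - Q_hat)
    if S_hat is not None:
        M = M - beta * (S_hat - Q_hat)
    A = M * W  # zero diagonal via W
    # 4 * sum_j A_ij (y_i - y_j)
    return 4.0 * (Y * A.sum(axis=1)[:, None] - A @ Y)


def _resolve_weights(cfg: EmbedConfig, has_spatial: bool) -> tuple[float, float]:
    default = DEFAULT_WEIGHTS_SPATIAL if has_spatial else DEFAULT_WEIGHTS_NO_SPATIAL
    alpha = default[0] if cfg.alpha is None else float(cfg.alpha)
    beta = default[1] if cfg.beta is None else float(cfg.beta)
    return alpha, beta


def compute_input_affinities(
    X: ArrayLike,
    Z=None,
    cfg: Optional[EmbedConfig] = None,
) -> AffinitySet:
    """Build the input-side affinity matrices P, P_hat and (optionally) S_hat.

    Spatial coordinates are centered and rescaled to unit RMS radius
    first (configurable): the distance-proportional kernel is not
    scale-invariant, so raw image units would otherwise leak into the
    loss weighting.
    """
    cfg = cfg or EmbedConfig()
    Xv = _values(X)
    N = Xv.shape[0]
    perplexity = cfg.perplexity
    if N < 3 * perplexity:
        clipped = (N - 1) / 3.0
        warnings.warn(
            f"perplexity {perplexity} too large for N={N}; clipped to {clipped:.2f}",
            stacklevel=2,
        )
        perplexity = clipped
    P_cond, sigmas = conditional_affinities(Xv, perplexity)
    P = symmetrize(P_cond)
    P_hat = global_affinities(Xv)
    S_hat = None
    if Z is not None:
        Zv = _coord_values(Z)
        if Zv.shape[0] != N:
            raise ValueError("spatial coordinates row count does not match X")
        if cfg.scale_spatial:
            Zv = scale_coords(Zv)
        S_hat = global_affinities(Zv)
    return AffinitySet(P=P, P_hat=P_hat, S_hat=S_hat, sigmas=sigmas)


def spasne_embed(
    X: ArrayLike,
    Z=None,
    cfg: Optional[EmbedConfig] = None,
) -> EmbeddingResult:
    """Embed expression (and optionally spatial) structure into 2-D/3-D.

    Runs momentum gradient descent on the three-term loss for exactly
    ``max_iter`` iterations (the only stopping rule), with early
    exaggeration applied to the local affinities P only — the global
    terms define the method's alpha/beta semantics and are never
    exaggerated. The loss is recorded every ``record_every`` iterations
    using the un-exaggerated P, so recorded values are comparable across
    the schedule. Deterministic for a fixed seed.
    """
    cfg = cfg or EmbedConfig()
    Xv = _values(X)
    has_spatial = Z is not None
    alpha, beta = _resolve_weights(cfg, has_spatial)
    if beta > 0 and Z is None:
        raise ValueError("beta > 0 requires spatial coordinates")
    cfg = replace(cfg, alpha=alpha, beta=beta)

    aff = compute_input_affinities(Xv, Z if beta > 0 or has_spatial else None, cfg)
    P, P_hat = aff.P, aff.P_hat
    S_hat = aff.S_hat if beta > 0 else None

    Y = initialize_embedding(Xv, cfg)
    inc = np.zeros_like(Y)
    gains = np.ones_like(Y)
    history: list[LossBreakdown] = []

    # The gradient magnitude grows with the total loss weight 1 + alpha +
    # beta; rescale the step so each loss term sees the step size the
    # reference schedule was tuned for. Without this, large weights make
    # lr=200 overshoot and the layout never settles.
    step = cfg.learning_rate / (1.0 + alpha + beta)

    for it in range(cfg.max_iter):
        P_eff = P * cfg.exaggeration_factor if it < cfg.exaggeration_iters else P
        grad = spasne_gradient(P_eff, P_hat, S_hat, Y, alpha, beta)
        momentum = (
            cfg.momentum_early if it < cfg.momentum_switch_iter else cfg.momentum_late
        )
        same_sign = np.sign(grad) == np.sign(inc)
        gains = np.where(same_sign, gains * 0.8, gains + 0.2)
        np.clip(gains, 0.01, None, out=gains)
        inc = momentum * inc - step * gains * grad
        Y = Y + inc
        Y = Y - Y.mean(axis=0)
        if (it + 1) % cfg.record_every == 0 or it == cfg.max_iter - 1:
            history.append(spasne_loss(P, P_hat, S_hat, Y, alpha, beta, it + 1))

    return EmbeddingResult(Y=Y, loss_history=history, config=cfg, converged=True)


def tsne_embed(X: ArrayLike, cfg: Optional[EmbedConfig] = None) -> EmbeddingResult:
    """Plain t-SNE within this implementation: both global weights zero."""
    cfg = cfg or EmbedConfig()
    cfg = replace(cfg, alpha=0.0, beta=0.0)
    return spasne_embed(X, None, cfg)
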