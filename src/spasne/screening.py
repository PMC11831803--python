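"""Two-stage (alpha, beta) screening and final-embedding selection.

The weights alpha (global expression) and beta (spatial) trade off
against each other — raising alpha raises r_g at the expense of r_s and
vice versa — and large values destabilize the embedding by drowning out
the local term. The screening protocol picks a combination empirically:

1. Run repeated plain t-SNE; the maximum observed r_g is the threshold
   ``r_thres`` that a useful run must beat.
2. Rough screen on a coarse grid (default alpha in {2,5,10,20,30,50},
   beta in {1,5,10,15,25}), 10 repeats per cell; per repeat, r_g is
   zeroed if it fails the threshold, and the repeat maximizing r_g*r_s
   defines the cell's (r_g_opt, r_s_opt).
3. Fine screen on a denser grid around the rough optimum (default alpha
   5..20, beta 1..10), 20 repeats per cell, additionally recording the
   standard deviation of the (thresholded) r_g values as a stability
   penalty.
4. Choose the cell maximizing r_g_opt * r_s_opt * exp(1 - std).
5. Re-run many repeats at the chosen weights and keep the embedding with
   the largest r_g * r_s.

Every repeat uses a seed derived arithmetically from the base seed, the
stage, the grid-cell index and the repeat index, so reports are exactly
reproducible and cells are independent.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .embedding import (
    DEFAULT_WEIGHTS_SPATIAL,
    EmbedConfig,
    EmbeddingResult,
    spasne_embed,
    tsne_embed,
)
from .metrics import QualityScores, distance_correlation, evaluate

__all__ = [
    "ROUGH_ALPHAS",
    "ROUGH_BETAS",
    "FINE_ALPHAS",
    "FINE_BETAS",
    "ScreeningGrid",
    "CellResult",
    "ScreeningReport",
    "repeat_seed",
    "compute_threshold",
    "select_optimal_repeat",
    "screen_cell",
    "rough_screen",
    "select_fine_grid",
    "fine_screen",
    "choose_cell",
    "final_embedding",
    "screen",
]

logger = logging.getLogger("spasne")

# preset grids for the two screening stages
ROUGH_ALPHAS = (2.0, 5.0, 10.0, 20.0, 30.0, 50.0)
ROUGH_BETAS = (1.0, 5.0, 10.0, 15.0, 25.0)
FINE_ALPHAS = tuple(float(a) for a in range(5, 21))
FINE_BETAS = tuple(float(b) for b in range(1, 11))

# arithmetic seed schedule: distinct stages live in distinct blocks
_STAGE_OFFSET = {"threshold": 0, "rough": 1, "fine": 2, "final": 3}


@dataclass
class ScreeningGrid:
    """A grid of candidate (alpha, beta) cells and a repeat count."""

    alphas: Sequence[float]
    betas: Sequence[float]
    repeats: int = 10

    def __post_init__(self) -> None:
        if len(self.alphas) == 0 or len(self.betas) == 0:
            raise ValueError("grid must be nonempty")
        if self.repeats < 1:
            raise ValueError("repeats must be >= 1")

    def cells(self) -> list:
        return [(float(a), float(b)) for a in self.alphas for b in self.betas]


@dataclass
class CellResult:
    """Screening outcome of one (alpha, beta) cell."""

    alpha: float
    beta: float
    r_g_opt: float
    r_s_opt: float
    std: float
    score: float = 0.0


@dataclass
class ScreeningReport:
    """Fine-stage table plus the selected parameter combination."""

    r_thres: float
    cells: list = field(default_factory=list)
    chosen: tuple = (0.0, 0.0)
    rough_cells: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "r_thres": self.r_thres,
            "chosen": list(self.chosen),
            "cells": [vars(c) for c in self.cells],
            "rough_cells": [vars(c) for c in self.rough_cells],
        }


def repeat_seed(base_seed: int, stage: str, cell_index: int, repeat: int) -> int:
    """Stable arithmetic seed for repeat ``repeat`` of grid cell ``cell_index``.

    seed = base + 100_000 * stage_id + 1_000 * cell_index + repeat, kept
    below 2**31. No hashing: the schedule is documented and auditable.
    """
    s = base_seed + 100_000 * _STAGE_OFFSET[stage] + 1_000 * cell_index + repeat
    return int(s % (2**31))


def compute_threshold(
    X: np.ndarray,
    cfg: Optional[EmbedConfig] = None,
    n_repeats: int = 100,
) -> float:
    """Maximum r_g over repeated plain t-SNE runs (the screening floor)."""
    cfg = cfg or EmbedConfig()
    if n_repeats < 1:
        raise ValueError("n_repeats must be >= 1")
    best = -np.inf
    for r in range(n_repeats):
        run_cfg = replace(cfg, seed=repeat_seed(cfg.seed, "threshold", 0, r))
        res = tsne_embed(X, run_cfg)
        best = max(best, distance_correlation(X, res.Y))
    return float(best)


def select_optimal_repeat(
    metrics: Sequence[tuple], r_thres: float, std_on_thresholded: bool = True
) -> tuple:
    """Apply the thresholding/selection arithmetic to per-repeat (r_g, r_s).

    Each repeat's r_g is replaced by 0 when r_g <= r_thres; the repeat
    maximizing r_g * r_s wins (first index on ties). Returns
    (r_g_opt, r_s_opt, std, best_index) where std is the standard
    deviation of the (by default thresholded) r_g values.
    """
    if len(metrics) == 0:
        raise ValueError("no repeats supplied")
    raw_rg = np.array([m[0] for m in metrics], dtype=float)
    rs = np.array([m[1] for m in metrics], dtype=float)
    rg = np.where(raw_rg <= r_thres, 0.0, raw_rg)
    products = rg * rs
    best = int(np.argmax(products))
    std = float(np.std(rg if std_on_thresholded else raw_rg))
    return float(rg[best]), float(rs[best]), std, best


def screen_cell(
    X: np.ndarray,
    Z: np.ndarray,
    alpha: float,
    beta: float,
    repeats: int,
    r_thres: float,
    cfg: Optional[EmbedConfig] = None,
    stage: str = "rough",
    cell_index: int = 0,
    std_on_thresholded: bool = True,
) -> tuple:
    """Repeat SpaSNE at one (alpha, beta) and summarize as (r_g_opt, r_s_opt, std)."""
    cfg = cfg or EmbedConfig()
    metrics = []
    for r in range(repeats):
        run_cfg = replace(
            cfg,
            alpha=alpha,
            beta=beta,
            seed=repeat_seed(cfg.seed, stage, cell_index, r),
        )
        res = spasne_embed(X, Z, run_cfg)
        metrics.append(
            (distance_correlation(X, res.Y), distance_correlation(Z, res.Y))
        )
    rg, rs, std, _ = select_optimal_repeat(metrics, r_thres, std_on_thresholded)
    return rg, rs, std


def rough_screen(
    X: np.ndarray,
    Z: np.ndarray,
    grid: Optional[ScreeningGrid] = None,
    r_thres: float = 0.0,
    cfg: Optional[EmbedConfig] = None,
) -> list:
    """Coarse-grid screen; each cell's score is r_g_opt * r_s_opt."""
    grid = grid or ScreeningGrid(ROUGH_ALPHAS, ROUGH_BETAS, repeats=10)
    out = []
    for idx, (a, b) in enumerate(grid.cells()):
        rg, rs, std = screen_cell(
            X, Z, a, b, grid.repeats, r_thres, cfg, stage="rough", cell_index=idx
        )
        out.append(CellResult(a, b, rg, rs, std, score=rg * rs))
    return out


def select_fine_grid(
    rough_cells: Sequence[CellResult],
    repeats: int = 20,
    frac: float = 0.8,
    alpha_step: float = 1.0,
    beta_step: float = 1.0,
) -> ScreeningGrid:
    """Automate the fine-grid choice from the rough heatmap.

    The fine range is the bounding box of rough cells scoring within
    ``frac`` of the best rough score, expanded by one rough grid step and
    discretized at unit resolution.
    """
    scores = np.array([c.score for c in rough_cells])
    best = scores.max()
    if best <= 0:
        return ScreeningGrid(FINE_ALPHAS, FINE_BETAS, repeats)
    keep = [c for c, s in zip(rough_cells, scores) if s >= frac * best]
    alphas = sorted({c.alpha for c in rough_cells})
    betas = sorted({c.beta for c in rough_cells})
    a_lo, a_hi = min(c.alpha for c in keep), max(c.alpha for c in keep)
    b_lo, b_hi = min(c.beta for c in keep), max(c.beta for c in keep)
    # expand by one step of the rough grid where possible
    if a_lo in alphas and alphas.index(a_lo) > 0:
        a_lo = alphas[alphas.index(a_lo) - 1]
    if a_hi in alphas and alphas.index(a_hi) < len(alphas) - 1:
        a_hi = alphas[alphas.index(a_hi) + 1]
    if b_lo in betas and betas.index(b_lo) > 0:
        b_lo = betas[betas.index(b_lo) - 1]
    if b_hi in betas and betas.index(b_hi) < len(betas) - 1:
        b_hi = betas[betas.index(b_hi) + 1]
    fine_alphas = list(np.arange(a_lo, a_hi + alpha_step / 2, alpha_step))
    fine_betas = list(np.arange(max(b_lo, beta_step), b_hi + beta_step / 2, beta_step))
    return ScreeningGrid(fine_alphas, fine_betas, repeats)


def choose_cell(cells: Sequence[CellResult]) -> tuple:
    """Argmax of r_g_opt * r_s_opt * exp(1 - std); ties to smaller alpha, beta.

    When every score is zero (all repeats failed the threshold), fall
    back to the package defaults with a warning.
    """
    if len(cells) == 0:
        raise ValueError("empty screening table")
    best = None
    for c in cells:
        c.score = c.r_g_opt * c.r_s_opt * float(np.exp(1.0 - c.std))
        if (
            best is None
            or c.score > best.score
            or (c.score == best.score and (c.alpha, c.beta) < (best.alpha, best.beta))
        ):
            best = c
    if best.score <= 0:
        logger.warning(
            "all screening scores are zero; falling back to default weights %s",
            DEFAULT_WEIGHTS_SPATIAL,
        )
        return DEFAULT_WEIGHTS_SPATIAL
    return (best.alpha, best.beta)


def fine_screen(
    X: np.ndarray,
    Z: np.ndarray,
    grid: Optional[ScreeningGrid] = None,
    r_thres: float = 0.0,
    cfg: Optional[EmbedConfig] = None,
    std_on_thresholded: bool = True,
) -> ScreeningReport:
    """Fine-grid screen with the stability-penalized selection score."""
    grid = grid or ScreeningGrid(FINE_ALPHAS, FINE_BETAS, repeats=20)
    cells = []
    for idx, (a, b) in enumerate(grid.cells()):
        rg, rs, std = screen_cell(
            X,
            Z,
            a,
            b,
            grid.repeats,
            r_thres,
            cfg,
            stage="fine",
            cell_index=idx,
            std_on_thresholded=std_on_thresholded,
        )
        cells.append(CellResult(a, b, rg, rs, std))
    chosen = choose_cell(cells)
    return ScreeningReport(r_thres=r_thres, cells=cells, chosen=chosen)


def final_embedding(
    X: np.ndarray,
    Z: np.ndarray,
    chosen: tuple,
    n_repeats: int = 100,
    cfg: Optional[EmbedConfig] = None,
    labels=None,
) -> tuple:
    """Best-of-n repeats at the chosen weights, ranked by r_g * r_s.

    Returns the winning :class:`EmbeddingResult` and its
    :class:`QualityScores`.
    """
    cfg = cfg or EmbedConfig()
    if n_repeats < 1:
        raise ValueError("n_repeats must be >= 1")
    alpha, beta = chosen
    best_res: Optional[EmbeddingResult] = None
    best_prod = -np.inf
    for r in range(n_repeats):
        run_cfg = replace(
            cfg, alpha=alpha, beta=beta, seed=repeat_seed(cfg.seed, "final", 0, r)
        )
        res = spasne_embed(X, Z, run_cfg)
        prod = distance_correlation(X, res.Y) * distance_correlation(Z, res.Y)
        if prod > best_prod:
            best_prod, best_res = prod, res
    scores = evaluate(X, Z, best_res.Y, labels=labels)
    return best_res, scores


def screen(
    X: np.ndarray,
    Z: np.ndarray,
    cfg: Optional[EmbedConfig] = None,
    threshold_repeats: int = 100,
    rough_grid: Optional[ScreeningGrid] = None,
    fine_grid: Optional[ScreeningGrid] = None,
    final_repeats: int = 100,
    labels=None,
) -> tuple:
    """End-to-end protocol: threshold, rough, fine, selection, final run.

    When ``fine_grid`` is not given it is derived from the rough heatmap
    via :func:`select_fine_grid`. Returns (ScreeningReport,
    EmbeddingResult, QualityScores).
    """
    cfg = cfg or EmbedConfig()
    r_thres = compute_threshold(X, cfg, threshold_repeats)
    rough = rough_screen(X, Z, rough_grid, r_thres, cfg)
    if fine_grid is None:
        fine_grid = select_fine_grid(rough)
    report = fine_screen(X, Z, fine_grid, r_thres, cfg)
    report.rough_cells = rough
    res, scores = final_embedding(X, Z, report.chosen, final_repeats, cfg, labels)
    return report, res, scores
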