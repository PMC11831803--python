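"""Synthetic spatial-transcriptomics fixtures with known ground truth.

Emulates the structure the embedder targets: spatially compact cell
clusters, each with its own panel of up-regulated marker genes. Counts
follow a log-normal-then-Poisson scheme — gene baseline log-means are
drawn once, cluster markers are shifted up in log space, per-cell
log-normal noise is added, and UMI counts are Poisson draws from the
resulting rates — which yields realistic zero inflation at low depth
without extra parameters. Cluster centers are placed by one of three
layouts (square lattice, parallel bands like cortical layers, or a
ring), and cells are jittered around their center.

Everything is deterministic given the spec's seed, so the whole test
suite runs without any download.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .affinities import SpatialCoords
from .preprocess import CountMatrix

__all__ = ["FixtureSpec", "Fixture", "generate_fixture", "generate_layered_fixture"]

LAYOUTS = ("grid", "layered", "ring")


@dataclass
class FixtureSpec:
    """Parameters of one synthetic dataset.

    ``marker_effect`` is a log-scale mean shift applied to each cluster's
    marker genes (2.0 log units by default — strong, well-separated
    clusters). ``noise_sd`` is the standard deviation of per-cell-per-gene
    log-normal noise. ``spatial_jitter`` is the positional noise around a
    cluster center, in the same arbitrary units as the layout spacing
    (10 units between neighboring centers).
    """

    n_clusters: int = 4
    cells_per_cluster: int = 50
    n_genes: int = 100
    n_marker_genes_per_cluster: int = 10
    marker_effect: float = 2.0
    noise_sd: float = 0.3
    layout: str = "grid"
    spatial_jitter: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_clusters < 1 or self.cells_per_cluster < 1 or self.n_genes < 1:
            raise ValueError("cluster, cell and gene counts must be positive")
        if self.n_marker_genes_per_cluster < 0:
            raise ValueError("marker gene count must be nonnegative")
        if self.n_marker_genes_per_cluster * self.n_clusters > self.n_genes:
            raise ValueError(
                "infeasible marker allocation: "
                f"{self.n_marker_genes_per_cluster} markers x {self.n_clusters} "
                f"clusters exceeds {self.n_genes} genes"
            )
        if self.layout not in LAYOUTS:
            raise ValueError(f"layout must be one of {LAYOUTS}")
        if self.noise_sd <= 0 or self.spatial_jitter <= 0:
            raise ValueError("noise_sd and spatial_jitter must be positive")


@dataclass
class Fixture:
    """A generated dataset: counts, coordinates, labels, and its spec."""

    counts: CountMatrix
    coords: SpatialCoords
    labels: np.ndarray
    truth: FixtureSpec
    gradient_gene: Optional[int] = None
    marker_genes: dict = field(default_factory=dict)


_CENTER_SPACING = 10.0


def _cluster_centers(spec: FixtureSpec) -> np.ndarray:
    k = spec.n_clusters
    if spec.layout == "grid":
        side = int(np.ceil(np.sqrt(k)))
        pts = [(i % side, i // side) for i in range(k)]
        return np.asarray(pts, dtype=float) * _CENTER_SPACING
    if spec.layout == "layered":
        return np.column_stack([np.arange(k) * _CENTER_SPACING, np.zeros(k)])
    # ring: equally spaced on a circle whose chord spacing ~ the lattice spacing
    radius = max(_CENTER_SPACING, k * _CENTER_SPACING / (2 * np.pi))
    ang = 2 * np.pi * np.arange(k) / k
    return radius * np.column_stack([np.cos(ang), np.sin(ang)])


def _positions(spec: FixtureSpec, rng: np.random.Generator) -> np.ndarray:
    centers = _cluster_centers(spec)
    coords = np.empty((spec.n_clusters * spec.cells_per_cluster, 2))
    for c in range(spec.n_clusters):
        jitter = rng.normal(0.0, spec.spatial_jitter, size=(spec.cells_per_cluster, 2))
        if spec.layout == "layered":
            # bands extend along y; center jitter so band centroids sit
            # exactly on the (collinear) layout centers
            jitter[:, 1] *= 3.0
            jitter -= jitter.mean(axis=0)
        sl = slice(c * spec.cells_per_cluster, (c + 1) * spec.cells_per_cluster)
        coords[sl] = centers[c] + jitter
    return coords


def generate_fixture(spec: Optional[FixtureSpec] = None) -> Fixture:
    """Draw one synthetic dataset from ``spec`` (defaults: 4x50 cells, 100 genes)."""
    spec = spec or FixtureSpec()
    rng = np.random.default_rng(spec.seed)
    n_cells = spec.n_clusters * spec.cells_per_cluster

    # gene baseline log-means, drawn once
    base = rng.normal(1.0, 0.5, size=spec.n_genes)
    labels = np.repeat(np.arange(spec.n_clusters), spec.cells_per_cluster)

    # disjoint marker panels, one per cluster
    marker_genes: dict = {}
    log_mu = np.tile(base, (n_cells, 1))
    g = 0
    for c in range(spec.n_clusters):
        idx = np.arange(g, g + spec.n_marker_genes_per_cluster)
        marker_genes[c] = idx
        log_mu[np.ix_(labels == c, idx)] += spec.marker_effect
        g += spec.n_marker_genes_per_cluster

    log_mu = log_mu + rng.normal(0.0, spec.noise_sd, size=log_mu.shape)
    counts_values = rng.poisson(np.exp(log_mu)).astype(float)
    # a cell with an all-zero draw would be unusable downstream; bump one gene
    zero_rows = np.flatnonzero(counts_values.sum(axis=1) == 0)
    counts_values[zero_rows, 0] = 1.0

    coords = _positions(spec, rng)
    counts = CountMatrix(
        counts_values,
        [f"cell{i}" for i in range(n_cells)],
        [f"gene{j}" for j in range(spec.n_genes)],
    )
    return Fixture(
        counts=counts,
        coords=SpatialCoords(coords),
        labels=labels,
        truth=spec,
        marker_genes=marker_genes,
    )


GRADIENT_SLOPE = 0.5  # log-units of gradient-gene mean per band


def generate_layered_fixture(spec: Optional[FixtureSpec] = None) -> Fixture:
    """Layered fixture with a smooth gradient gene across the bands.

    The last non-marker gene's log-mean increases by ``GRADIENT_SLOPE``
    log units per band, emulating a developmental-trajectory signal that
    runs across cortical-layer-like bands without dominating the
    expression space. The gene's index is recorded in
    ``Fixture.gradient_gene``.

    The default spec emulates a cortex-like section: 7 parallel bands
    (as in a visual-cortex section with layers L1-L6 plus white matter)
    of 30 cells each, with *subtle* expression differences between
    adjacent layers (marker effect 1.0 log unit) — the regime where the
    bands' global order is carried by the spatial arrangement rather
    than by expression alone.
    """
    spec = spec or FixtureSpec(
        layout="layered", n_clusters=7, cells_per_cluster=30,
        n_marker_genes_per_cluster=8, marker_effect=1.0,
    )
    if spec.layout != "layered":
        raise ValueError("layered fixture requires layout='layered'")
    n_markers = spec.n_marker_genes_per_cluster * spec.n_clusters
    if n_markers >= spec.n_genes:
        raise ValueError("no free gene left for the gradient signal")
    fx = generate_fixture(spec)
    gradient_gene = spec.n_genes - 1
    rng = np.random.default_rng(spec.seed + 1)
    band = fx.labels
    log_mu = 0.5 + GRADIENT_SLOPE * band + rng.normal(0.0, spec.noise_sd, size=band.shape)
    fx.counts.values[:, gradient_gene] = rng.poisson(np.exp(log_mu)).astype(float)
    fx.gradient_gene = gradient_gene
    return fx
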