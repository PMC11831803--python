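"""Expression preprocessing: median-count normalization, log transform, PCA.

Raw UMI counts are turned into the feature matrix consumed by the embedder
following the standard single-cell workflow: scale every cell to the median
total count, move to natural-log scale with ``ln(1 + x)``, and (for panels
large enough to warrant it) reduce to the leading principal components.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.decomposition import PCA

__all__ = [
    "CountMatrix",
    "ExpressionMatrix",
    "normalize_counts",
    "log_transform",
    "reduce_pca",
    "preprocess",
]


@dataclass
class CountMatrix:
    """A cells x genes matrix of nonnegative molecule counts.

    Parameters
    ----------
    values : ndarray of shape (n_cells, n_genes)
        Nonnegative counts (UMIs or equivalent).
    cell_ids : list of str
        Unique per-cell identifiers, one per row.
    gene_ids : list of str
        Gene identifiers, one per column.
    """

    values: np.ndarray
    cell_ids: list = field(default_factory=list)
    gene_ids: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("count matrix must be 2-D (cells x genes)")
        n_cells, n_genes = self.values.shape
        if n_cells < 2 or n_genes < 2:
            raise ValueError("need at least 2 cells and 2 genes")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("count matrix contains non-finite entries")
        if np.any(self.values < 0):
            raise ValueError("count matrix contains negative entries")
        if not self.cell_ids:
            self.cell_ids = [f"cell{i}" for i in range(n_cells)]
        if not self.gene_ids:
            self.gene_ids = [f"gene{j}" for j in range(n_genes)]
        self.cell_ids = [str(c) for c in self.cell_ids]
        self.gene_ids = [str(g) for g in self.gene_ids]
        if len(self.cell_ids) != n_cells:
            raise ValueError("cell_ids length does not match row count")
        if len(self.gene_ids) != n_genes:
            raise ValueError("gene_ids length does not match column count")
        if len(set(self.cell_ids)) != n_cells:
            raise ValueError("cell_ids must be unique")

    @property
    def shape(self) -> tuple:
        return self.values.shape


@dataclass
class ExpressionMatrix:
    """A cells x features matrix of processed expression values.

    Features are genes (after normalization/log) or principal-component
    scores. Row order is identical to the source :class:`CountMatrix`.
    """

    values: np.ndarray
    cell_ids: list = field(default_factory=list)
    feature_ids: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("expression matrix must be 2-D")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("expression matrix contains non-finite entries")
        n_cells, n_feat = self.values.shape
        if not self.cell_ids:
            self.cell_ids = [f"cell{i}" for i in range(n_cells)]
        if not self.feature_ids:
            self.feature_ids = [f"feature{j}" for j in range(n_feat)]
        if len(self.cell_ids) != n_cells:
            raise ValueError("cell_ids length does not match row count")

    @property
    def shape(self) -> tuple:
        return self.values.shape


def normalize_counts(counts: CountMatrix) -> CountMatrix:
    """Scale each cell so its total equals the median of per-cell totals.

    Within-cell proportions are preserved exactly; only the library size
    changes. Idempotent once all totals are equal.

    Raises
    ------
    ValueError
        If any cell has a total count of zero (names the offending cell).
    """
    totals = counts.values.sum(axis=1)
    zero = np.flatnonzero(totals == 0)
    if zero.size:
        names = ", ".join(counts.cell_ids[i] for i in zero[:5])
        raise ValueError(f"cell(s) with zero total count: {names}")
    target = float(np.median(totals))
    scaled = counts.values * (target / totals)[:, None]
    return CountMatrix(scaled, list(counts.cell_ids), list(counts.gene_ids))


def log_transform(m: CountMatrix) -> ExpressionMatrix:
    """Natural-log transform ``x -> ln(1 + x)``.

    The +1 shift keeps the ubiquitous zeros of UMI data at zero while
    placing everything else on a natural-log scale.
    """
    if np.any(m.values < 0):
        raise ValueError("log transform requires nonnegative entries")
    return ExpressionMatrix(np.log1p(m.values), list(m.cell_ids), list(m.gene_ids))


def _fix_signs(scores: np.ndarray, components: np.ndarray) -> np.ndarray:
    """Flip each component so its largest-magnitude loading is positive."""
    idx = np.argmax(np.abs(components), axis=1)
    signs = np.sign(components[np.arange(components.shape[0]), idx])
    signs[signs == 0] = 1.0
    return scores * signs[None, :]


def reduce_pca(m: ExpressionMatrix, n_components: int) -> ExpressionMatrix:
    """Project onto the top ``n_components`` principal components.

    Features are mean-centered (not variance-scaled) before the
    decomposition; components are ordered by decreasing explained variance
    and sign-fixed so the largest-magnitude loading of each component is
    positive, for reproducibility across SVD backends.
    """
    n_cells, n_feat = m.values.shape
    if not (1 <= n_components <= min(n_cells, n_feat)):
        raise ValueError(
            f"n_components={n_components} must be in [1, min(cells, features)="
            f"{min(n_cells, n_feat)}]"
        )
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(m.values)
    scores = _fix_signs(scores, pca.components_)
    ids = [f"PC{j + 1}" for j in range(n_components)]
    return ExpressionMatrix(scores, list(m.cell_ids), ids)


def preprocess(counts: CountMatrix, n_components: int = 200) -> ExpressionMatrix:
    """Full pipeline: median normalization, log1p, then PCA.

    PCA is skipped entirely when the panel has fewer than ``n_components``
    genes (targeted panels such as a 161-gene MERFISH run are used as-is),
    and ``n_components`` is clipped to the number of cells otherwise.
    """
    logged = log_transform(normalize_counts(counts))
    n_cells, n_genes = logged.values.shape
    if n_genes < n_components:
        return logged
    return reduce_pca(logged, min(n_components, n_cells))
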