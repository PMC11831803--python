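"""Embedding-quality metrics: r_g, r_s, silhouette, trustworthiness.

``r_g`` is the Pearson correlation between pairwise expression distances
and pairwise embedding distances (a Shepard-diagram-style measure of
global expression preservation); ``r_s`` is the same correlation against
pairwise spatial distances. The silhouette score, computed on the
embedding with ground-truth labels, measures how well the layout
separates the annotated clusters. Trustworthiness measures local
neighborhood preservation against either reference space; the product of
the expression- and spatial-reference scores serves as a label-free
alternative to the silhouette.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.spatial.distance import pdist
from scipy.stats import pearsonr
from sklearn.manifold import trustworthiness as _sk_trustworthiness
from sklearn.metrics import silhouette_score as _sk_silhouette

__all__ = [
    "QualityScores",
    "distance_correlation",
    "silhouette_score",
    "trustworthiness",
    "evaluate",
]


@dataclass
class QualityScores:
    """Bundle of the embedding-quality measures for one embedding."""

    r_g: float
    r_s: Optional[float] = None
    silhouette: Optional[float] = None
    trust_expr: Optional[float] = None
    trust_spatial: Optional[float] = None
    trust_product: Optional[float] = None
    k: Optional[int] = None

    def to_dict(self) -> dict:
        return {
            "r_g": self.r_g,
            "r_s": self.r_s,
            "silhouette": self.silhouette,
            "trust_expr": self.trust_expr,
            "trust_spatial": self.trust_spatial,
            "trust_product": self.trust_product,
            "k": self.k,
        }


def distance_correlation(A: np.ndarray, B: np.ndarray) -> float:
    """Pearson correlation of the two pairwise Euclidean distance vectors.

    Computes r_g when A is the (processed) expression matrix and B the
    embedding, and r_s when A holds the spatial coordinates. Symmetric in
    its arguments and invariant to rigid motion or uniform scaling of
    either one.
    """
    A = np.asarray(A, dtype=float)
    B = np.asarray(B, dtype=float)
    if A.shape[0] != B.shape[0]:
        raise ValueError("A and B must have the same number of rows")
    if A.shape[0] < 3:
        raise ValueError("need at least 3 points")
    da = pdist(A)
    db = pdist(B)
    if np.ptp(da) == 0 or np.ptp(db) == 0:
        raise ValueError("constant distance vector: correlation undefined")
    return float(pearsonr(da, db)[0])


def silhouette_score(Y: np.ndarray, labels) -> float:
    """Mean silhouette ``(b - a) / max(a, b)`` under Euclidean distance.

    ``a`` is a point's mean intra-cluster distance and ``b`` its smallest
    mean distance to any other cluster.
    """
    labels = np.asarray(labels)
    if np.unique(labels).size < 2:
        raise ValueError("silhouette requires at least 2 distinct labels")
    return float(_sk_silhouette(np.asarray(Y, dtype=float), labels, metric="euclidean"))


def trustworthiness(X_ref: np.ndarray, Y: np.ndarray, k: int = 12) -> float:
    """Penalize embedding neighbors that are not reference-space neighbors.

    The standard rank-weighted score in [0, 1]; 1 means every k-nearest
    embedding neighborhood is drawn from the reference k-neighborhood.
    """
    X_ref = np.asarray(X_ref, dtype=float)
    Y = np.asarray(Y, dtype=float)
    n = X_ref.shape[0]
    if not (1 <= k < n / 2):
        raise ValueError(f"k must satisfy 1 <= k < N/2 (N={n}), got {k}")
    return float(_sk_trustworthiness(X_ref, Y, n_neighbors=k, metric="euclidean"))


def evaluate(
    X: np.ndarray,
    Z: Optional[np.ndarray],
    Y: np.ndarray,
    labels=None,
    k: int = 12,
) -> QualityScores:
    """Assemble all applicable quality scores for one embedding.

    Absent inputs yield absent fields: no spatial coordinates means no
    r_s / trust_spatial / trust_product, no labels means no silhouette.
    ``X`` should be the same processed matrix the embedding consumed.
    The trustworthiness neighborhood ``k`` is clipped to the largest
    valid value for small datasets; the effective k is reported.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    k = min(k, (X.shape[0] - 1) // 2)
    scores = QualityScores(r_g=distance_correlation(X, Y), k=k)
    scores.trust_expr = trustworthiness(X, Y, k)
    if Z is not None:
        Z = np.asarray(Z, dtype=float)
        scores.r_s = distance_correlation(Z, Y)
        scores.trust_spatial = trustworthiness(Z, Y, k)
        scores.trust_product = scores.trust_expr * scores.trust_spatial
    if labels is not None:
        scores.silhouette = silhouette_score(Y, labels)
    return scores
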