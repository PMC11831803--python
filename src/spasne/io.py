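"""Readers and writers for expression matrices, metadata and embeddings.

Dense matrices travel as CSV/TSV with cells in rows, a mandatory header
row of gene ids and the first column holding cell ids. Sparse matrices
use Matrix Market (.mtx, 1-based indices per the standard) with
companion one-id-per-line barcode (cell) and feature (gene) files.
Metadata tables carry a cell-id column plus 2-D spatial coordinates and
optional label columns; readers realign metadata to the expression row
order and fail loudly on unmatched ids.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from scipy.io import mmread, mmwrite
from scipy.sparse import csr_matrix

from .affinities import SpatialCoords
from .embedding import EmbeddingResult
from .preprocess import CountMatrix

__all__ = [
    "Metadata",
    "read_expression",
    "write_expression",
    "read_metadata",
    "write_metadata",
    "write_embedding",
    "read_embedding",
]


@dataclass
class Metadata:
    """Per-cell annotations: spatial coordinates and optional labels."""

    cell_ids: list
    coords: SpatialCoords
    labels: Optional[pd.DataFrame] = field(default=None)

    def label_column(self, name: str) -> np.ndarray:
        if self.labels is None or name not in self.labels.columns:
            raise KeyError(f"no label column named {name!r}")
        return self.labels[name].to_numpy()


def _infer_sep(path: Path, fmt: Optional[str]) -> str:
    if fmt == "tsv" or (fmt is None and path.suffix.lower() in {".tsv", ".txt"}):
        return "\t"
    return ","


def read_expression(
    path,
    fmt: Optional[str] = None,
    barcodes=None,
    features=None,
    transpose: bool = False,
) -> CountMatrix:
    """Read a cells x genes count matrix from CSV/TSV or Matrix Market.

    For ``.mtx`` input, ``barcodes`` and ``features`` name the companion
    id files (cells and genes respectively); matrix rows are cells unless
    ``transpose`` is set (use it for gene x cell exports).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if fmt == "mtx" or (fmt is None and path.suffix.lower() == ".mtx"):
        if barcodes is None or features is None:
            raise ValueError("mtx input requires companion barcode and feature files")
        mat = np.asarray(mmread(str(path)).todense(), dtype=float)
        if transpose:
            mat = mat.T
        cell_ids = Path(barcodes).read_text().split()
        gene_ids = Path(features).read_text().split()
        if mat.shape != (len(cell_ids), len(gene_ids)):
            raise ValueError(
                f"matrix shape {mat.shape} does not match "
                f"{len(cell_ids)} barcodes x {len(gene_ids)} features"
            )
        return CountMatrix(mat, cell_ids, gene_ids)

    sep = _infer_sep(path, fmt)
    df = pd.read_csv(path, sep=sep, index_col=0)
    if df.shape[1] == 0:
        raise ValueError(f"{path}: no data columns found")
    if transpose:
        df = df.T
    values = df.to_numpy(dtype=float)
    if np.isnan(values).any():
        raise ValueError(f"{path}: matrix contains missing values")
    return CountMatrix(values, [str(i) for i in df.index], [str(c) for c in df.columns])


def write_expression(m: CountMatrix, path, fmt: Optional[str] = None) -> None:
    """Write a count matrix as CSV/TSV, or as .mtx with companion id files."""
    path = Path(path)
    if fmt == "mtx" or (fmt is None and path.suffix.lower() == ".mtx"):
        mmwrite(str(path), csr_matrix(m.values))
        path.with_suffix(".barcodes.txt").write_text("\n".join(m.cell_ids) + "\n")
        path.with_suffix(".features.txt").write_text("\n".join(m.gene_ids) + "\n")
        return
    sep = _infer_sep(path, fmt)
    df = pd.DataFrame(m.values, index=m.cell_ids, columns=m.gene_ids)
    df.to_csv(path, sep=sep, index_label="cell_id")


def read_metadata(
    path,
    cell_ids=None,
    id_col: str = "cell_id",
    x_col: str = "x",
    y_col: str = "y",
    fmt: Optional[str] = None,
) -> Metadata:
    """Read per-cell metadata and align it to an expression row order.

    When ``cell_ids`` is given (usually from the expression matrix), rows
    are reordered to match it and any id present in one table but not
    the other raises an error naming the offenders.
    """
    path = Path(path)
    sep = _infer_sep(path, fmt)
    df = pd.read_csv(path, sep=sep)
    for col in (id_col, x_col, y_col):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    df[id_col] = df[id_col].astype(str)
    if df[id_col].duplicated().any():
        dupes = df[id_col][df[id_col].duplicated()].tolist()[:5]
        raise ValueError(f"{path}: duplicate cell ids: {dupes}")
    if cell_ids is not None:
        cell_ids = [str(c) for c in cell_ids]
        missing = sorted(set(cell_ids) - set(df[id_col]))
        extra = sorted(set(df[id_col]) - set(cell_ids))
        if missing or extra:
            raise ValueError(
                f"{path}: metadata/expression id mismatch; "
                f"missing from metadata: {missing[:5]}, unmatched: {extra[:5]}"
            )
        df = df.set_index(id_col).loc[cell_ids].reset_index()
    xy = df[[x_col, y_col]].to_numpy(dtype=float)
    if not np.all(np.isfinite(xy)):
        raise ValueError(f"{path}: non-finite spatial coordinates")
    label_cols = [c for c in df.columns if c not in (id_col, x_col, y_col)]
    labels = df[label_cols] if label_cols else None
    return Metadata(df[id_col].tolist(), SpatialCoords(xy), labels)


def write_metadata(meta: Metadata, path, labels=None) -> None:
    """Write metadata (cell_id, x, y, plus any label columns) as CSV."""
    df = pd.DataFrame(
        {
            "cell_id": meta.cell_ids,
            "x": meta.coords.values[:, 0],
            "y": meta.coords.values[:, 1],
        }
    )
    if meta.labels is not None:
        for col in meta.labels.columns:
            df[col] = meta.labels[col].to_numpy()
    if labels is not None:
        df["label"] = np.asarray(labels)
    df.to_csv(path, index=False)


def write_embedding(result: EmbeddingResult, path, cell_ids=None) -> None:
    """Write embedding coordinates as CSV plus a JSON sidecar.

    The sidecar (``<path>.json``) records the resolved configuration and
    the loss history so a run can be audited and reproduced.
    """
    path = Path(path)
    Y = result.Y
    ids = cell_ids if cell_ids is not None else [f"cell{i}" for i in range(len(Y))]
    cols = {"cell_id": ids}
    for d in range(Y.shape[1]):
        cols[f"y{d + 1}"] = Y[:, d]
    pd.DataFrame(cols).to_csv(path, index=False)
    sidecar = {
        "config": vars(result.config) if result.config else None,
        "converged": result.converged,
        "loss_history": [lb.to_dict() for lb in result.loss_history],
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=2))


def read_embedding(path) -> tuple:
    """Read an embedding CSV back as (cell_ids, Y)."""
    df = pd.read_csv(path)
    ycols = [c for c in df.columns if c.startswith("y")]
    return df["cell_id"].astype(str).tolist(), df[ycols].to_numpy(dtype=float)
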