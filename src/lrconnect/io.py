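"""Readers and writers for expression matrices and cluster labels.

Supported inputs: matrix-market sparse triplets with genes/barcodes
sidecar files (cells in MTX columns, the common exchange convention), or
a dense CSV in either orientation. Cluster labels come as a two-column
CSV (cell_id, cluster).
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .preprocess import ClusteredExpression

logger = logging.getLogger(__name__)


def read_mtx(
    matrix_path: str | Path,
    genes_path: str | Path,
    barcodes_path: str | Path,
    clusters_path: str | Path | None = None,
    cells_in_columns: bool = True,
) -> ClusteredExpression:
    """Load a sparse MTX matrix with gene/barcode sidecars (raw counts)."""
    m = scipy.io.mmread(str(matrix_path)).tocsr()
    genes = pd.read_csv(genes_path, header=None, sep="\t")[0].astype(str)
    barcodes = pd.read_csv(barcodes_path, header=None, sep="\t")[0].astype(str)
    if cells_in_columns:
        m = m.T.tocsr()
    if m.shape != (len(barcodes), len(genes)):
        raise ValueError(
            f"matrix shape {m.shape} does not match {len(barcodes)} barcodes x {len(genes)} genes"
        )
    labels = _labels_for(barcodes, clusters_path)
    return ClusteredExpression(
        matrix=m,
        gene_names=pd.Index(genes),
        cell_ids=pd.Index(barcodes),
        cluster_labels=labels,
        is_normalized=False,
    )


def read_dense_csv(
    path: str | Path,
    clusters_path: str | Path | None = None,
    cells_in_rows: bool = True,
    is_normalized: bool = False,
) -> ClusteredExpression:
    """Load a dense CSV matrix with row/column labels in the first row/column."""
    df = pd.read_csv(path, index_col=0)
    if not cells_in_rows:
        df = df.T
    labels = _labels_for(pd.Index(df.index.astype(str)), clusters_path)
    return ClusteredExpression(
        matrix=df.to_numpy(dtype=float),
        gene_names=pd.Index(df.columns.astype(str)),
        cell_ids=pd.Index(df.index.astype(str)),
        cluster_labels=labels,
        is_normalized=is_normalized,
    )


def read_cluster_labels(path: str | Path) -> pd.Series:
    """Two-column CSV (cell_id, cluster) -> Series indexed by cell id."""
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise ValueError(f"cluster file {path} needs 2 columns (cell_id, cluster)")
    return pd.Series(df.iloc[:, 1].values, index=df.iloc[:, 0].astype(str).values)


def _labels_for(cell_ids: pd.Index, clusters_path) -> pd.Series:
    if clusters_path is None:
        return pd.Series([np.nan] * len(cell_ids), index=cell_ids)
    labels = read_cluster_labels(clusters_path)
    missing = [c for c in cell_ids if c not in labels.index]
    if missing:
        logger.warning("%d cells lack a cluster label", len(missing))
    return labels.reindex(cell_ids)


def write_mtx(
    expr: ClusteredExpression,
    out_dir: str | Path,
    prefix: str = "",
    cells_in_columns: bool = True,
) -> dict[str, Path]:
    """Write counts as MTX + genes/barcodes/clusters sidecars; returns the paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    m = sp.coo_matrix(expr.matrix)
    if cells_in_columns:
        m = m.T
    paths = {
        "matrix": out_dir / f"{prefix}matrix.mtx",
        "genes": out_dir / f"{prefix}genes.tsv",
        "barcodes": out_dir / f"{prefix}barcodes.tsv",
        "clusters": out_dir / f"{prefix}clusters.csv",
    }
    scipy.io.mmwrite(str(paths["matrix"]), m)
    paths["genes"].write_text("\n".join(map(str, expr.gene_names)) + "\n")
    paths["barcodes"].write_text("\n".join(map(str, expr.cell_ids)) + "\n")
    pd.DataFrame(
        {"cell_id": expr.cell_ids, "cluster": expr.cluster_labels.values}
    ).to_csv(paths["clusters"], index=False)
    return paths
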