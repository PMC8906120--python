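"""Per-cluster expression summaries: the node-level quantities edges are built from.

A clustered cells x genes matrix is reduced, per cluster and per gene, to
the mean normalized expression, the mean system-wide z-scaled expression,
the fraction of cells expressing, and a one-vs-rest Wilcoxon rank-sum
p-value. Every edge weight downstream is a function of these four numbers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp
from statsmodels.stats.multitest import multipletests

from ._stats import rank_sum_pvalues

logger = logging.getLogger(__name__)


@dataclass
class ClusteredExpression:
    """A cells x genes expression matrix with a per-cell cluster label.

    ``matrix`` may be dense or scipy-sparse, cells in rows. Values must be
    finite and non-negative when ``is_normalized`` is False (raw counts).
    """

    matrix: np.ndarray | sp.spmatrix
    gene_names: pd.Index
    cell_ids: pd.Index
    cluster_labels: pd.Series
    is_normalized: bool = False
    is_log1p: bool = False  # True when values are log(1 + normalized); set by normalize()

    def __post_init__(self) -> None:
        self.gene_names = pd.Index(self.gene_names)
        self.cell_ids = pd.Index(self.cell_ids)
        n_cells, n_genes = self.matrix.shape
        if n_cells != len(self.cell_ids):
            raise ValueError(f"matrix has {n_cells} rows but {len(self.cell_ids)} cell ids")
        if n_genes != len(self.gene_names):
            raise ValueError(f"matrix has {n_genes} columns but {len(self.gene_names)} gene names")
        labels = pd.Series(self.cluster_labels)
        if len(labels) != n_cells:
            raise ValueError("cluster_labels length does not match cell count")
        labels.index = self.cell_ids
        self.cluster_labels = labels
        if not self.is_normalized:
            data = self.matrix.data if sp.issparse(self.matrix) else np.asarray(self.matrix)
            if data.size and (not np.all(np.isfinite(data)) or data.min() < 0):
                raise ValueError("raw count matrix must be finite and non-negative")

    @property
    def n_cells(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_genes(self) -> int:
        return self.matrix.shape[1]

    def dense(self) -> np.ndarray:
        m = self.matrix
        return np.asarray(m.todense()) if sp.issparse(m) else np.asarray(m, dtype=float)

    def subset_genes(self, genes: list[str]) -> "ClusteredExpression":
        idx = self.gene_names.get_indexer(genes)
        if (idx < 0).any():
            missing = [g for g, i in zip(genes, idx) if i < 0]
            raise KeyError(f"genes not in matrix: {missing}")
        m = self.matrix.tocsc()[:, idx].tocsr() if sp.issparse(self.matrix) else self.matrix[:, idx]
        return replace(self, matrix=m, gene_names=pd.Index(genes))

    def to_anndata(self):
        import anndata as ad

        adata = ad.AnnData(
            X=sp.csr_matrix(self.matrix) if sp.issparse(self.matrix) else np.asarray(self.matrix),
            obs=pd.DataFrame({"cluster": self.cluster_labels.values}, index=self.cell_ids.astype(str)),
            var=pd.DataFrame(index=self.gene_names.astype(str)),
        )
        adata.uns["is_normalized"] = self.is_normalized
        return adata

    @classmethod
    def from_anndata(cls, adata, cluster_key: str = "cluster", is_normalized: bool | None = None):
        if is_normalized is None:
            is_normalized = bool(adata.uns.get("is_normalized", False))
        return cls(
            matrix=adata.X.copy() if sp.issparse(adata.X) else np.asarray(adata.X),
            gene_names=pd.Index(adata.var_names),
            cell_ids=pd.Index(adata.obs_names),
            cluster_labels=pd.Series(adata.obs[cluster_key].values, index=adata.obs_names),
            is_normalized=is_normalized,
        )


@dataclass
class ClusterProfile:
    """Per-cluster, per-gene summary statistics (clusters x genes frames)."""

    mean_norm: pd.DataFrame
    mean_scaled: pd.DataFrame
    frac_expr: pd.DataFrame
    pval: pd.DataFrame
    pval_adj: pd.DataFrame
    cells_per_cluster: pd.Series

    @property
    def clusters(self) -> list:
        return list(self.mean_norm.index)

    @property
    def genes(self) -> pd.Index:
        return self.mean_norm.columns

    def to_long(self) -> pd.DataFrame:
        """Long-format table: cluster, gene, mean_norm, mean_scaled, frac_expr, pval, pval_adj."""
        frames = {
            "mean_norm": self.mean_norm,
            "mean_scaled": self.mean_scaled,
            "frac_expr": self.frac_expr,
            "pval": self.pval,
            "pval_adj": self.pval_adj,
        }
        long = pd.concat(
            {k: v.stack() for k, v in frames.items()}, axis=1
        ).reset_index()
        long.columns = ["cluster", "gene", *frames.keys()]
        return long

    def write(self, path: str | Path) -> None:
        self.to_long().to_csv(path, index=False)


def normalize(expr: ClusteredExpression, scale_factor: float = 1e4) -> ClusteredExpression:
    """Library-size normalize each cell to ``scale_factor`` total, then log1p.

    The standard single-cell recipe: counts are scaled so every cell sums
    to ``scale_factor`` before the log transform; output values are
    ``log(1 + scaled)``.
    """
    if expr.is_normalized:
        raise ValueError("expression is already normalized")
    if scale_factor <= 0:
        raise ValueError("scale_factor must be positive")
    m = expr.matrix
    totals = np.asarray(m.sum(axis=1)).ravel()
    zero = np.flatnonzero(totals == 0)
    if zero.size:
        raise ValueError(f"cells with zero total counts: {list(expr.cell_ids[zero[:10]])}")
    factors = scale_factor / totals
    if sp.issparse(m):
        out = sp.diags(factors) @ m.tocsr()
        out.data = np.log1p(out.data)
    else:
        out = np.log1p(np.asarray(m, dtype=float) * factors[:, None])
    return replace(expr, matrix=out, is_normalized=True, is_log1p=True)


def zscale_genes(
    expr: ClusteredExpression, clip: float | None = None, ddof: int = 1
) -> np.ndarray:
    """Gene-wise z-scores across all cells (dense cells x genes array).

    Each gene column is centered and scaled to unit SD computed across the
    whole system (``ddof=1`` sample SD by default). Zero-variance genes map
    to all-zero columns. ``clip`` truncates to ``[-clip, +clip]``.
    """
    if not expr.is_normalized:
        raise ValueError("z-scaling expects normalized expression")
    x = expr.dense()
    mu = x.mean(axis=0)
    sd = x.std(axis=0, ddof=ddof)
    z = np.zeros_like(x)
    nonconst = sd > 0
    z[:, nonconst] = (x[:, nonconst] - mu[nonconst]) / sd[nonconst]
    if clip is not None:
        if clip <= 0:
            raise ValueError("clip must be positive")
        np.clip(z, -clip, clip, out=z)
    return z


def cluster_profile(
    expr: ClusteredExpression,
    min_cells_per_ident: int = 0,
    clip: float | None = None,
    ddof: int = 1,
) -> ClusterProfile:
    """Summarize a normalized clustered matrix into per-cluster statistics.

    Clusters with fewer than ``min_cells_per_ident`` cells are dropped from
    all outputs. ``pval`` is the two-sided one-vs-rest Wilcoxon rank-sum
    p-value of each gene in each cluster against all other retained cells;
    ``pval_adj`` is its Benjamini-Hochberg adjustment within each cluster.
    Z-scaling is system-wide across the retained cells, which is what makes
    the scaled weight reflect specificity within the whole system.

    ``mean_norm`` is reported on the linear normalized scale: when the
    matrix is log1p-transformed (as :func:`normalize` produces), values are
    un-logged with expm1 before cluster averaging, so downstream fold
    changes compare normalized expression rather than its logarithm.
    Z-scores, fractions and rank-sum tests use the values as stored.
    """
    if not expr.is_normalized:
        raise ValueError("cluster_profile expects normalized expression")
    labels = expr.cluster_labels
    na_mask = labels.isna()
    if na_mask.any():
        logger.warning("dropping %d cells with missing cluster label", int(na_mask.sum()))
    keep_cells = ~na_mask.values
    counts = labels[keep_cells].value_counts()
    surviving = sorted(counts.index[counts >= max(min_cells_per_ident, 1)])
    if len(surviving) < 2:
        raise ValueError(
            f"fewer than 2 clusters with >= {min_cells_per_ident} cells "
            f"(surviving: {surviving})"
        )
    keep_cells &= labels.isin(surviving).values
    sub = ClusteredExpression(
        matrix=expr.matrix[np.flatnonzero(keep_cells), :],
        gene_names=expr.gene_names,
        cell_ids=expr.cell_ids[keep_cells],
        cluster_labels=labels[keep_cells],
        is_normalized=True,
        is_log1p=expr.is_log1p,
    )
    x = sub.dense()
    lin = np.expm1(x) if expr.is_log1p else x
    z = zscale_genes(sub, clip=clip, ddof=ddof)
    lab = sub.cluster_labels.values

    genes = sub.gene_names
    mean_norm, mean_scaled, frac, pv = {}, {}, {}, {}
    for cl in surviving:
        in_cl = lab == cl
        xi, xo = x[in_cl], x[~in_cl]
        mean_norm[cl] = lin[in_cl].mean(axis=0)
        mean_scaled[cl] = z[in_cl].mean(axis=0)
        frac[cl] = (xi > 0).mean(axis=0)
        pv[cl] = rank_sum_pvalues(xi, xo)

    def frame(d):
        return pd.DataFrame.from_dict(d, orient="index", columns=genes).loc[surviving]

    pval = frame(pv)
    padj = pval.copy()
    for cl in surviving:
        padj.loc[cl] = multipletests(pval.loc[cl].values, method="fdr_bh")[1]
    return ClusterProfile(
        mean_norm=frame(mean_norm),
        mean_scaled=frame(mean_scaled),
        frac_expr=frame(frac),
        pval=pval,
        pval_adj=padj,
        cells_per_cluster=pd.Series(
            {cl: int((lab == cl).sum()) for cl in surviving}, name="n_cells"
        ),
    )
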