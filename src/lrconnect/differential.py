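"""Differential connectomics: edge-for-edge comparison of two conditions.

Two connectomes built against the same ligand-receptor database and with
aligned cluster labels are compared edge by edge. Each edge gets a log2
fold change for the ligand (in its source cluster) and the receptor (in
its target cluster), a cross-condition Wilcoxon p-value per gene computed
on individual cells, and a perturbation score

    score = |log2 FC(ligand)| x |log2 FC(receptor)|

which is zero for unperturbed edges and grows with change on both sides
regardless of direction. The signs of the two fold changes place each
perturbed edge into one of four categories: both up (activated), both
down (deactivated), ligand down / receptor up (ligand starvation) or
ligand up / receptor down (ligand pressure).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from ._stats import rank_sum_pvalues
from .core import ConnectomeEdgeList
from .preprocess import ClusteredExpression

logger = logging.getLogger(__name__)

CATEGORIES = ("UP_UP", "DOWN_DOWN", "UP_DOWN", "DOWN_UP", "NULL")

CATEGORY_DISPLAY = {
    "UP_UP": "activated",
    "DOWN_DOWN": "deactivated",
    "UP_DOWN": "ligand pressure",
    "DOWN_UP": "ligand starvation",
    "NULL": "unperturbed",
}

DIFF_COLUMNS = [
    "source",
    "target",
    "ligand",
    "receptor",
    "mechanism_id",
    "family",
    "ligand_norm_ctrl",
    "ligand_norm_test",
    "ligand_log2fc",
    "ligand_frac_ctrl",
    "ligand_frac_test",
    "ligand_p_cross",
    "receptor_norm_ctrl",
    "receptor_norm_test",
    "receptor_log2fc",
    "receptor_frac_ctrl",
    "receptor_frac_test",
    "receptor_p_cross",
    "perturbation_score",
    "category",
]


@dataclass
class DifferentialEdgeList:
    """Edge-for-edge comparison of two connectomes with shared clusters."""

    edges: pd.DataFrame
    conditions: tuple[str, str]  # (control label, test label)
    clusters: list
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [c for c in DIFF_COLUMNS if c not in self.edges.columns]
        if missing:
            raise ValueError(f"differential edge table missing columns: {missing}")

    def __len__(self) -> int:
        return len(self.edges)

    def write(self, path: str | Path) -> None:
        self.edges[DIFF_COLUMNS].to_csv(path, index=False)


def _log2fc(ctrl: np.ndarray, test: np.ndarray, pseudocount: float) -> np.ndarray:
    both_zero = (ctrl == 0) & (test == 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.log2((test + pseudocount) / (ctrl + pseudocount))
    # a gene silent in both conditions is unchanged, not undefined
    return np.where(both_zero, 0.0, out)


def _categories(lig_fc: np.ndarray, rec_fc: np.ndarray) -> np.ndarray:
    cat = np.full(lig_fc.shape, "NULL", dtype=object)
    cat[(lig_fc > 0) & (rec_fc > 0)] = "UP_UP"
    cat[(lig_fc < 0) & (rec_fc < 0)] = "DOWN_DOWN"
    cat[(lig_fc > 0) & (rec_fc < 0)] = "UP_DOWN"
    cat[(lig_fc < 0) & (rec_fc > 0)] = "DOWN_UP"
    return cat


def differential_connectome(
    ctrl: ConnectomeEdgeList,
    test: ConnectomeEdgeList,
    pseudocount: float = 0.01,
    conditions: tuple[str, str] = ("control", "test"),
    cross_pvalues: pd.DataFrame | None = None,
) -> DifferentialEdgeList:
    """Join two connectomes edge-for-edge and score every perturbation.

    Both connectomes must be unfiltered builds against the same database;
    clusters present in only one condition are dropped (logged). The fold
    change uses a symmetric pseudocount so zero means are well-defined;
    edges where a gene's mean is zero in both conditions get a fold change
    of exactly 0 and fall in the NULL category. ``cross_pvalues`` (from
    :func:`cross_condition_wilcoxon`) attaches per-(cluster, gene)
    cross-condition p-values; absent that, p columns are NaN.
    """
    if pseudocount < 0:
        raise ValueError("pseudocount must be non-negative")
    shared = [c for c in ctrl.clusters if c in set(test.clusters)]
    if not shared:
        raise ValueError("control and test connectomes share no clusters")
    dropped = (set(ctrl.clusters) | set(test.clusters)) - set(shared)
    if dropped:
        logger.warning("dropping clusters absent from one condition: %s", sorted(map(str, dropped)))

    keys = ["source", "target", "mechanism_id"]
    carry = keys + ["ligand", "receptor", "family"]
    attrs = ["ligand_norm", "receptor_norm", "ligand_frac", "receptor_frac"]
    c = ctrl.edges[carry + attrs]
    t = test.edges[keys + attrs]
    m = c.merge(t, on=keys, suffixes=("_ctrl", "_test"), how="inner")
    m = m[m["source"].isin(shared) & m["target"].isin(shared)].reset_index(drop=True)

    lig_fc = _log2fc(m["ligand_norm_ctrl"].to_numpy(float), m["ligand_norm_test"].to_numpy(float), pseudocount)
    rec_fc = _log2fc(m["receptor_norm_ctrl"].to_numpy(float), m["receptor_norm_test"].to_numpy(float), pseudocount)
    m["ligand_log2fc"] = lig_fc
    m["receptor_log2fc"] = rec_fc
    m["perturbation_score"] = np.abs(lig_fc) * np.abs(rec_fc)
    m["category"] = _categories(lig_fc, rec_fc)

    if cross_pvalues is not None:
        pv = cross_pvalues.set_index(["cluster", "gene"])["pval"]
        m["ligand_p_cross"] = [
            pv.get((s, g), np.nan) for s, g in zip(m["source"], m["ligand"])
        ]
        m["receptor_p_cross"] = [
            pv.get((s, g), np.nan) for s, g in zip(m["target"], m["receptor"])
        ]
    else:
        m["ligand_p_cross"] = np.nan
        m["receptor_p_cross"] = np.nan

    m = m.sort_values(["mechanism_id", "source", "target"], kind="mergesort").reset_index(drop=True)
    return DifferentialEdgeList(
        edges=m[DIFF_COLUMNS],
        conditions=conditions,
        clusters=shared,
        provenance={"pseudocount": pseudocount, "conditions": list(conditions)},
    )


def cross_condition_wilcoxon(
    ctrl_expr: ClusteredExpression,
    test_expr: ClusteredExpression,
    genes: set[str] | list[str] | None = None,
) -> pd.DataFrame:
    """Per-cluster, per-gene Wilcoxon rank-sum test of test vs control cells.

    For each cluster shared by both conditions and each requested gene, the
    two-sided rank-sum p-value comparing that cluster's individual cells
    across conditions on normalized expression. Clusters with < 2 cells on
    either side get p = 1 with a warning. Returns a long table (cluster,
    gene, pval).
    """
    if not (ctrl_expr.is_normalized and test_expr.is_normalized):
        raise ValueError("cross-condition testing expects normalized expression")
    if genes is None:
        genes = [g for g in ctrl_expr.gene_names if g in set(test_expr.gene_names)]
    genes = list(genes)
    for name, expr in (("control", ctrl_expr), ("test", test_expr)):
        absent = [g for g in genes if g not in set(expr.gene_names)]
        if absent:
            raise KeyError(f"genes absent from the {name} matrix: {absent}")
    shared = sorted(
        set(ctrl_expr.cluster_labels.dropna()) & set(test_expr.cluster_labels.dropna())
    )
    if not shared:
        raise ValueError("no shared clusters across conditions")

    xc = ctrl_expr.subset_genes(genes).dense()
    xt = test_expr.subset_genes(genes).dense()
    rows = []
    for cl in shared:
        ci = ctrl_expr.cluster_labels.values == cl
        ti = test_expr.cluster_labels.values == cl
        if ci.sum() < 2 or ti.sum() < 2:
            logger.warning("cluster %s has < 2 cells in a condition; p set to 1", cl)
            p = np.ones(len(genes))
        else:
            p = rank_sum_pvalues(xt[ti], xc[ci])
        rows.append(pd.DataFrame({"cluster": cl, "gene": genes, "pval": p}))
    return pd.concat(rows, ignore_index=True)


def filter_differential(
    diff: DifferentialEdgeList,
    max_p: float = 0.05,
    min_frac_either: float = 0.1,
    min_score: float = 0.0,
) -> DifferentialEdgeList:
    """Keep edges significantly changed on both sides and expressed in either condition.

    The ligand and receptor cross-condition p-values must each be strictly
    below ``max_p``; ligand and receptor must each be expressed in strictly
    more than ``min_frac_either`` of their cluster in at least one of the
    two conditions; the perturbation score must be at least ``min_score``
    (inclusive floor).
    """
    if not 0 < max_p <= 1:
        raise ValueError("max_p must be in (0, 1]")
    if not 0 <= min_frac_either <= 1:
        raise ValueError("min_frac_either must be in [0, 1]")
    if min_score < 0:
        raise ValueError("min_score must be non-negative")
    e = diff.edges
    keep = (
        (e["ligand_p_cross"] < max_p)
        & (e["receptor_p_cross"] < max_p)
        & (np.maximum(e["ligand_frac_ctrl"], e["ligand_frac_test"]) > min_frac_either)
        & (np.maximum(e["receptor_frac_ctrl"], e["receptor_frac_test"]) > min_frac_either)
        & (e["perturbation_score"] >= min_score)
    )
    out = e[keep].reset_index(drop=True)
    if out.empty:
        logger.warning("filter_differential: no edges survive")
    prov = dict(diff.provenance)
    prov["filter"] = {
        "max_p": max_p,
        "min_frac_either": min_frac_either,
        "min_score": min_score,
        "n_before": len(e),
        "n_after": len(out),
    }
    return replace(diff, edges=out, provenance=prov)


def categorize(diff: DifferentialEdgeList) -> dict[str, pd.DataFrame]:
    """Partition non-NULL edges by the signs of the two fold changes."""
    e = diff.edges
    return {
        cat: e[e["category"] == cat].reset_index(drop=True)
        for cat in ("UP_UP", "DOWN_DOWN", "UP_DOWN", "DOWN_UP")
    }
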