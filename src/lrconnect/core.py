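"""Build and manipulate the celltype-ligand-receptor-celltype edge list.

Every ordered pair of clusters (self-pairs included) is connected through
every ligand-receptor mechanism whose genes are measured, giving
|clusters|^2 x |mechanisms| edges before filtering. Each edge carries two
weights:

* ``weight_norm`` (w1) — the product of the source cluster's mean
  normalized ligand expression and the target cluster's mean normalized
  receptor expression: raw connectivity.
* ``weight_scale`` (w2) — the mean of the system-wide gene z-scores of the
  ligand (in the source) and receptor (in the target): specificity of the
  edge within the system.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .lrdb import LRDatabase, restrict_to_genes
from .preprocess import ClusterProfile

logger = logging.getLogger(__name__)

EDGE_COLUMNS = [
    "source",
    "target",
    "ligand",
    "receptor",
    "mechanism_id",
    "family",
    "ligand_norm",
    "receptor_norm",
    "ligand_scaled",
    "receptor_scaled",
    "ligand_frac",
    "receptor_frac",
    "ligand_p",
    "receptor_p",
    "ligand_p_adj",
    "receptor_p_adj",
    "weight_norm",
    "weight_scale",
]

SLICE_MODES = ("interactome", "outgoing", "niche", "vector")


@dataclass
class ConnectomeEdgeList:
    """Edge list plus node/mechanism vocabularies and a provenance snapshot."""

    edges: pd.DataFrame
    clusters: list
    mechanisms: list[str]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [c for c in EDGE_COLUMNS if c not in self.edges.columns]
        if missing:
            raise ValueError(f"edge table missing columns: {missing}")
        triple = self.edges[["source", "target", "mechanism_id"]]
        if triple.duplicated().any():
            raise ValueError("duplicate (source, target, mechanism_id) triples")

    def __len__(self) -> int:
        return len(self.edges)

    @property
    def families(self) -> list[str]:
        return sorted(self.edges["family"].unique())


def create_connectome(profile: ClusterProfile, db: LRDatabase) -> ConnectomeEdgeList:
    """Map a cluster profile against an LR database into the full edge list.

    One edge per (source cluster, target cluster, mechanism), self-edges
    included; edge order is (mechanism, source, target), lexicographic in
    cluster order, so output is byte-reproducible.
    """
    db = restrict_to_genes(db, set(profile.genes))
    if len(db) == 0:
        raise ValueError("no ligand-receptor pairs measured in this profile")
    clusters = list(profile.clusters)
    if len(clusters) < 2:
        raise ValueError("need at least 2 clusters")
    n = len(clusters)

    src = np.repeat(np.arange(n), n)  # source-major within a mechanism
    tgt = np.tile(np.arange(n), n)
    blocks = []
    for pair in db:
        lig, rec = pair.ligand, pair.receptor
        block = pd.DataFrame(
            {
                "source": np.asarray(clusters, dtype=object)[src],
                "target": np.asarray(clusters, dtype=object)[tgt],
                "ligand": lig,
                "receptor": rec,
                "mechanism_id": pair.mechanism_id,
                "family": pair.family,
                "ligand_norm": profile.mean_norm[lig].values[src],
                "receptor_norm": profile.mean_norm[rec].values[tgt],
                "ligand_scaled": profile.mean_scaled[lig].values[src],
                "receptor_scaled": profile.mean_scaled[rec].values[tgt],
                "ligand_frac": profile.frac_expr[lig].values[src],
                "receptor_frac": profile.frac_expr[rec].values[tgt],
                "ligand_p": profile.pval[lig].values[src],
                "receptor_p": profile.pval[rec].values[tgt],
                "ligand_p_adj": profile.pval_adj[lig].values[src],
                "receptor_p_adj": profile.pval_adj[rec].values[tgt],
            }
        )
        blocks.append(block)
    edges = pd.concat(blocks, ignore_index=True)
    edges["weight_norm"] = edges["ligand_norm"] * edges["receptor_norm"]
    edges["weight_scale"] = (edges["ligand_scaled"] + edges["receptor_scaled"]) / 2.0
    edges = edges[EDGE_COLUMNS]
    return ConnectomeEdgeList(
        edges=edges,
        clusters=clusters,
        mechanisms=db.mechanism_ids,
        provenance={"n_clusters": n, "n_mechanisms": len(db)},
    )


def filter_connectome(
    conn: ConnectomeEdgeList,
    min_frac: float = 0.1,
    max_p: float = 0.05,
    min_weight_norm: float | None = None,
    min_z: float | None = None,
    sources: set | None = None,
    targets: set | None = None,
    mechanisms: set | None = None,
    families: set | None = None,
) -> ConnectomeEdgeList:
    """Retain edges expressed and significant in their respective clusters.

    An edge survives when the ligand and receptor are each expressed in
    strictly more than ``min_frac`` of the source and target cluster, and
    each have a one-vs-rest Wilcoxon p strictly below ``max_p`` — the
    ligand is tested in the source cluster and the receptor in the target.
    ``min_z`` additionally requires both scaled expressions strictly above
    it; the remaining arguments restrict to subsets of nodes/mechanisms.
    """
    if not 0 <= min_frac <= 1:
        raise ValueError("min_frac must be in [0, 1]")
    if not 0 < max_p <= 1:
        raise ValueError("max_p must be in (0, 1]")
    e = conn.edges
    keep = (
        (e["ligand_frac"] > min_frac)
        & (e["receptor_frac"] > min_frac)
        & (e["ligand_p"] < max_p)
        & (e["receptor_p"] < max_p)
    )
    if min_weight_norm is not None:
        keep &= e["weight_norm"] > min_weight_norm
    if min_z is not None:
        keep &= (e["ligand_scaled"] > min_z) & (e["receptor_scaled"] > min_z)
    if sources is not None:
        keep &= e["source"].isin(sources)
    if targets is not None:
        keep &= e["target"].isin(targets)
    if mechanisms is not None:
        keep &= e["mechanism_id"].isin(mechanisms)
    if families is not None:
        keep &= e["family"].isin(families)
    out = e[keep].reset_index(drop=True)
    if out.empty:
        logger.warning("filter_connectome: no edges survive")
    prov = dict(conn.provenance)
    prov["filter"] = {
        "min_frac": min_frac,
        "max_p": max_p,
        "min_weight_norm": min_weight_norm,
        "min_z": min_z,
        "n_before": len(e),
        "n_after": len(out),
    }
    return replace(conn, edges=out, provenance=prov)


def slice_connectome(conn: ConnectomeEdgeList, mode: str, key) -> ConnectomeEdgeList:
    """Canonical cuts through the edge tensor.

    ``interactome`` — all edges of one mechanism; ``outgoing`` — all edges
    sent by one cluster; ``niche`` — all edges received by one cluster;
    ``vector`` — all edges of one (source, target) pair.
    """
    e = conn.edges
    if mode == "interactome":
        if key not in set(conn.mechanisms):
            raise KeyError(f"unknown mechanism {key!r}; valid: {sorted(conn.mechanisms)}")
        keep = e["mechanism_id"] == key
    elif mode == "outgoing":
        if key not in set(conn.clusters):
            raise KeyError(f"unknown cluster {key!r}; valid: {sorted(map(str, conn.clusters))}")
        keep = e["source"] == key
    elif mode == "niche":
        if key not in set(conn.clusters):
            raise KeyError(f"unknown cluster {key!r}; valid: {sorted(map(str, conn.clusters))}")
        keep = e["target"] == key
    elif mode == "vector":
        src, tgt = key
        bad = [k for k in (src, tgt) if k not in set(conn.clusters)]
        if bad:
            raise KeyError(f"unknown cluster(s) {bad}; valid: {sorted(map(str, conn.clusters))}")
        keep = (e["source"] == src) & (e["target"] == tgt)
    else:
        raise ValueError(f"unknown slice mode {mode!r}; valid: {SLICE_MODES}")
    prov = dict(conn.provenance)
    prov["slice"] = {"mode": mode, "key": key if not isinstance(key, tuple) else list(key)}
    return replace(conn, edges=e[keep].reset_index(drop=True), provenance=prov)


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".provenance.json")


def write_edgelist(conn: ConnectomeEdgeList, path: str | Path) -> None:
    """Write the edge list as long-format CSV plus a JSON provenance sidecar."""
    path = Path(path)
    conn.edges.to_csv(path, index=False)
    meta = {
        "clusters": [str(c) for c in conn.clusters],
        "mechanisms": list(conn.mechanisms),
        "provenance": conn.provenance,
    }
    _sidecar(path).write_text(json.dumps(meta, indent=2, default=str))


def read_edgelist(path: str | Path) -> ConnectomeEdgeList:
    """Read an edge list CSV written by :func:`write_edgelist`."""
    path = Path(path)
    edges = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in EDGE_COLUMNS if c not in edges.columns]
    if missing:
        raise ValueError(f"edge list {path} missing columns: {missing}")
    side = _sidecar(path)
    if side.exists():
        meta = json.loads(side.read_text())
        clusters, mechanisms = meta["clusters"], meta["mechanisms"]
        provenance = meta.get("provenance", {})
    else:
        logger.warning("no provenance sidecar for %s; reconstructing vocabularies", path)
        clusters = sorted(set(edges["source"].astype(str)) | set(edges["target"].astype(str)))
        mechanisms = list(pd.unique(edges["mechanism_id"]))
        provenance = {}
    edges["source"] = edges["source"].astype(str)
    edges["target"] = edges["target"].astype(str)
    return ConnectomeEdgeList(
        edges=edges, clusters=list(clusters), mechanisms=list(mechanisms), provenance=provenance
    )
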