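"""Node centrality within signaling networks.

Two metrics, both computed on a weighted adjacency aggregated over the
mechanisms of an edge subset: the cumulative incoming/outgoing edgeweight
fraction per node, and Kleinberg hub/authority scores. Hubs send signal
that authorities receive. Networks are usually decomposed per signaling
family first, and families grouped by which cell class dominates incoming
centrality.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import ConnectomeEdgeList

logger = logging.getLogger(__name__)

CENTRALITY_COLUMNS = [
    "network_label",
    "cluster",
    "hub_score",
    "authority_score",
    "out_weight_frac",
    "in_weight_frac",
    "n_edges_considered",
]


@dataclass
class CentralityTable:
    """Long table of per-(network, cluster) centrality metrics."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in CENTRALITY_COLUMNS if c not in self.table.columns]
        if missing:
            raise ValueError(f"centrality table missing columns: {missing}")

    @property
    def network_labels(self) -> list[str]:
        return list(pd.unique(self.table["network_label"]))

    def block(self, label: str) -> pd.DataFrame:
        return self.table[self.table["network_label"] == label].set_index("cluster")

    def write(self, path) -> None:
        self.table.to_csv(path, index=False)


def aggregate_adjacency(
    conn: ConnectomeEdgeList, weight: str = "weight_scale", negative: str = "floor"
) -> pd.DataFrame:
    """Sum the chosen weight over mechanisms into a clusters x clusters matrix.

    HITS requires non-negative weights but ``weight_scale`` can be
    negative; negatives are floored at 0 by default (``negative`` may also
    be ``"drop"`` to drop those edges, or ``"shift"`` to add the global
    minimum).
    """
    if len(conn) == 0:
        raise ValueError("empty edge list")
    if weight not in ("weight_norm", "weight_scale"):
        raise ValueError("weight must be weight_norm or weight_scale")
    e = conn.edges[["source", "target", weight]].copy()
    w = e[weight].to_numpy(dtype=float)
    if negative == "floor":
        w = np.maximum(w, 0.0)
    elif negative == "drop":
        e, w = e[w > 0], w[w > 0]
    elif negative == "shift":
        if w.size and w.min() < 0:
            w = w - w.min()
    else:
        raise ValueError(f"unknown negative-weight policy {negative!r}")
    e = e.assign(w=w)
    clusters = list(conn.clusters)
    adj = (
        e.pivot_table(index="source", columns="target", values="w", aggfunc="sum", fill_value=0.0)
        .reindex(index=clusters, columns=clusters, fill_value=0.0)
    )
    if not (adj.to_numpy() > 0).any():
        raise ValueError("no positive-weight edges after aggregation")
    return adj


def hits_centrality(
    adj: pd.DataFrame | np.ndarray, tol: float = 1e-12, max_iter: int = 1000
) -> tuple[np.ndarray, np.ndarray]:
    """Kleinberg hub/authority scores by power iteration with mutual updates.

    ``hub`` is the dominant eigenvector direction of A A^T and
    ``authority`` of A^T A; iteration starts from the uniform vector
    (deterministic) and both outputs are scaled so their maximum is 1.
    """
    a = adj.to_numpy(dtype=float) if isinstance(adj, pd.DataFrame) else np.asarray(adj, dtype=float)
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValueError("adjacency must be square")
    if (a < 0).any():
        raise ValueError("adjacency must be non-negative")
    if not (a > 0).any():
        raise ValueError("adjacency has no positive entries")
    n = a.shape[0]
    hub = np.full(n, 1.0 / n)
    auth = np.full(n, 1.0 / n)
    for _ in range(max_iter):
        new_auth = a.T @ hub
        new_hub = a @ new_auth
        # normalize to max 1 each step to keep iterates bounded
        if new_auth.max() > 0:
            new_auth = new_auth / new_auth.max()
        if new_hub.max() > 0:
            new_hub = new_hub / new_hub.max()
        resid = max(np.abs(new_hub - hub).max(), np.abs(new_auth - auth).max())
        hub, auth = new_hub, new_auth
        if resid < tol:
            break
    else:
        raise RuntimeError(f"HITS did not converge in {max_iter} iterations (residual {resid:.2e})")
    return hub, auth


def weight_fractions(adj: pd.DataFrame | np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-node outgoing/incoming edgeweight as a fraction of total edgeweight."""
    a = adj.to_numpy(dtype=float) if isinstance(adj, pd.DataFrame) else np.asarray(adj, dtype=float)
    total = a.sum()
    if total <= 0:
        raise ValueError("total edgeweight is zero")
    return a.sum(axis=1) / total, a.sum(axis=0) / total


def _centrality_block(conn: ConnectomeEdgeList, weight: str, label: str) -> pd.DataFrame:
    adj = aggregate_adjacency(conn, weight=weight)
    hub, auth = hits_centrality(adj)
    out_frac, in_frac = weight_fractions(adj)
    return pd.DataFrame(
        {
            "network_label": label,
            "cluster": list(adj.index),
            "hub_score": hub,
            "authority_score": auth,
            "out_weight_frac": out_frac,
            "in_weight_frac": in_frac,
            "n_edges_considered": len(conn),
        }
    )


def network_centrality(
    conn: ConnectomeEdgeList, weight: str = "weight_scale", label: str = "network"
) -> CentralityTable:
    """Centrality metrics for one edge subset as a single network block."""
    return CentralityTable(_centrality_block(conn, weight, label))


def family_centrality(
    conn: ConnectomeEdgeList, weight: str = "weight_scale", families: set[str] | None = None
) -> CentralityTable:
    """Per-family centrality: subset to each family's edges, then score nodes.

    Families with no positive-weight edge after aggregation are skipped
    with a log entry.
    """
    wanted = sorted(families) if families is not None else conn.families
    blocks = []
    for fam in wanted:
        sub = conn.edges[conn.edges["family"] == fam]
        sub_conn = ConnectomeEdgeList(
            edges=sub.reset_index(drop=True),
            clusters=conn.clusters,
            mechanisms=[m for m in conn.mechanisms if m in set(sub["mechanism_id"])],
            provenance=dict(conn.provenance),
        )
        try:
            blocks.append(_centrality_block(sub_conn, weight, fam))
        except ValueError as err:
            logger.info("skipping family %s: %s", fam, err)
    if not blocks:
        raise ValueError("no family yielded a positive-weight network")
    return CentralityTable(pd.concat(blocks, ignore_index=True))


def group_by_dominant_receiver(
    table: CentralityTable, class_map: dict
) -> dict[str, str]:
    """Assign each family network to the class of its dominant receiver.

    The dominant receiver is the cluster with maximal authority score; ties
    break by incoming weight fraction, then lexicographic cluster name.
    """
    missing = [
        c for c in table.table["cluster"].unique() if c not in class_map
    ]
    if missing:
        raise KeyError(f"class_map missing clusters: {missing}")
    out = {}
    for label in table.network_labels:
        block = table.block(label).reset_index()
        block = block.sort_values(
            by=["authority_score", "in_weight_frac", "cluster"],
            ascending=[False, False, True],
            kind="mergesort",
        )
        out[label] = class_map[block.iloc[0]["cluster"]]
    return out


def compare_centrality(
    tables: list[tuple[str, CentralityTable]]
) -> pd.DataFrame:
    """Stack centrality tables from several systems for side-by-side comparison.

    Systems need not share cell types; clusters absent from a system simply
    have no row.
    """
    if len(tables) < 2:
        raise ValueError("need at least 2 systems to compare")
    frames = []
    for system, tab in tables:
        t = tab.table.copy()
        if t.empty:
            logger.warning("system %s contributes no centrality rows", system)
        t.insert(0, "system", system)
        frames.append(t)
    return pd.concat(frames, ignore_index=True)
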