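"""Vectortype embedding.

Each (source celltype, target celltype) pair — a "vectortype" — is a
feature vector of mechanism edgeweights. Similar vectortypes use similar
signaling channels. Rows are L2-normalized, joined into a k-nearest-
neighbor graph on Euclidean distance, laid out in 2D with a seeded
force-directed layout, and clustered by Leiden community detection on the
kNN graph. Coordinates are seed-dependent; the kNN graph and communities
are deterministic given the distances and seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import igraph
import leidenalg
import networkx as nx
import numpy as np
import pandas as pd
from sklearn.neighbors import NearestNeighbors

from .core import ConnectomeEdgeList


@dataclass
class VectortypeMatrix:
    """(source, target) x mechanism matrix of edgeweights."""

    values: pd.DataFrame  # MultiIndex rows (source, target), columns mechanism_id

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            raise ValueError("duplicate (source, target) rows")
        if not np.isfinite(self.values.to_numpy(float)).all():
            raise ValueError("non-finite values in vectortype matrix")

    @property
    def pairs(self) -> list[tuple]:
        return list(self.values.index)

    def __len__(self) -> int:
        return len(self.values)


def build_vectortype_matrix(
    conn: ConnectomeEdgeList, weight: str = "weight_scale", min_nonzero: int = 0
) -> VectortypeMatrix:
    """Pivot the edge list to (source, target) rows x mechanism columns.

    Edges removed by filtering fill in as 0; rows with fewer than
    ``min_nonzero`` nonzero entries are dropped.
    """
    if len(conn) == 0:
        raise ValueError("empty edge list")
    wide = conn.edges.pivot_table(
        index=["source", "target"], columns="mechanism_id", values=weight, fill_value=0.0
    )
    wide = wide.reindex(columns=conn.mechanisms, fill_value=0.0)
    if min_nonzero > 0:
        wide = wide[(wide.to_numpy() != 0).sum(axis=1) >= min_nonzero]
    return VectortypeMatrix(values=wide)


def knn_graph(vm: VectortypeMatrix, n_neighbors: int) -> nx.Graph:
    """Undirected kNN graph (Euclidean on L2-normalized rows)."""
    x = vm.values.to_numpy(dtype=float)
    norms = np.linalg.norm(x, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    x = x / norms
    if len(vm) < n_neighbors + 1:
        raise ValueError(f"need at least {n_neighbors + 1} rows for {n_neighbors} neighbors")
    nn = NearestNeighbors(n_neighbors=n_neighbors + 1, metric="euclidean").fit(x)
    _, idx = nn.kneighbors(x)
    g = nx.Graph()
    g.add_nodes_from(range(len(vm)))
    for i, row in enumerate(idx):
        for j in row[1:]:
            g.add_edge(i, int(j))
    return g


def embed_vectortypes(
    vm: VectortypeMatrix,
    n_neighbors: int = 10,
    seed: int = 0,
    resolution: float = 1.0,
) -> pd.DataFrame:
    """2D coordinates plus a community label for every vectortype.

    Returns a table with columns source, target, dim1, dim2,
    vectortype_cluster; deterministic given ``seed``.
    """
    g = knn_graph(vm, n_neighbors)
    pos = nx.spring_layout(g, seed=seed)
    ig = igraph.Graph(n=g.number_of_nodes(), edges=list(g.edges()))
    part = leidenalg.find_partition(
        ig,
        leidenalg.RBConfigurationVertexPartition,
        resolution_parameter=resolution,
        seed=seed,
    )
    membership = np.asarray(part.membership)
    coords = np.array([pos[i] for i in range(len(vm))])
    idx = vm.values.index
    return pd.DataFrame(
        {
            "source": idx.get_level_values(0),
            "target": idx.get_level_values(1),
            "dim1": coords[:, 0],
            "dim2": coords[:, 1],
            "vectortype_cluster": membership,
        }
    )
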