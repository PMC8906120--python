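"""Minimal network rendering.

Directed graph drawings where edge thickness is proportional to the
chosen weight and edge color keyed to the source celltype. Every plot
also writes a companion CSV of exactly the data drawn, so figure-level
assertions are data assertions.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import networkx as nx
import pandas as pd


def plot_network(
    edges: pd.DataFrame,
    weight: str,
    out_path: str | Path,
    seed: int = 0,
    max_linewidth: float = 6.0,
) -> pd.DataFrame:
    """Render an edge table as a directed graph; returns the drawn-data table.

    ``edges`` needs source/target columns and the ``weight`` column.
    Negative weights draw at zero width. The companion CSV is written next
    to the image with suffix ``.data.csv``.
    """
    if edges.empty:
        raise ValueError("cannot plot an empty edge list")
    out_path = Path(out_path)
    drawn = (
        edges.groupby(["source", "target"], as_index=False)[weight]
        .sum()
        .rename(columns={weight: "weight"})
    )
    wmax = max(drawn["weight"].max(), 1e-12)
    drawn["linewidth"] = drawn["weight"].clip(lower=0) / wmax * max_linewidth

    g = nx.DiGraph()
    g.add_nodes_from(sorted(set(drawn["source"]) | set(drawn["target"])))
    for _, r in drawn.iterrows():
        g.add_edge(r["source"], r["target"], weight=r["weight"], linewidth=r["linewidth"])
    pos = nx.circular_layout(g)
    sources = sorted(set(drawn["source"]))
    cmap = plt.get_cmap("tab20")
    color_of = {s: cmap(i % 20) for i, s in enumerate(sources)}

    fig, ax = plt.subplots(figsize=(6, 6))
    nx.draw_networkx_nodes(g, pos, ax=ax, node_color="lightgray", node_size=900)
    nx.draw_networkx_labels(g, pos, ax=ax, font_size=8)
    for u, v, d in g.edges(data=True):
        nx.draw_networkx_edges(
            g,
            pos,
            edgelist=[(u, v)],
            ax=ax,
            width=max(d["linewidth"], 0.1),
            edge_color=[color_of[u]],
            connectionstyle="arc3,rad=0.1",
        )
    ax.set_axis_off()
    fig.savefig(out_path, dpi=120)
    plt.close(fig)
    drawn.to_csv(out_path.with_suffix(out_path.suffix + ".data.csv"), index=False)
    return drawn
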