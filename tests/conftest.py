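import numpy as np
import pandas as pd
import pytest

from lrconnect import (
    ClusteredExpression,
    SyntheticSpec,
    cluster_profile,
    create_connectome,
    generate,
    normalize,
)
from lrconnect.lrdb import LRDatabase, LRPair


@pytest.fixture
def tiny_lr_csv(tmp_path):
    p = tmp_path / "lr.csv"
    p.write_text(
        "ligand,receptor,family,mode\n"
        "TGFB1,TGFBR1,TGFB,secreted\n"
        "TGFB1,TGFBR2,TGFB,secreted\n"
        "VEGFA,KDR,VEGF,secreted\n"
    )
    return p


@pytest.fixture
def toy_db():
    return LRDatabase(
        pairs=[
            LRPair("L1", "R1", family="famA"),
            LRPair("L2", "R2", family="famB"),
        ]
    )


def make_expression(values, clusters, genes=None, is_normalized=False, is_log1p=False):
    """Small dense ClusteredExpression from a nested list."""
    values = np.asarray(values, dtype=float)
    n_cells, n_genes = values.shape
    genes = genes or [f"g{j}" for j in range(n_genes)]
    cells = [f"c{i}" for i in range(n_cells)]
    return ClusteredExpression(
        matrix=values,
        gene_names=pd.Index(genes),
        cell_ids=pd.Index(cells),
        cluster_labels=pd.Series(clusters, index=cells),
        is_normalized=is_normalized,
        is_log1p=is_log1p,
    )


@pytest.fixture
def toy_profile(toy_db):
    # 3 clusters x 4 cells; L1 marks A, R1 marks B, L2/R2 spread
    rng = np.random.default_rng(0)
    base = rng.uniform(0.1, 0.5, size=(12, 4))
    base[0:4, 0] += 3.0  # L1 high in A
    base[4:8, 1] += 3.0  # R1 high in B
    expr = make_expression(
        base,
        clusters=["A"] * 4 + ["B"] * 4 + ["C"] * 4,
        genes=["L1", "R1", "L2", "R2"],
        is_normalized=True,
    )
    return cluster_profile(expr)


@pytest.fixture
def toy_connectome(toy_profile, toy_db):
    return create_connectome(toy_profile, toy_db)


@pytest.fixture(scope="session")
def planted_system():
    """One medium synthetic tissue run through the full single-tissue path."""
    spec = SyntheticSpec(
        planted_edges=[("C0", "LIG1", "C1", "REC1", 4.0), ("C2", "LIG2", "C3", "REC2", 4.0)],
        seed=11,
    )
    expr, db, truth = generate(spec)
    norm = normalize(expr)
    profile = cluster_profile(norm)
    conn = create_connectome(profile, db)
    return {"spec": spec, "expr": norm, "db": db, "truth": truth, "profile": profile, "conn": conn}
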