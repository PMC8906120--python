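"""Cluster-structured synthetic single-cell counts with planted LR signal.

Counts are drawn from a negative binomial (overdispersed relative to
Poisson, as scRNA-seq counts are) with independent Bernoulli dropout.
A planted edge (source cluster, ligand, target cluster, receptor,
effect size) multiplies the ligand's mean in its source cluster and the
receptor's mean in its target cluster, creating a cluster-specific
ligand-receptor channel the inference should recover. The returned
database holds the planted pairs plus decoy pairs drawn among background
genes, so ranking and type-I behavior can both be probed. The generator
is a caricature — no batch effects, trajectories or gene-gene
correlation — sufficient for exercising thresholds and rankings.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .lrdb import LRDatabase, LRPair, make_mechanism_id
from .preprocess import ClusteredExpression

PlantedEdge = tuple[str, str, str, str, float]  # (source, ligand, target, receptor, effect)
ConditionEffect = tuple[str, str, float]  # (cluster, gene, fold)


@dataclass
class SyntheticSpec:
    """Declarative description of a synthetic clustered tissue."""

    n_clusters: int = 4
    cells_per_cluster: int = 200
    n_background_genes: int = 50
    planted_edges: list[PlantedEdge] = field(default_factory=list)
    baseline_mean: float = 1.0
    dispersion: float = 0.5  # NB size parameter; smaller = more overdispersed
    dropout_rate: float = 0.1
    condition_effects: list[ConditionEffect] = field(default_factory=list)
    n_decoy_pairs: int = 10
    seed: int = 0

    @property
    def cluster_names(self) -> list[str]:
        return [f"C{i}" for i in range(self.n_clusters)]

    @property
    def background_genes(self) -> list[str]:
        return [f"BG{i:03d}" for i in range(self.n_background_genes)]

    @property
    def planted_genes(self) -> list[str]:
        out: list[str] = []
        for _, lig, _, rec, _ in self.planted_edges:
            for g in (lig, rec):
                if g not in out:
                    out.append(g)
        return out

    def validate(self) -> None:
        problems = []
        if self.n_clusters < 2:
            problems.append("n_clusters must be >= 2")
        if self.cells_per_cluster < 1:
            problems.append("cells_per_cluster must be >= 1")
        if self.n_background_genes < 1:
            problems.append("n_background_genes must be >= 1")
        if self.baseline_mean <= 0:
            problems.append("baseline_mean must be positive")
        if self.dispersion <= 0:
            problems.append("dispersion must be positive")
        if not 0 <= self.dropout_rate < 1:
            problems.append("dropout_rate must be in [0, 1)")
        bg = set(self.background_genes)
        clusters = set(self.cluster_names)
        for src, lig, tgt, rec, eff in self.planted_edges:
            if src not in clusters or tgt not in clusters:
                problems.append(f"planted edge {src}->{tgt} names unknown cluster")
            if lig in bg or rec in bg:
                problems.append(f"planted genes {lig}/{rec} collide with background names")
            if eff < 1:
                problems.append(f"planted effect size {eff} must be >= 1")
        all_genes = bg | set(self.planted_genes)
        for cl, gene, fold in self.condition_effects:
            if cl not in clusters:
                problems.append(f"condition effect names unknown cluster {cl}")
            if gene not in all_genes:
                problems.append(f"condition effect names unknown gene {gene}")
            if fold <= 0:
                problems.append(f"condition fold {fold} must be positive")
        if problems:
            raise ValueError("invalid SyntheticSpec: " + "; ".join(problems))


def _mean_matrix(spec: SyntheticSpec, condition: str | None) -> tuple[pd.DataFrame, list[str]]:
    genes = spec.planted_genes + spec.background_genes
    means = pd.DataFrame(
        spec.baseline_mean, index=spec.cluster_names, columns=genes, dtype=float
    )
    for src, lig, tgt, rec, eff in spec.planted_edges:
        means.loc[src, lig] *= eff
        means.loc[tgt, rec] *= eff
    if condition == "test":
        for cl, gene, fold in spec.condition_effects:
            means.loc[cl, gene] *= fold
    return means, genes


def _draw_counts(
    spec: SyntheticSpec, means: pd.DataFrame, genes: list[str], rng: np.random.Generator, tag: str
) -> ClusteredExpression:
    n_cells = spec.n_clusters * spec.cells_per_cluster
    labels = np.repeat(spec.cluster_names, spec.cells_per_cluster)
    theta = spec.dispersion
    mean_per_cell = means.loc[labels, genes].to_numpy(float)
    p = theta / (theta + mean_per_cell)
    counts = rng.negative_binomial(theta, p).astype(float)
    if spec.dropout_rate > 0:
        counts *= rng.random(counts.shape) >= spec.dropout_rate
    cell_ids = pd.Index([f"{tag}_cell{i:05d}" for i in range(n_cells)])
    return ClusteredExpression(
        matrix=counts,
        gene_names=pd.Index(genes),
        cell_ids=cell_ids,
        cluster_labels=pd.Series(labels, index=cell_ids),
        is_normalized=False,
    )


def _database(spec: SyntheticSpec, rng: np.random.Generator) -> LRDatabase:
    pairs = [
        LRPair(ligand=lig, receptor=rec, family="planted")
        for _, lig, _, rec, _ in spec.planted_edges
    ]
    seen = {p.mechanism_id for p in pairs}
    bg = spec.background_genes
    guard = 0
    while len(pairs) < len(spec.planted_edges) + spec.n_decoy_pairs and guard < 10000:
        guard += 1
        lig, rec = rng.choice(bg, size=2, replace=False)
        key = make_mechanism_id(lig, rec)
        if key in seen:
            continue
        seen.add(key)
        pairs.append(LRPair(ligand=str(lig), receptor=str(rec), family="decoy"))
    return LRDatabase(pairs=pairs)


def _ground_truth(spec: SyntheticSpec) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "source": src,
                "ligand": lig,
                "target": tgt,
                "receptor": rec,
                "effect_size": eff,
                "mechanism_id": make_mechanism_id(lig, rec),
            }
            for src, lig, tgt, rec, eff in spec.planted_edges
        ]
    )


def generate(spec: SyntheticSpec) -> tuple[ClusteredExpression, LRDatabase, pd.DataFrame]:
    """Draw one clustered count matrix plus its LR database and ground truth."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    means, genes = _mean_matrix(spec, condition=None)
    expr = _draw_counts(spec, means, genes, rng, tag="ctrl")
    db = _database(spec, rng)
    return expr, db, _ground_truth(spec)


def generate_pair(
    spec: SyntheticSpec,
) -> tuple[ClusteredExpression, ClusteredExpression, LRDatabase, pd.DataFrame]:
    """Draw a control/test pair differing only by the spec's condition effects."""
    spec.validate()
    if not spec.condition_effects:
        raise ValueError("generate_pair requires non-empty condition_effects")
    rng = np.random.default_rng(spec.seed)
    means_ctrl, genes = _mean_matrix(spec, condition=None)
    means_test, _ = _mean_matrix(spec, condition="test")
    ctrl = _draw_counts(spec, means_ctrl, genes, rng, tag="ctrl")
    test = _draw_counts(spec, means_test, genes, rng, tag="test")
    db = _database(spec, rng)
    truth = _ground_truth(spec)
    return ctrl, test, db, truth
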