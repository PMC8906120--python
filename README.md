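# lrconnect

Ligand–receptor cell–cell connectomics for clustered single-cell RNA-seq
data. Given a cells × genes expression matrix, a per-cell cluster (cell
type) assignment and a reference table of known ligand→receptor
signaling mechanisms (e.g. the FANTOM5 pair list), `lrconnect` builds the
complete directed, weighted cell–cell signaling network, filters it to
the expressed and statistically specific edges, quantifies each cell
type's sending/receiving role, compares two conditions edge-for-edge,
and embeds cell–cell "vectortypes" by their signaling profiles.

It is aimed at computational biologists who already have a clustered
single-cell object and want a quantitative, graph-theoretic view of
intercellular signaling — within one tissue, or between a control and a
perturbed condition.

## The model

Cells are parcellated into cell types (nodes). For every ordered pair of
clusters *(i, j)* — self-pairs included — and every ligand–receptor
mechanism *k* = (L, R), one edge is created with two weights:

- **weight_norm** (w₁) = mean normalized expression of L in cluster *i*
  × mean normalized expression of R in cluster *j*. Raw connectivity;
  comparable across conditions.
- **weight_scale** (w₂) = mean of the system-wide gene z-scores of L
  (in *i*) and R (in *j*). Specificity of the edge within the system;
  suited to ranking cellular roles in one tissue.

Single-tissue analysis keeps edges whose ligand and receptor are each
expressed in > 10 % of their respective clusters and are each
cluster-specific at p < 0.05 by a one-vs-rest Wilcoxon rank-sum test.
Node roles are measured by Kleinberg hub/authority scores and by each
node's share of total incoming/outgoing edgeweight, usually per
signaling family.

Differential analysis aligns two connectomes edge-for-edge and scores
each edge with

  score = |log₂ FC(ligand in source)| × |log₂ FC(receptor in target)|,

gated by a per-cluster cross-condition Wilcoxon test (p < 0.05 on both
sides) and an expressed-in-either-condition rule. The fold-change signs
classify each perturbed edge as activated (both up), deactivated (both
down), ligand starvation (ligand down, receptor up) or ligand pressure
(ligand up, receptor down).

## Worked example

Simulate a 4-cluster tissue (200 cells per cluster, negative-binomial
counts) with two planted channels — cluster C0 signals to C1 through
LIG1→REC1 and C2 to C3 through LIG2→REC2, both at 4× enrichment — plus
10 decoy mechanisms among background genes:

```python
from lrconnect import *

spec = SyntheticSpec(
    planted_edges=[("C0", "LIG1", "C1", "REC1", 4.0),
                   ("C2", "LIG2", "C3", "REC2", 4.0)], seed=0)
expr, db, truth = generate(spec)
conn = create_connectome(cluster_profile(normalize(expr)), db)
filt = filter_connectome(conn, min_frac=0.1, max_p=0.05)
print(filt.edges.nlargest(5, "weight_scale")[
    ["source", "target", "mechanism_id", "family",
     "weight_norm", "weight_scale", "ligand_p", "receptor_p"]])
```

```
source target mechanism_id  family  weight_norm  weight_scale  ligand_p  receptor_p
    C2     C3    LIG2|REC2 planted     3.81e+05         0.461  1.08e-12     1.5e-20
    C0     C1    LIG1|REC1 planted     3.74e+05         0.454  1.38e-17    1.15e-14
    C3     C3    LIG2|REC2 planted     9.92e+04         0.216    0.0477     1.5e-20
    C0     C3    LIG1|REC1 planted     9.09e+04         0.168  1.38e-17     0.00883
    C0     C3    LIG2|REC2 planted     8.52e+04         0.162  0.000534     1.5e-20
```

The two planted edges top the specificity ranking. Centrality on the
filtered network recovers the planted senders as hubs and receivers as
authorities:

```python
print(family_centrality(filt).block("planted").round(3))
```

```
         hub_score  authority_score  out_weight_frac  in_weight_frac
cluster
C0           1.000            0.319            0.426           0.127
C1           0.141            0.801            0.059           0.392
C2           0.827            0.049            0.352           0.022
C3           0.441            1.000            0.162           0.459
```

C0 and C2 dominate sending (hub, outgoing weight), C1 and C3 receiving
(authority, incoming weight) — exactly the planted architecture.

The same steps are available from the shell:

```bash
lrconnect simulate --out-dir sim --seed 0
lrconnect build --matrix sim/matrix.mtx --lr-db sim/lr_db.csv --out-dir run
lrconnect filter --edges run/edges.csv --min-frac 0.1 --max-p 0.05 --out-dir run
lrconnect centrality --edges run/edges_filtered.csv --per-family --out-dir run
```

## Acceptance script

`scripts/acceptance.py` exercises the whole pipeline from scratch:
it simulates a control/test pair with planted single-tissue and
condition effects, builds and filters both connectomes, runs per-family
centrality, the differential comparison with cross-condition testing,
and the vectortype embedding, printing stage-by-stage edge counts.

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

## Layout

- `lrconnect.lrdb` — ligand–receptor reference tables (loading,
  family subsetting, gene restriction; a small bundled example table).
- `lrconnect.preprocess` — normalization, system-wide z-scaling, and
  per-cluster summary statistics including the Wilcoxon marker test.
- `lrconnect.core` — edge-list construction, filtering, slicing
  (interactome / outgoing / niche / vector), lossless CSV round-trips.
- `lrconnect.centrality` — hub/authority and edgeweight-fraction
  centrality, per-family decomposition, dominant-receiver grouping.
- `lrconnect.differential` — fold changes, cross-condition testing,
  perturbation scores, four-way edge categorization.
- `lrconnect.embedding` — kNN-graph embedding and community detection
  on celltype–celltype vectortypes.
- `lrconnect.simulate` — the synthetic-data generator used throughout
  the tests.
- `lrconnect.cli` — the `lrconnect` command-line interface.
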