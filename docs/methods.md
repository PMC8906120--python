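# Methods

## Model and procedure

A clustered single-cell dataset is reduced to a directed, weighted
multigraph. Nodes are cell-type clusters. For every ordered cluster pair
*(i, j)* (including *i = j*, autocrine signaling) and every
ligand–receptor mechanism *k* = (L, R) in the reference table whose two
genes are measured, one edge is created. The full, unfiltered edge list
therefore has |clusters|² × |mechanisms| rows, and every analysis is a
subset of it: an *interactome* (one mechanism, all pairs), an *outgoing
network* (one source, everything it sends), a *niche* (one target,
everything it receives), or a *vector* (one ordered pair).

Edge attributes come from four per-cluster, per-gene summaries:

- `mean_norm` — mean normalized expression. Cells are library-size
  normalized to a common total (default 10 000) and log1p-transformed;
  cluster means are taken on the un-logged (expm1) normalized scale so
  that downstream ratios are ratios of expression, not of its
  logarithm. If a matrix is supplied already normalized on a linear
  scale, values are averaged as-is.
- `mean_scaled` — mean of the gene's z-scores computed across **all**
  retained cells (sample SD, ddof = 1; zero-variance genes map to 0).
  System-wide scaling is what makes the scaled weight a measure of
  specificity within the whole tissue rather than within one cluster.
- `frac_expr` — fraction of the cluster's cells with expression > 0.
- `pval` — two-sided one-vs-rest Wilcoxon rank-sum p-value of the gene
  in the cluster against all other retained cells, with a
  Benjamini–Hochberg adjusted companion column (the default gates use
  raw p, the adjusted values are surfaced for users).

The two edge weights are
`weight_norm = mean_norm(L, i) × mean_norm(R, j)` (raw connectivity) and
`weight_scale = (mean_scaled(L, i) + mean_scaled(R, j)) / 2`
(specificity). Single-tissue filtering keeps edges with
`frac_expr > min_frac` (default 0.1) and `pval < max_p` (default 0.05)
for the ligand in the source cluster **and** the receptor in the target
cluster; fraction and p comparisons are strict, matching the
greater-than / less-than reading of the thresholds, and boundary
behavior is pinned by tests. An optional `min_z` gate requires both
scaled expressions strictly above a z-score cutoff.

## Wilcoxon testing

Rank-sum p-values are computed by `scipy.stats.mannwhitneyu`, vectorized
over genes. For total sample size ≤ 25 the exact null distribution of
the U statistic (computed on midranks) is used — this reproduces the
exact permutation p-value for small tied toys such as (0,0,0) vs
(2,2,2) → p = 0.1 — and larger samples use the normal approximation
with tie and continuity corrections. Degenerate comparisons (a group
with < 2 cells in cross-condition mode, or all values identical) report
p = 1. The test suite checks small-sample exactness against an
independent exhaustive enumeration oracle.

## Centrality

An edge subset (typically one signaling family) is aggregated into a
clusters × clusters adjacency by summing the chosen weight over
mechanisms per (source, target). Two node metrics are computed:

- cumulative outgoing/incoming edgeweight per node, expressed as a
  fraction of the subset's total edgeweight;
- Kleinberg hub and authority scores, by power iteration with mutual
  reinforcement from a uniform start (deterministic; tolerance 1e-12 in
  max-norm), each vector scaled to maximum 1 for plot readability.

`weight_scale` can be negative; HITS requires non-negative weights, so
negative values are floored at 0 during aggregation (configurable to
"drop" or "shift"). On the filtered networks the metrics are meant for,
surviving scaled weights are positive in practice, so the floor rarely
binds; this is a package design decision, not a property inherited from
the method description. Families whose aggregated adjacency has no
positive entry are skipped with a log message. Per-family networks are
summarized by their *dominant receiver*: the cluster with maximal
authority score (ties broken by incoming weight fraction, then
lexicographic name), mapped through a user-supplied cluster → class
map. Centrality tables from systems with different cell-type sets stack
without padding for cross-system comparison.

## Differential connectomics

Two unfiltered connectomes built against the same reference table and
sharing cluster labels are joined on (source, target, mechanism).
Per edge, `log2fc = log₂((test + c) / (ctrl + c))` with a symmetric
pseudocount c (default 0.01) applied to the mean normalized expression
of the ligand in the source and the receptor in the target; a gene with
zero mean in both conditions gets a fold change of exactly 0. The
perturbation score is the product of the absolute fold changes —
zero iff either side is unchanged, unbounded above, invariant to sign
and to swapping the conditions. Sign combinations classify edges as
UP_UP (activated), DOWN_DOWN (deactivated), UP_DOWN (ligand pressure)
or DOWN_UP (ligand starvation); exactly-zero fold changes fall into a
fifth NULL bucket so unperturbed edges never contaminate the four
classes. Significance gating uses a per-cluster Wilcoxon test of test
vs control on individual cells; the filter requires p < 0.05 on both
sides (strict), expression > 10 % of the cluster in **either**
condition (strict), and perturbation score ≥ a floor (inclusive,
matching the "minimum score" reading).

## Vectortype embedding

Each (source, target) pair is a feature vector of mechanism weights
(default `weight_scale`; filtered-out edges contribute 0). Rows are
L2-normalized, joined into an undirected k-nearest-neighbor graph
(Euclidean, `sklearn`), laid out in 2D with a seeded force-directed
(spring) layout, and clustered with seeded Leiden community detection
on the kNN graph. The concrete recipe is a package choice made for
reproducibility; coordinates are seed-dependent and carry no tested
meaning — all structural claims (and all tests) are about the kNN graph
and its communities, which are deterministic given the distances and
seed.

## Synthetic data

The generator emulates the statistical structure the method assumes:
cluster-labeled cells, overdispersed counts, and cluster-specific
ligand/receptor enrichment. Counts are negative binomial with
configurable mean (default 1.0) and size/dispersion parameter (default
0.5, variance = m + m²/θ), followed by independent Bernoulli dropout
(default rate 0.1). A planted edge multiplies the ligand's mean in its
source cluster and the receptor's mean in its target cluster by the
effect size (default scenarios use 4×, with 4 clusters × 200 cells and
10 decoy mechanisms drawn among background genes). Condition effects
multiply chosen (cluster, gene) means in the test condition only, with
control and test otherwise identical in law. Everything is a pure
function of the spec including its seed.

What the generator does **not** model: batch effects, trajectories,
gene–gene correlation, compositional shifts, empty droplets or ambient
RNA. A green planted-recovery test therefore establishes that the
pipeline's ranking and gating behave correctly under clean
cluster-specific enrichment — not that the method is robust to the full
messiness of real tissue data.

## Numerical choices

- Deterministic edge order (mechanism, then source, then target) and
  round-trip float parsing (`float_precision="round_trip"`) make CSV
  outputs byte-reproducible.
- Z-scores use sample SD (ddof = 1) to match the dominant single-cell
  ecosystem; clipping is off by default because it changes
  `weight_scale`.
- The fold-change pseudocount (0.01) is small relative to normalized
  means at the default scale factor (order 10²–10³), so it matters only
  near zero, where it regularizes the otherwise-undefined ratio.
- Power iteration on a 2-cycle-free adjacency converges geometrically;
  ties in the dominant eigenspace (e.g. perfectly symmetric graphs)
  resolve to the uniform vector because iteration starts uniform.

## Known limitations

- Multi-subunit receptor complexes are not modeled; the reference table
  is strictly pairwise.
- Cluster labels must match exactly across conditions; no fuzzy
  harmonization.
- Negative-weight handling in centrality and the embedding recipe are
  package decisions where the method description is silent; both are
  configurable and documented above.
- No spatial or downstream-transduction information enters the edge
  weights.
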