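"""Independent brute-force oracles used only by the test suite."""

from itertools import combinations

import numpy as np


def exact_ranksum_pvalue(x, y):
    """Two-sided Wilcoxon rank-sum p by exhaustive enumeration.

    Midranks handle ties; the null is every assignment of the pooled ranks
    to a group of size len(x); the p-value is the fraction of assignments
    whose rank-sum deviates from its null mean at least as much as observed.
    """
    x, y = np.asarray(x, float), np.asarray(y, float)
    pooled = np.concatenate([x, y])
    order = np.argsort(pooled, kind="mergesort")
    ranks = np.empty(len(pooled))
    sorted_vals = pooled[order]
    i = 0
    while i < len(pooled):
        j = i
        while j + 1 < len(pooled) and sorted_vals[j + 1] == sorted_vals[i]:
            j += 1
        ranks[order[i : j + 1]] = (i + j) / 2 + 1
        i = j + 1
    nx = len(x)
    observed = ranks[:nx].sum()
    mu = ranks.sum() * nx / len(pooled)
    dev = abs(observed - mu)
    hits = total = 0
    for combo in combinations(range(len(pooled)), nx):
        total += 1
        if abs(ranks[list(combo)].sum() - mu) >= dev - 1e-12:
            hits += 1
    return hits / total


def dense_hits(adj):
    """Hub/authority via dense symmetric eigendecomposition, max-normalized."""
    a = np.asarray(adj, float)
    out = []
    for m in (a @ a.T, a.T @ a):
        vals, vecs = np.linalg.eigh(m)
        v = vecs[:, np.argmax(vals)]
        v = np.abs(v)  # Perron direction of a non-negative PSD matrix
        out.append(v / v.max())
    return tuple(out)
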