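"""Wilcoxon rank-sum p-values, vectorized over genes.

Small samples (total n <= 25) use scipy's exact null distribution of the
Mann-Whitney U statistic computed on midranks; larger samples use the
normal approximation with tie and continuity corrections. Degenerate
comparisons (all values identical, or an empty group) report p = 1.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import stats

EXACT_MAX_N = 25


def rank_sum_pvalues(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Two-sided Wilcoxon rank-sum p-value per column of two (cells x genes) arrays."""
    x = np.atleast_2d(np.asarray(x, dtype=float))
    y = np.atleast_2d(np.asarray(y, dtype=float))
    n_genes = x.shape[1]
    if x.shape[0] < 1 or y.shape[0] < 1:
        return np.ones(n_genes)
    method = "exact" if x.shape[0] + y.shape[0] <= EXACT_MAX_N else "asymptotic"
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # constant columns produce harmless divide warnings
        res = stats.mannwhitneyu(x, y, axis=0, method=method, alternative="two-sided")
    p = np.asarray(res.pvalue, dtype=float).reshape(n_genes)
    # columns where every value ties across both groups carry no information
    p = np.where(np.isnan(p), 1.0, np.minimum(p, 1.0))
    return p
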