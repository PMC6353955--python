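"""Cross-stage association statistics.

Pearson correlation for linear-scale comparisons, Spearman rank
correlation for log-scale ones, the Wilcoxon rank-sum test for group
comparisons, and the fraction-of-occupied-motifs (FOM) ratio.  For small
samples p-values are exact: correlations use full permutation enumeration
(all n! rearrangements of y) and the rank-sum test the exact null
distribution of the rank sum; larger samples fall back to the usual
asymptotic approximations.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

#: largest n for which correlation p-values are computed by full enumeration
EXACT_PERMUTATION_MAX_N = 8
#: largest min(group size) for which the rank-sum test is exact (tie-free)
EXACT_RANKSUM_MAX_N = 20


@dataclass
class AssociationResult:
    method: str
    statistic: float
    p_value: float
    n: int


def _pearson_r(x: np.ndarray, y: np.ndarray) -> float:
    xc = x - x.mean()
    yc = y - y.mean()
    return float(xc @ yc / np.sqrt((xc @ xc) * (yc @ yc)))


def _exact_permutation_p(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided exact permutation p-value for the correlation of x and y."""
    r_obs = abs(_pearson_r(x, y))
    count = 0
    total = 0
    for perm in itertools.permutations(range(len(y))):
        total += 1
        if abs(_pearson_r(x, y[list(perm)])) >= r_obs - 1e-12:
            count += 1
    return count / total


def correlate(x, y, method: str = "pearson") -> AssociationResult:
    """Correlation with a two-sided p-value.

    ``method`` is ``"pearson"`` (linear scale) or ``"spearman"`` (rank
    based, average ranks on ties; appropriate for log-scale displays).
    Replicate measurements should be averaged by the caller beforehand.
    For n <= 8 the p-value is an exact permutation enumeration; otherwise
    the standard asymptotic p-value is used.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have the same length")
    n = int(x.size)
    if n < 3:
        raise ValueError("need at least 3 observations")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance input")
    if method == "spearman":
        xr = sps.rankdata(x)
        yr = sps.rankdata(y)
        stat = _pearson_r(xr, yr)
        if n <= EXACT_PERMUTATION_MAX_N:
            p = _exact_permutation_p(xr, yr)
        else:
            p = float(sps.spearmanr(x, y).pvalue)
    elif method == "pearson":
        stat = _pearson_r(x, y)
        if n <= EXACT_PERMUTATION_MAX_N:
            p = _exact_permutation_p(x, y)
        else:
            p = float(sps.pearsonr(x, y).pvalue)
    else:
        raise ValueError("method must be 'pearson' or 'spearman'")
    return AssociationResult(method=method, statistic=float(stat), p_value=float(p), n=n)


def rank_sum_test(group_a, group_b) -> AssociationResult:
    """Two-sided Wilcoxon rank-sum test.

    Exact null enumeration for tie-free samples with min(n) <= 20, normal
    approximation with continuity correction otherwise.  The statistic is
    the rank sum W of ``group_a``.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 3 or b.size < 3:
        raise ValueError("both groups need at least 3 observations")
    pooled = np.concatenate([a, b])
    has_ties = np.unique(pooled).size < pooled.size
    exact = (not has_ties) and min(a.size, b.size) <= EXACT_RANKSUM_MAX_N
    res = sps.mannwhitneyu(
        a, b, alternative="two-sided", method="exact" if exact else "asymptotic"
    )
    w = float(res.statistic + a.size * (a.size + 1) / 2)  # U -> rank sum of a
    return AssociationResult(
        method="ranksum", statistic=w, p_value=float(res.pvalue), n=int(a.size + b.size)
    )


def fraction_occupied_motifs(n_peaks_with_motif: int, n_genome_occurrences: int) -> float:
    """FOM: ChIP-seq peaks containing the top motif over its genome-wide count."""
    if n_genome_occurrences <= 0:
        raise ValueError("genome occurrence count must be positive")
    if n_peaks_with_motif < 0:
        raise ValueError("peak count must be non-negative")
    return n_peaks_with_motif / n_genome_occurrences
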