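"""Rank-based exact tests and multiple-testing helpers.

The exact null distributions for the Wilcoxon rank-sum and signed-rank
statistics are computed by dynamic programming over doubled mid-ranks
(doubling makes tie-averaged ranks integral), so ties and zero differences
are handled exactly; above the exact-size cutoffs the tests fall back to the
normal approximation with tie correction.  Two-sided p-values double the
smaller tail and are capped at 1, matching the convention of exact rank
tests.
"""

from __future__ import annotations

import numpy as np
import scipy.stats
from statsmodels.stats.multitest import multipletests

from .types import DataError

EXACT_MAX = 25


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (monotone, clipped to [0, 1])."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def _doubled_ranks(values: np.ndarray) -> np.ndarray:
    """Tie-averaged ranks multiplied by two, as exact integers."""
    ranks = scipy.stats.rankdata(values) * 2
    out = np.rint(ranks).astype(np.int64)
    assert np.allclose(ranks, out)
    return out


def _ranksum_null(ranks2: np.ndarray, n_x: int) -> np.ndarray:
    """Distribution of the doubled rank-sum of a size-``n_x`` subset.

    ``null[k, s]`` counts size-``k`` subsets of ``ranks2`` summing to ``s``;
    the returned vector is the ``k = n_x`` row.
    """
    total = int(ranks2.sum())
    table = np.zeros((n_x + 1, total + 1))
    table[0, 0] = 1.0
    for r in ranks2:
        r = int(r)
        # iterate k downwards so each rank is used at most once
        for k in range(n_x, 0, -1):
            table[k, r:] += table[k - 1, : total + 1 - r]
    return table[n_x]


def ranksum_test(x, y, exact_max: int = EXACT_MAX) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    Returns ``(rank_sum_of_x, p)``.  Exact when both groups have at most
    ``exact_max`` observations, normal approximation with tie correction
    otherwise.  Identical constant samples give p = 1 by convention.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise DataError("both groups must be non-empty")
    combined = np.concatenate([x, y])
    if np.ptp(combined) == 0:
        return float(scipy.stats.rankdata(combined)[: x.size].sum()), 1.0
    ranks2 = _doubled_ranks(combined)
    w2 = int(ranks2[: x.size].sum())
    if x.size <= exact_max and y.size <= exact_max:
        null = _ranksum_null(ranks2, x.size)
        total = null.sum()
        lower = null[: w2 + 1].sum() / total
        upper = null[w2:].sum() / total
        p = min(1.0, 2.0 * min(lower, upper))
    else:
        p = float(scipy.stats.mannwhitneyu(
            x, y, alternative="two-sided", method="asymptotic").pvalue)
    return w2 / 2.0, p


def _signed_rank_null(ranks2: np.ndarray) -> np.ndarray:
    """Distribution of the doubled positive-rank sum over sign assignments."""
    total = int(ranks2.sum())
    dist = np.zeros(total + 1)
    dist[0] = 1.0
    for r in ranks2:
        r = int(r)
        new = dist.copy()
        new[r:] += dist[: total + 1 - r]
        dist = new
    return dist


def signed_rank_test(differences, exact_max: int = EXACT_MAX
                     ) -> tuple[float, float]:
    """Two-sided Wilcoxon signed-rank test on paired differences.

    Zero differences are dropped; ties receive average ranks.  Exact (by
    enumeration of sign assignments, via DP) for at most ``exact_max``
    non-zero pairs, normal approximation otherwise.  All-zero differences
    give p = 1.
    """
    d = np.asarray(differences, dtype=float)
    d = d[d != 0]
    if d.size == 0:
        return 0.0, 1.0
    ranks2 = _doubled_ranks(np.abs(d))
    w2 = int(ranks2[d > 0].sum())
    if d.size <= exact_max:
        null = _signed_rank_null(ranks2)
        total = null.sum()
        lower = null[: w2 + 1].sum() / total
        upper = null[w2:].sum() / total
        p = min(1.0, 2.0 * min(lower, upper))
    else:
        p = float(scipy.stats.wilcoxon(
            d, alternative="two-sided", mode="approx").pvalue)
    return w2 / 2.0, p


def hypergeom_upper(k: int, N: int, K: int, n: int) -> float:
    """Upper-tail hypergeometric probability P(X >= k) for overlap ``k``
    between a size-``K`` category and a size-``n`` draw from ``N`` items."""
    if N <= 0:
        raise DataError("empty universe")
    if K < 0 or n < 0 or K > N or n > N:
        raise DataError("invalid hypergeometric parameters")
    return float(scipy.stats.hypergeom.sf(k - 1, N, K, n))
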