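"""Exact and rank-based statistics, implemented from first principles.

These are the small-sample tests the pipeline reports p-values through.
Fisher's exact test enumerates the full hypergeometric family of tables with
the observed margins in log-space; the two-sided p is the minimum-likelihood
convention (sum over tables no more probable than the observed one, with a
1e-7 relative tolerance on the comparison), which is the convention of
mainstream statistical software. The signed-rank test is exact up to n = 25
via dynamic programming on doubled mid-ranks (so tied ranks stay integral)
and uses a continuity-corrected normal approximation beyond. Mid-ranks are
used for ties everywhere.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.special import gammaln
from scipy.stats import norm, rankdata, t as t_dist

__all__ = [
    "ContingencyTable2x2",
    "fisher_exact_2x2",
    "wilcoxon_signed_rank",
    "wilcoxon_rank_sum",
    "spearman",
    "bh_fdr",
    "bonferroni",
]

_REL_TOL = 1e-7


@dataclass(frozen=True)
class ContingencyTable2x2:
    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for v in (self.a, self.b, self.c, self.d):
            if v < 0 or v != int(v):
                raise ValueError("cell counts must be non-negative integers")
        if self.a + self.b + self.c + self.d == 0:
            raise ValueError("table total must be positive")


def _log_hypergeom_pmf(a: np.ndarray, r1: int, r2: int, c1: int) -> np.ndarray:
    """log P(A = a) for the hypergeometric family with fixed margins."""
    n = r1 + r2

    def lc(x, y):
        return gammaln(x + 1) - gammaln(y + 1) - gammaln(x - y + 1)

    return lc(r1, a) + lc(r2, c1 - a) - lc(n, c1)


def fisher_exact_2x2(table: ContingencyTable2x2 | Sequence[Sequence[int]]) -> float:
    """Two-sided Fisher exact p-value for a 2x2 table."""
    if not isinstance(table, ContingencyTable2x2):
        (a, b), (c, d) = table
        table = ContingencyTable2x2(int(a), int(b), int(c), int(d))
    r1, r2 = table.a + table.b, table.c + table.d
    c1 = table.a + table.c
    a_min = max(0, c1 - r2)
    a_max = min(r1, c1)
    support = np.arange(a_min, a_max + 1)
    logp = _log_hypergeom_pmf(support.astype(float), r1, r2, c1)
    log_obs = float(_log_hypergeom_pmf(np.array([float(table.a)]), r1, r2, c1)[0])
    include = logp <= log_obs + math.log1p(_REL_TOL)
    # log-sum-exp over the included tables
    m = logp[include].max()
    p = float(np.exp(m) * np.exp(logp[include] - m).sum())
    return min(p, 1.0)


def _signed_rank_distribution(doubled_ranks: np.ndarray) -> np.ndarray:
    """Exact null pmf of W+ on the support of summed doubled ranks.

    Each difference contributes its doubled mid-rank with probability 1/2;
    returns counts[w] over w = 0..sum(doubled_ranks), to be divided by 2^n.
    """
    total = int(doubled_ranks.sum())
    counts = np.zeros(total + 1)
    counts[0] = 1.0
    for r in doubled_ranks:
        r = int(r)
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: total + 1 - r]
        counts = counts + shifted
    return counts


def wilcoxon_signed_rank(
    x: Sequence[float], y: Sequence[float] | None = None
) -> tuple[float, float]:
    """Two-sided Wilcoxon signed-rank test on paired differences.

    Pass differences directly, or two paired samples. Zero differences are
    dropped; mid-ranks handle ties. Exact enumeration of the null for
    n <= 25 non-zero differences, continuity-corrected normal approximation
    above. Returns (W+, two-sided p).
    """
    d = np.asarray(x, dtype=float)
    if y is not None:
        d = d - np.asarray(y, dtype=float)
    d = d[d != 0.0]
    n = d.size
    if n == 0:
        raise ValueError("all paired differences are zero")
    if n < 5:
        raise ValueError("need at least 5 non-zero paired differences")
    ranks = rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    if n <= 25:
        doubled = np.round(2.0 * ranks).astype(int)
        counts = _signed_rank_distribution(doubled)
        total = counts.sum()  # 2^n
        w2 = int(round(2.0 * w_plus))
        p_le = counts[: w2 + 1].sum() / total
        p_ge = counts[w2:].sum() / total
        p = min(1.0, 2.0 * min(p_le, p_ge))
        return w_plus, float(p)
    mean = n * (n + 1) / 4.0
    tie_groups = np.unique(ranks, return_counts=True)[1]
    var = n * (n + 1) * (2 * n + 1) / 24.0 - ((tie_groups**3 - tie_groups).sum()) / 48.0
    z = (w_plus - mean - 0.5 * np.sign(w_plus - mean)) / math.sqrt(var)
    return w_plus, float(min(1.0, 2.0 * norm.sf(abs(z))))


def wilcoxon_rank_sum(
    x: Sequence[float], y: Sequence[float]
) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    Returns (rank sum of x, p) using the tie-corrected, continuity-corrected
    normal approximation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = x.size, y.size
    if n1 == 0 or n2 == 0:
        raise ValueError("both samples must be non-empty")
    combined = np.concatenate([x, y])
    ranks = rankdata(combined)
    w = float(ranks[:n1].sum())
    n = n1 + n2
    mean = n1 * (n + 1) / 2.0
    tie_groups = np.unique(ranks, return_counts=True)[1]
    tie_term = ((tie_groups**3 - tie_groups).sum()) / (n * (n - 1))
    var = n1 * n2 / 12.0 * (n + 1 - tie_term)
    if var <= 0:
        return w, 1.0
    z = (w - mean - 0.5 * np.sign(w - mean)) / math.sqrt(var)
    return w, float(min(1.0, 2.0 * norm.sf(abs(z))))


def spearman(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Spearman rank correlation: Pearson correlation of mid-ranks.

    The p-value uses the t approximation with n - 2 degrees of freedom.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 points")
    rx, ry = rankdata(x), rankdata(y)
    sx, sy = rx.std(), ry.std()
    if sx == 0 or sy == 0:
        raise ValueError("constant input: rank correlation undefined")
    rho = float(np.corrcoef(rx, ry)[0, 1])
    if abs(rho) >= 1.0:
        return float(np.sign(rho)), 0.0
    t_stat = rho * math.sqrt((n - 2) / (1.0 - rho * rho))
    p = float(min(1.0, 2.0 * t_dist.sf(abs(t_stat), df=n - 2)))
    return rho, p


def bh_fdr(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values with monotonicity enforcement."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def bonferroni(p_values: Sequence[float]) -> np.ndarray:
    """Bonferroni adjustment: min(1, m * p)."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return np.minimum(1.0, p * p.size)
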