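"""Exact and vectorized Mann-Whitney U machinery.

The per-probe scan and the permutation null both reduce to the same
computation: for a fixed probes x samples matrix, the rank of each value
within its probe row never changes when group labels are permuted, so the
U statistic for any labeling is a sum over the case columns of a
precomputed rank matrix.  Exact (enumeration-based) two-sided p-values for
tie-free rows are then a table lookup on integer U; rows with ties fall
back to the tie-corrected normal approximation whose variance is likewise
label-invariant.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats


def u_null_counts(n1: int, n2: int) -> np.ndarray:
    """Counts of label assignments yielding each U value in 0..n1*n2.

    Classic recursion: f(n1, n2, u) = f(n1-1, n2, u-n2) + f(n1, n2-1, u),
    realised as an iterative Gaussian-binomial convolution.  The total is
    C(n1+n2, n1).
    """
    if n1 < 0 or n2 < 0:
        raise ValueError("group sizes must be nonnegative")
    umax = n1 * n2
    # dp[i][u] = count for i case samples and the current number of controls
    dp = np.zeros((n1 + 1, umax + 1), dtype=np.float64)
    dp[:, 0] = 1.0  # zero controls: U is always 0
    for j in range(1, n2 + 1):
        for i in range(1, n1 + 1):
            # c(i, j, u) = c(i-1, j, u-j) + c(i, j-1, u)
            shifted = np.zeros(umax + 1)
            shifted[j:] = dp[i - 1, : umax + 1 - j]
            dp[i] = dp[i] + shifted
    return dp[n1]


def exact_two_sided_table(n1: int, n2: int) -> np.ndarray:
    """Two-sided exact p-value indexed by integer U (0..n1*n2), no ties."""
    counts = u_null_counts(n1, n2)
    total = counts.sum()
    cdf = np.cumsum(counts) / total
    sf = np.cumsum(counts[::-1])[::-1] / total  # P(U >= u)
    p = 2.0 * np.minimum(cdf, sf)
    return np.minimum(p, 1.0)


def _tie_adjusted_sigma(row_sorted: np.ndarray, n1: int, n2: int) -> float:
    """Std dev of U under the null with tie correction (values pre-sorted)."""
    n = n1 + n2
    if n < 2:
        return 0.0
    _, t = np.unique(row_sorted, return_counts=True)
    tie_term = float(np.sum(t**3 - t))
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    return math.sqrt(max(var, 0.0))


def _normal_p(u: np.ndarray, n1: int, n2: int, sigma, continuity: bool = False):
    """Two-sided normal-approximation p for U statistic(s)."""
    mu = n1 * n2 / 2.0
    dev = np.abs(np.asarray(u, dtype=float) - mu)
    if continuity:
        dev = np.maximum(dev - 0.5, 0.0)
    sigma = np.asarray(sigma, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(sigma > 0, dev / np.where(sigma > 0, sigma, 1.0), 0.0)
    p = 2.0 * stats.norm.sf(z)
    p = np.where(sigma > 0, p, 1.0)
    return np.minimum(p, 1.0)


def mwu_exact_p(
    a,
    b,
    exact_threshold: int = 25,
    continuity: bool = False,
) -> float:
    """Two-sided Mann-Whitney U p-value for two samples.

    Exact by enumeration of the U null distribution when the smaller group
    has at most ``exact_threshold`` observations and the pooled data are
    tie-free; tie-corrected normal approximation (no continuity correction
    by default) otherwise.  Symmetric in (a, b).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be nonempty")
    if not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise ValueError("non-finite values in input")
    pooled = np.concatenate([a, b])
    if np.ptp(pooled) == 0.0:
        return 1.0
    has_ties = np.unique(pooled).size < pooled.size
    if not has_ties and min(a.size, b.size) <= exact_threshold:
        method = "exact"
    else:
        method = "asymptotic"
    res = stats.mannwhitneyu(
        a, b, alternative="two-sided", method=method, use_continuity=continuity
    )
    return float(res.pvalue)


@dataclass
class RankScan:
    """Label-invariant per-row rank state for a probes x samples matrix."""

    ranks: np.ndarray          # K x N average ranks per row
    tie_free: np.ndarray       # K bool, row has no tied values
    sigma: np.ndarray          # K tie-adjusted normal sd of U (for given n1, n2)
    n1: int
    n2: int
    exact_table: np.ndarray | None  # p by integer U, None if exact disabled

    @property
    def n(self) -> int:
        return self.n1 + self.n2


def prepare_rank_scan(
    values: np.ndarray,
    n1: int,
    exact_threshold: int = 25,
) -> RankScan:
    """Precompute ranks, tie structure and the exact-p table for a matrix.

    ``values`` is probes x samples with the convention that any label
    assignment selects ``n1`` of the columns as group 1.  Rows must be
    complete (no NaN) — callers route incomplete rows through the scalar
    path.
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 2:
        raise ValueError("expected a 2-D matrix")
    n2 = values.shape[1] - n1
    if n1 < 1 or n2 < 1:
        raise ValueError("need at least one sample per group")
    ranks = stats.rankdata(values, axis=1)
    srt = np.sort(values, axis=1)
    tie_free = ~np.any(srt[:, 1:] == srt[:, :-1], axis=1)
    sigma = np.array(
        [_tie_adjusted_sigma(srt[i], n1, n2) for i in range(values.shape[0])]
    )
    table = None
    if min(n1, n2) <= exact_threshold:
        table = exact_two_sided_table(n1, n2)
    return RankScan(ranks, tie_free, sigma, n1, n2, table)


def scan_p_for_labels(rs: RankScan, case_cols: np.ndarray,
                      continuity: bool = False) -> np.ndarray:
    """p-value per row for one labeling (case column indices)."""
    return scan_p_for_label_matrix(
        rs, np.asarray(case_cols, dtype=int)[:, None], continuity
    )[:, 0]


def scan_p_for_label_matrix(
    rs: RankScan, case_col_matrix: np.ndarray, continuity: bool = False
) -> np.ndarray:
    """p-values (rows x labelings) for many labelings at once.

    ``case_col_matrix`` is n1 x B: each column lists the case column
    indices of one labeling.  U per labeling is a gather-sum over the
    precomputed rank matrix.
    """
    n1, n2 = rs.n1, rs.n2
    if case_col_matrix.shape[0] != n1:
        raise ValueError("labeling matrix must have n1 rows")
    # rank sums: K x B
    rank_sums = rs.ranks[:, case_col_matrix].sum(axis=1)
    u = rank_sums - n1 * (n1 + 1) / 2.0
    p = np.empty_like(u)
    if rs.exact_table is not None and rs.tie_free.any():
        tf = rs.tie_free
        p[tf] = rs.exact_table[np.rint(u[tf]).astype(int)]
        rest = ~tf
    else:
        rest = np.ones(u.shape[0], dtype=bool)
    if rest.any():
        p[rest] = _normal_p(u[rest], n1, n2, rs.sigma[rest, None], continuity)
    return p
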