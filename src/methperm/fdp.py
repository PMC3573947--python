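"""Permutation control of the false discovery proportion (FDP).

The procedure: permute case/control labels B times while preserving the
group sizes, recompute every probe's Mann-Whitney p-value per
permutation, and sort each permutation's p-vector ascending.  The
distribution over permutations of the "best" (smallest) p-value
calibrates the gamma = 0 cutoff: at confidence 1 - alpha the cutoff is
the ceil(alpha * B)-th smallest permutation minimum, and observed
p-values strictly below it are declared significant with FDP = 0 at that
confidence.  For gamma > 0 the rank-substitution generalization is used:
find the largest s such that the s-th smallest observed p lies strictly
below the ceil(alpha * B)-th smallest value of the per-permutation
(floor(gamma * s) + 1)-th order statistic; the top s probes are declared,
guaranteeing FDP <= gamma with confidence 1 - alpha.  gamma = 0 reduces
exactly to the best-p rule.

Only case and control samples are permuted; variant-of-unknown-
significance samples never enter the null.  The observed labeling is not
counted among the B sampled permutations; exhaustive mode enumerates
every distinct assignment exactly once (and therefore contains it).
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._mwu import mwu_exact_p, prepare_rank_scan, scan_p_for_label_matrix


@dataclass
class PermutationNull:
    """Sorted per-permutation p-values (B x K, rows ascending)."""

    sorted_p: np.ndarray
    probe_ids: np.ndarray
    n_case: int
    n_control: int
    seed: int | None
    exhaustive: bool

    @property
    def B(self) -> int:
        return self.sorted_p.shape[0]


def n_distinct_assignments(n_case: int, n_control: int) -> int:
    return math.comb(n_case + n_control, n_case)


def build_null(
    beta: pd.DataFrame,
    sheet: pd.DataFrame,
    B: int = 1000,
    seed: int = 0,
    exhaustive: bool = False,
    exact_threshold: int = 25,
    exhaustive_cap: int = 200_000,
) -> PermutationNull:
    """Permutation null of sorted per-probe p-values.

    Sampling mode draws ``B`` label permutations from the given seed; if
    ``B`` is at least the number of distinct assignments, a warning is
    issued and the mode switches to exhaustive enumeration.  Rows of
    ``sorted_p`` are each permutation's probe p-values sorted ascending.
    """
    s = sheet.set_index("sample_id") if "sample_id" in sheet else sheet
    cases = [c for c in beta.columns if c in s.index and s.loc[c, "group"] == "case"]
    controls = [c for c in beta.columns
                if c in s.index and s.loc[c, "group"] == "control"]
    if not cases or not controls:
        raise ValueError("both case and control groups must be present")
    cols = cases + controls
    n1, n = len(cases), len(cols)
    total = n_distinct_assignments(n1, n - n1)

    if not exhaustive and B >= total:
        warnings.warn(
            f"B={B} >= {total} distinct assignments; switching to exhaustive",
            stacklevel=2,
        )
        exhaustive = True
    if exhaustive and total > exhaustive_cap:
        raise ValueError(
            f"{total} assignments exceed exhaustive_cap={exhaustive_cap}"
        )

    X = beta[cols].to_numpy(dtype=float)
    incomplete = np.isnan(X).any(axis=1)
    rs = prepare_rank_scan(X[~incomplete], n1, exact_threshold) \
        if (~incomplete).any() else None

    if exhaustive:
        labelings = np.array(
            list(itertools.combinations(range(n), n1)), dtype=int
        ).T  # n1 x total
    else:
        rng = np.random.default_rng(seed)
        labelings = np.empty((n1, B), dtype=int)
        for b in range(B):
            labelings[:, b] = rng.permutation(n)[:n1]
    nperm = labelings.shape[1]

    P = np.empty((X.shape[0], nperm))
    if rs is not None:
        P[~incomplete] = scan_p_for_label_matrix(rs, labelings)
    for i in np.flatnonzero(incomplete):
        row = X[i]
        for b in range(nperm):
            sel = np.zeros(n, dtype=bool)
            sel[labelings[:, b]] = True
            a = row[sel]
            c = row[~sel]
            a = a[~np.isnan(a)]
            c = c[~np.isnan(c)]
            P[i, b] = mwu_exact_p(a, c, exact_threshold) \
                if (a.size >= 2 and c.size >= 2) else np.nan
    sorted_p = np.sort(P.T, axis=1)  # nperm x K, NaN sorts last
    return PermutationNull(
        sorted_p=sorted_p,
        probe_ids=beta.index.to_numpy(),
        n_case=n1,
        n_control=n - n1,
        seed=None if exhaustive else seed,
        exhaustive=exhaustive,
    )


def _alpha_rank(alpha: float, B: int) -> int:
    if alpha * B < 1:
        raise ValueError(
            f"B={B} cannot resolve alpha={alpha}; minimum feasible alpha is {1 / B}"
        )
    return math.ceil(alpha * B)


def fdp_cutoff(
    null: PermutationNull,
    gamma: float = 0.0,
    alpha: float = 0.05,
    observed_p: np.ndarray | None = None,
) -> float:
    """p-value cutoff controlling FDP <= gamma at confidence 1 - alpha.

    gamma = 0: the ceil(alpha*B)-th smallest per-permutation minimum p.
    gamma > 0 requires the observed p-vector (rank-substitution rule; see
    module docstring).  Observed p strictly below the cutoff is
    significant.
    """
    if gamma < 0:
        raise ValueError("gamma must be >= 0")
    if not (0 < alpha < 1):
        raise ValueError("alpha must be in (0, 1)")
    B = null.B
    r = _alpha_rank(alpha, B)
    if gamma == 0:
        minima = np.sort(null.sorted_p[:, 0])
        return float(minima[r - 1])
    if observed_p is None:
        raise ValueError("gamma > 0 requires the observed p-vector")
    obs = np.sort(np.asarray(observed_p, dtype=float))
    obs = obs[~np.isnan(obs)]
    K = null.sorted_p.shape[1]

    def threshold(s: int) -> float:
        j = min(int(math.floor(gamma * s)), K - 1)  # order-statistic index
        col = np.sort(null.sorted_p[:, j])
        return float(col[r - 1])

    for s in range(min(obs.size, K), 0, -1):
        t = threshold(s)
        if obs[s - 1] < t:
            return t
    return 0.0


@dataclass
class FdpResult:
    """Significant sets per (gamma, alpha) plus a count grid."""

    cutoffs: dict[tuple[float, float], float]
    significant: dict[tuple[float, float], set]
    counts: pd.DataFrame            # rows gamma, columns alpha
    loss_gain: dict[tuple[float, float], tuple[int, int]] = field(default_factory=dict)


def call_significant(
    diff: pd.DataFrame,
    null: PermutationNull,
    gammas: tuple[float, ...] = (0.0, 0.05, 0.1, 0.2),
    alphas: tuple[float, ...] = (0.005, 0.05, 0.1),
) -> FdpResult:
    """Apply permutation cutoffs to an observed scan over a (gamma, alpha) grid.

    ``diff`` is a probe_scan table on the same probe set as the null.
    Probes with observed p strictly below the cutoff are significant;
    counts are tallied per cell with loss (delta_beta < 0) / gain
    (delta_beta > 0) direction splits.
    """
    diff_ids = np.asarray(diff["probe_id"])
    if set(diff_ids) != set(null.probe_ids):
        raise ValueError("diff table and permutation null cover different probes")
    pv = diff.set_index("probe_id")["p_value"]
    delta = diff.set_index("probe_id")["delta_beta"]
    cutoffs: dict[tuple[float, float], float] = {}
    signif: dict[tuple[float, float], set] = {}
    loss_gain: dict[tuple[float, float], tuple[int, int]] = {}
    counts = pd.DataFrame(0, index=list(gammas), columns=list(alphas))
    obs = pv.to_numpy(dtype=float)
    for g in gammas:
        for a in alphas:
            c = fdp_cutoff(null, g, a, observed_p=obs)
            hit = set(pv.index[pv < c])
            cutoffs[(g, a)] = c
            signif[(g, a)] = hit
            counts.loc[g, a] = len(hit)
            d = delta.loc[list(hit)] if hit else delta.iloc[0:0]
            loss_gain[(g, a)] = (int((d < 0).sum()), int((d > 0).sum()))
    counts.index.name = "gamma"
    counts.columns.name = "alpha"
    return FdpResult(cutoffs, signif, counts, loss_gain)
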