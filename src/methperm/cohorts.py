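"""Multi-group, sex, dosage and population-reference comparisons.

Covers the analyses around the core case/control scan: Kruskal-Wallis
tests across karyotype or tissue groups, a sex-difference scan with
Benjamini-Hochberg q-values, monotone dose-response assessment of
methylation against functional KDM5C/KDM5D copy number (Spearman rho and
a Jonckheere-Terpstra trend test), and an outlier screen of query
samples against a large population reference.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from ._mwu import mwu_exact_p
from .simulate import effective_dose


def _kw_h(groups: list[np.ndarray]) -> float:
    """Tie-corrected Kruskal-Wallis H statistic."""
    pooled = np.concatenate(groups)
    n = pooled.size
    ranks = stats.rankdata(pooled)
    h = 0.0
    start = 0
    for g in groups:
        r = ranks[start:start + g.size]
        h += r.sum() ** 2 / g.size
        start += g.size
    h = 12.0 / (n * (n + 1)) * h - 3 * (n + 1)
    _, t = np.unique(pooled, return_counts=True)
    corr = 1.0 - np.sum(t**3 - t) / (n**3 - n)
    return h / corr if corr > 0 else 0.0


def _multiset_assignments(indices: tuple[int, ...], sizes: list[int]):
    """Yield every split of ``indices`` into ordered groups of the given sizes."""
    if len(sizes) == 1:
        yield (indices,)
        return
    for first in itertools.combinations(indices, sizes[0]):
        rest = tuple(i for i in indices if i not in set(first))
        for tail in _multiset_assignments(rest, sizes[1:]):
            yield (first, *tail)


def kruskal_wallis(*groups, exact: bool = False) -> tuple[float, float]:
    """Kruskal-Wallis H and p across >= 2 groups.

    ``exact=True`` enumerates every assignment of the pooled values to
    the group sizes (feasible for total n <= 10) and returns the exact
    tail probability P(H >= observed); otherwise the chi-square
    approximation with groups - 1 degrees of freedom is used.
    """
    if len(groups) < 2:
        raise ValueError("need >= 2 groups")
    arrs = [np.asarray(g, dtype=float) for g in groups]
    if any(a.size == 0 for a in arrs):
        raise ValueError("empty group")
    pooled = np.concatenate(arrs)
    if np.ptp(pooled) == 0:
        return 0.0, 1.0
    if exact:
        n = pooled.size
        if n > 10:
            raise ValueError("exact mode supported for total n <= 10")
        h_obs = _kw_h(arrs)
        sizes = [a.size for a in arrs]
        count = 0
        total = 0
        for parts_idx in _multiset_assignments(tuple(range(n)), sizes):
            parts = [pooled[list(ix)] for ix in parts_idx]
            if _kw_h(parts) >= h_obs - 1e-12:
                count += 1
            total += 1
        return float(h_obs), count / total
    h, p = stats.kruskal(*arrs)
    return float(h), float(p)


def sex_scan(
    beta: pd.DataFrame,
    sheet: pd.DataFrame,
    probes=None,
) -> pd.DataFrame:
    """Per-probe male/female Mann-Whitney scan with BH q-values."""
    s = sheet.set_index("sample_id") if "sample_id" in sheet else sheet
    males = [c for c in beta.columns if c in s.index and s.loc[c, "sex"] == "M"]
    females = [c for c in beta.columns if c in s.index and s.loc[c, "sex"] == "F"]
    if not males or not females:
        raise ValueError("both sexes must be present")
    sub = beta.loc[probes] if probes is not None else beta
    rows = []
    for pid, row in sub.iterrows():
        f = row[females].to_numpy(dtype=float)
        m = row[males].to_numpy(dtype=float)
        f = f[~np.isnan(f)]
        m = m[~np.isnan(m)]
        p = mwu_exact_p(f, m)
        rows.append((pid, float(np.mean(f)), float(np.mean(m)), p))
    out = pd.DataFrame(rows, columns=["probe_id", "mean_female", "mean_male",
                                      "p_value"])
    out["delta_beta"] = out["mean_female"] - out["mean_male"]
    out["q_value"] = bh_qvalues(out["p_value"].to_numpy())
    return out


def bh_qvalues(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    return multipletests(np.asarray(p, dtype=float), method="fdr_bh")[1]


def jonckheere_terpstra(
    groups: list[np.ndarray],
    n_perm: int = 2000,
    seed: int = 0,
) -> tuple[float, float]:
    """JT trend statistic across ordered groups with a permutation p.

    The statistic sums, over ordered group pairs (i < j), the count of
    value pairs where the later group exceeds the earlier (ties count
    half).  The two-sided p is estimated by permuting pooled values
    across the group sizes with a seeded generator.
    """

    def jt_stat(parts):
        t = 0.0
        for i in range(len(parts)):
            for j in range(i + 1, len(parts)):
                a, b = parts[i], parts[j]
                t += (b[:, None] > a[None, :]).sum() \
                    + 0.5 * (b[:, None] == a[None, :]).sum()
        return t

    arrs = [np.asarray(g, dtype=float) for g in groups]
    obs = jt_stat(arrs)
    pooled = np.concatenate(arrs)
    sizes = [a.size for a in arrs]
    npairs = sum(
        sizes[i] * sizes[j]
        for i in range(len(sizes)) for j in range(i + 1, len(sizes))
    )
    center = npairs / 2.0
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(pooled)
        parts = []
        start = 0
        for sz in sizes:
            parts.append(perm[start:start + sz])
            start += sz
        if abs(jt_stat(parts) - center) >= abs(obs - center) - 1e-12:
            hits += 1
    return float(obs), (hits + 1) / (n_perm + 1)


@dataclass
class DosageTrend:
    spearman_rho: float
    spearman_p: float
    jt_stat: float
    jt_p: float
    group_means: pd.Series  # indexed by group label, ordered by dose


def dosage_trend(
    beta_row: pd.Series,
    sheet: pd.DataFrame,
    kdm5d_weight: float = 0.5,
    n_perm: int = 2000,
    seed: int = 0,
) -> DosageTrend:
    """Dose-response of one probe's beta against effective KDM5C/KDM5D dose."""
    s = sheet.set_index("sample_id") if "sample_id" in sheet else sheet
    s = s.loc[[c for c in beta_row.index if c in s.index]]
    if "effective_dose" in s:
        dose = s["effective_dose"].to_numpy(dtype=float)
    else:
        dose = effective_dose(
            s["kdm5c_copies"].to_numpy(), s["kdm5d_copies"].to_numpy(),
            kdm5d_weight,
        )
    if np.ptp(dose) == 0:
        raise ValueError("constant dose: trend undefined")
    vals = beta_row.loc[s.index].to_numpy(dtype=float)
    rho, rho_p = stats.spearmanr(dose, vals)
    order = pd.Series(dose, index=s.index).groupby(s["group"]).mean() \
        .sort_values()
    grouped = [vals[(s["group"] == g).to_numpy()] for g in order.index]
    if len(grouped) < 3:
        raise ValueError("need >= 3 dose groups")
    jt, jt_p = jonckheere_terpstra(grouped, n_perm=n_perm, seed=seed)
    means = pd.Series(
        [float(np.mean(g)) for g in grouped], index=order.index,
        name="mean_beta",
    )
    return DosageTrend(float(rho), float(rho_p), jt, jt_p, means)


@dataclass
class OutlierScreen:
    flags: pd.DataFrame      # query samples x probes, bool
    rule: str
    n_flagged_samples: int


def population_outlier_screen(
    query: pd.DataFrame,
    reference: pd.DataFrame,
    margin: float = 0.0,
    rule: str = "minimum",
    min_reference: int = 30,
) -> OutlierScreen:
    """Flag query samples whose beta falls below the population reference.

    ``query`` and ``reference`` are probes x samples on a shared probe
    set.  Under the default ``minimum`` rule a query observation is
    flagged when it lies below the reference minimum minus ``margin``;
    the robust alternative ``mad`` flags values below
    reference median - 5 * MAD.
    """
    probes = query.index.intersection(reference.index)
    if len(probes) == 0:
        raise ValueError("query and reference share no probes")
    ref = reference.loc[probes]
    if ref.shape[1] < min_reference:
        import warnings

        warnings.warn(
            f"reference has {ref.shape[1]} < {min_reference} samples; "
            "screen computed anyway",
            stacklevel=2,
        )
    if rule == "minimum":
        lower = ref.min(axis=1) - margin
    elif rule == "mad":
        med = ref.median(axis=1)
        mad = (ref.sub(med, axis=0)).abs().median(axis=1)
        lower = med - 5.0 * mad
    else:
        raise ValueError(f"unknown rule {rule!r}")
    q = query.loc[probes]
    flags = q.lt(lower, axis=0)
    return OutlierScreen(
        flags=flags.T,
        rule=rule,
        n_flagged_samples=int(flags.any(axis=0).sum()),
    )
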