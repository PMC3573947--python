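"""Group comparisons: Kruskal-Wallis, sex scan, dosage trend, outlier screen."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from methperm import (DosageConfig, bh_qvalues, dosage_trend,
                      jonckheere_terpstra, kruskal_wallis,
                      population_outlier_screen, sex_scan,
                      simulate_dosage_cohort)


def test_kruskal_constant_pooled_data():
    h, p = kruskal_wallis([1.0, 1.0], [1.0, 1.0, 1.0])
    assert h == 0.0 and p == 1.0


def test_kruskal_single_group_rejected():
    with pytest.raises(ValueError):
        kruskal_wallis([1.0, 2.0])


def test_two_group_kruskal_approaches_mwu(rng):
    """K-W with 2 groups is asymptotically the two-sided rank-sum test."""
    a = rng.normal(0.0, 1.0, 50)
    b = rng.normal(0.4, 1.0, 50)
    _, p_kw = kruskal_wallis(a, b)
    p_mwu = stats.mannwhitneyu(a, b, alternative="two-sided",
                               method="asymptotic",
                               use_continuity=False).pvalue
    assert p_kw == pytest.approx(p_mwu, rel=0.05)


def kw_exact_oracle(groups):
    """Independent enumeration over raw permutations using scipy's H."""
    pooled = np.concatenate(groups)
    sizes = [len(g) for g in groups]
    h_obs = stats.kruskal(*groups)[0]
    hits = total = 0
    for perm in itertools.permutations(pooled):
        parts, start = [], 0
        for s in sizes:
            parts.append(np.asarray(perm[start:start + s]))
            start += s
        try:
            h = stats.kruskal(*parts)[0]
        except ValueError:  # all identical after permutation
            h = 0.0
        hits += h >= h_obs - 1e-12
        total += 1
    return hits / total


def test_kruskal_exact_matches_enumeration_oracle(rng):
    groups = [rng.random(2), rng.random(3), rng.random(2)]
    h, p = kruskal_wallis(*groups, exact=True)
    assert h == pytest.approx(stats.kruskal(*groups)[0])
    assert p == pytest.approx(kw_exact_oracle(groups), rel=1e-9)


def test_bh_step_up_arithmetic():
    q = bh_qvalues([0.01, 0.02, 0.03, 0.04])
    assert np.allclose(q, [0.04, 0.04, 0.04, 0.04])
    # monotone with p, max 1, order-invariant
    p = np.array([0.2, 0.01, 0.9, 0.04])
    q = bh_qvalues(p)
    assert (q[np.argsort(p)] == np.sort(q)).all() and q.max() <= 1
    assert np.allclose(bh_qvalues(p[::-1])[::-1], q)


def _sex_cohort(rng, n_m=48, n_f=51, n_probes=9, n_spiked=5, effect=0.03):
    males = [f"m{i}" for i in range(n_m)]
    females = [f"f{i}" for i in range(n_f)]
    base = rng.uniform(0.3, 0.7, n_probes)
    beta = base[:, None] + rng.normal(0, 0.02, (n_probes, n_m + n_f))
    beta[:n_spiked, n_m:] += effect  # females methylated higher at spikes
    bdf = pd.DataFrame(beta, index=[f"p{i}" for i in range(n_probes)],
                       columns=males + females)
    sheet = pd.DataFrame({"sample_id": males + females,
                          "group": "control",
                          "sex": ["M"] * n_m + ["F"] * n_f})
    return bdf, sheet


def test_sex_scan_identical_probes_all_q_one(rng):
    beta, sheet = _sex_cohort(rng, n_probes=6, n_spiked=0, effect=0.0)
    beta.loc[:, :] = 0.5
    res = sex_scan(beta, sheet)
    assert (res["q_value"] == 1.0).all()


def test_sex_scan_spiked_probes_rank_first(rng):
    beta, sheet = _sex_cohort(rng)
    res = sex_scan(beta, sheet).set_index("probe_id")
    spiked = [f"p{i}" for i in range(5)]
    others = [f"p{i}" for i in range(5, 9)]
    assert res.loc[spiked, "q_value"].max() < res.loc[others, "q_value"].min()
    assert (res.loc[spiked, "delta_beta"] > 0).all()


def test_sex_scan_single_sex_rejected(rng):
    beta, sheet = _sex_cohort(rng)
    with pytest.raises(ValueError):
        sex_scan(beta, sheet.assign(sex="M"))


def test_dosage_trend_monotone_beta_gives_rho_one():
    sheet = pd.DataFrame({
        "sample_id": [f"s{i}" for i in range(9)],
        "group": ["a"] * 3 + ["b"] * 3 + ["c"] * 3,
        "kdm5c_copies": [0] * 3 + [1] * 3 + [2] * 3,
        "kdm5d_copies": 0,
    })
    beta = pd.Series(np.arange(9, dtype=float) / 10.0,
                     index=sheet["sample_id"])
    # within-dose variation exists but order follows dose
    res = dosage_trend(beta, sheet, n_perm=200)
    assert res.spearman_rho > 0.8
    assert res.jt_p < 0.02
    assert list(res.group_means.index) == ["a", "b", "c"]


def test_dosage_trend_constant_dose_rejected():
    sheet = pd.DataFrame({
        "sample_id": ["s1", "s2", "s3"],
        "group": ["a", "a", "b"],
        "kdm5c_copies": 1, "kdm5d_copies": 0,
    })
    with pytest.raises(ValueError):
        dosage_trend(pd.Series([0.1, 0.2, 0.3], index=sheet["sample_id"]),
                     sheet)


def test_jt_null_is_uniformish(rng):
    groups = [rng.random(5) for _ in range(3)]
    _, p = jonckheere_terpstra(groups, n_perm=300, seed=1)
    assert p > 0.05


def test_dosage_cohort_ordering_single_seed():
    beta, sheet = simulate_dosage_cohort(DosageConfig(seed=0))
    res = dosage_trend(beta.mean(axis=0).rename("beta"), sheet, n_perm=300)
    assert res.spearman_rho >= 0.7
    # group means ordered by dose must increase (ties allowed at equal dose)
    sh = sheet.set_index("sample_id")
    dose = sh.groupby("group")["effective_dose"].first()
    m = res.group_means
    d = dose[m.index].to_numpy()
    vals = m.to_numpy()
    for i in range(len(vals) - 1):
        assert vals[i] < vals[i + 1] or d[i] == d[i + 1]


def test_outlier_screen_rules(rng):
    probes = ["p1", "p2"]
    ref = pd.DataFrame(rng.uniform(0.5, 0.9, (2, 100)), index=probes)
    med = ref.median(axis=1)
    query = pd.DataFrame({"q_med": med, "q_low": ref.min(axis=1) - 0.05}).T.T
    query.columns = ["q_med", "q_low"]
    res = population_outlier_screen(query, ref)
    assert not res.flags.loc["q_med"].any()
    assert res.flags.loc["q_low"].all()
    mad_res = population_outlier_screen(query, ref, rule="mad")
    assert mad_res.rule == "mad"


def test_outlier_screen_small_reference_warns(rng):
    ref = pd.DataFrame(rng.random((2, 5)), index=["p1", "p2"])
    q = pd.DataFrame({"s": [0.5, 0.5]}, index=["p1", "p2"])
    with pytest.warns(UserWarning, match="reference"):
        population_outlier_screen(q, ref)


def test_population_screen_separates_cases(rng):
    """946 reference draws vs 10 shifted cases: all cases flagged, no
    reference sample self-flags under leave-one-out."""
    n_ref = 946
    probes = ["g1", "g2", "g3"]
    center = np.array([0.85, 0.7, 0.5])
    ref = pd.DataFrame(
        np.clip(center[:, None] + rng.normal(0, 0.05, (3, n_ref)), 0, 1),
        index=probes, columns=[f"r{i}" for i in range(n_ref)],
    )
    cases = pd.DataFrame(
        np.clip(center[:, None] - 0.45 + rng.normal(0, 0.05, (3, 10)), 0, 1),
        index=probes, columns=[f"k{i}" for i in range(10)],
    )
    res = population_outlier_screen(cases, ref)
    assert res.flags.all(axis=1).all()     # every case, every gene
    # leave-one-out self-screen: a reference sample shows case-comparable
    # loss only if it sits strictly below all others at every gene
    vals = ref.to_numpy()
    strict_minima = [
        set(np.flatnonzero(vals[i] < np.partition(vals[i], 1)[1]))
        for i in range(len(probes))
    ]
    self_flagged = set.intersection(*strict_minima)
    assert not self_flagged
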