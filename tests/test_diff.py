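"""Mann-Whitney scan: exactness, symmetries, robustness enumeration."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from methperm import mwu_exact_p, probe_scan, subset_robustness


def enumeration_p(a, b):
    """Independent oracle: full enumeration of label assignments.

    Two-sided p = fraction of assignments with |U - n1 n2 / 2| at least
    as extreme as observed (valid for tie-free data, where the U null is
    symmetric).
    """
    pooled = np.concatenate([a, b])
    n1 = len(a)
    r = stats.rankdata(pooled)
    mid = n1 * len(b) / 2.0
    u_obs = r[:n1].sum() - n1 * (n1 + 1) / 2.0
    us = np.array(
        [
            r[list(c)].sum() - n1 * (n1 + 1) / 2.0
            for c in itertools.combinations(range(len(pooled)), n1)
        ]
    )
    return float(np.mean(np.abs(us - mid) >= abs(u_obs - mid) - 1e-12))


def test_complete_separation_floor_10v19():
    a = 0.3 + 0.01 * np.arange(10)
    b = 0.8 + 0.01 * np.arange(19)
    p = mwu_exact_p(a, b)
    assert p == pytest.approx(2 / math.comb(29, 10), rel=1e-12)
    from methperm.io import format_p

    assert format_p(p) == "9.98E-08"


def test_all_tied_gives_one():
    assert mwu_exact_p([0.5] * 4, [0.5] * 6) == 1.0


def test_complete_separation_2v2_is_one_third():
    assert mwu_exact_p([1.0, 2.0], [3.0, 4.0]) == pytest.approx(1 / 3)


def test_symmetry_and_errors(rng):
    a, b = rng.random(6), rng.random(9)
    assert mwu_exact_p(a, b) == pytest.approx(mwu_exact_p(b, a))
    with pytest.raises(ValueError):
        mwu_exact_p([], [1.0])
    with pytest.raises(ValueError):
        mwu_exact_p([np.nan], [1.0])


def test_exact_p_matches_enumeration_all_small_splits(rng):
    """Exhaustive check against the enumeration oracle for n1+n2 <= 12."""
    for n1 in range(1, 12):
        for n2 in range(1, 13 - n1):
            x = rng.random(n1 + n2)
            p = mwu_exact_p(x[:n1], x[n1:])
            assert p == pytest.approx(enumeration_p(x[:n1], x[n1:]), rel=1e-9), \
                (n1, n2)


def _sheet(cases, controls, vus=()):
    rows = [(s, "case", f"F{i + 1}") for i, s in enumerate(cases)]
    rows += [(s, "control", "") for s in controls]
    rows += [(s, "vus", "") for s in vus]
    df = pd.DataFrame(rows, columns=["sample_id", "group", "family_id"])
    df["relative_pool"] = False
    return df


def test_probe_scan_constant_probe():
    cases = [f"k{i}" for i in range(3)]
    controls = [f"c{i}" for i in range(4)]
    beta = pd.DataFrame(0.5, index=["p1"], columns=cases + controls)
    res = probe_scan(beta, _sheet(cases, controls))
    assert res.loc[0, "p_value"] == 1.0
    assert res.loc[0, "delta_beta"] == 0.0


def test_probe_scan_printed_group_means_give_delta():
    # group means 0.41 (cases) and 0.89 (controls) -> delta -0.48
    cases = [f"k{i}" for i in range(10)]
    controls = [f"c{i}" for i in range(19)]
    cv = 0.41 + 0.001 * (np.arange(10) - 4.5)
    kv = 0.89 + 0.001 * (np.arange(19) - 9.0)
    beta = pd.DataFrame(np.r_[cv, kv][None, :], index=["cg02630888"],
                        columns=cases + controls)
    res = probe_scan(beta, _sheet(cases, controls))
    assert res.loc[0, "delta_beta"] == pytest.approx(-0.48)
    from methperm.io import format_p

    assert format_p(res.loc[0, "p_value"]) == "9.98E-08"


def test_probe_scan_matches_scalar_oracle(small_cohort):
    beta = small_cohort.beta.iloc[:40]
    res = probe_scan(beta, small_cohort.sample_sheet).set_index("probe_id")
    sheet = small_cohort.sample_sheet.set_index("sample_id")
    cases = [s for s in beta.columns if sheet.loc[s, "group"] == "case"]
    controls = [s for s in beta.columns if sheet.loc[s, "group"] == "control"]
    for pid in beta.index[::7]:
        expected = stats.mannwhitneyu(
            beta.loc[pid, cases], beta.loc[pid, controls],
            alternative="two-sided", method="exact",
        ).pvalue
        assert res.loc[pid, "p_value"] == pytest.approx(expected, rel=1e-9)


def test_probe_scan_order_invariance(small_cohort):
    beta = small_cohort.beta.iloc[:30]
    sheet = small_cohort.sample_sheet
    base = probe_scan(beta, sheet).set_index("probe_id").sort_index()
    shuffled_cols = beta.sample(frac=1, axis=1, random_state=0)
    shuffled_rows = beta.sample(frac=1, axis=0, random_state=1)
    for other in (shuffled_cols, shuffled_rows):
        res = probe_scan(other, sheet).set_index("probe_id").sort_index()
        pd.testing.assert_frame_equal(base, res)


def test_probe_scan_relabel_antisymmetry(small_cohort):
    beta = small_cohort.beta.iloc[:30]
    sheet = small_cohort.sample_sheet
    fwd = probe_scan(beta, sheet).set_index("probe_id")
    swapped = sheet.copy()
    swapped["group"] = swapped["group"].map(
        {"case": "control", "control": "case"}).fillna(swapped["group"])
    rev = probe_scan(beta, swapped).set_index("probe_id")
    assert np.allclose(fwd["p_value"], rev["p_value"])
    assert np.allclose(fwd["delta_beta"], -rev["delta_beta"])
    assert np.allclose(fwd["delta_z"], -rev["delta_z"])


def test_probe_scan_vus_reported_not_tested(small_cohort):
    res = probe_scan(small_cohort.beta.iloc[:10], small_cohort.sample_sheet)
    assert "mean_vus" in res.columns
    # vus samples never affect the p-value: drop them, p unchanged
    sheet_no_vus = small_cohort.sample_sheet.query("group != 'vus'")
    res2 = probe_scan(small_cohort.beta.iloc[:10], sheet_no_vus)
    assert np.allclose(res["p_value"], res2["p_value"])


def test_probe_scan_flags_untestable():
    cases = ["k1", "k2", "k3"]
    controls = ["c1", "c2", "c3"]
    beta = pd.DataFrame(
        [[0.1, np.nan, np.nan, 0.5, 0.6, 0.7]],
        index=["p1"], columns=cases + controls,
    )
    res = probe_scan(beta, _sheet(cases, controls))
    assert not res.loc[0, "testable"]
    assert np.isnan(res.loc[0, "p_value"])


def test_delta_z_sign_and_scale(small_cohort):
    res = probe_scan(small_cohort.beta, small_cohort.sample_sheet)
    spiked = small_cohort.truth.loc[small_cohort.truth["is_spiked"], "probe_id"]
    dz = res.set_index("probe_id").loc[spiked, "delta_z"]
    # methylation loss in cases -> positive delta_z around the 1.8-2 scale
    assert (dz > 1.0).all() and (dz < 2.5).all()


# -- subset robustness -----------------------------------------------------

def test_single_combination():
    cases = ["k1", "k2"]
    controls = ["c1", "c2", "c3", "r1"]
    sheet = _sheet(cases, controls)
    sheet.loc[sheet["sample_id"] == "r1", "relative_pool"] = True
    rng = np.random.default_rng(0)
    beta = pd.DataFrame(rng.random((5, 6)), index=[f"p{i}" for i in range(5)],
                        columns=cases + controls)
    res = subset_robustness(beta, sheet, alpha_levels=(0.05,))
    assert len(res.combinations) == 1


def test_seventy_two_combinations(small_cohort):
    res = subset_robustness(small_cohort.beta.iloc[:5],
                            small_cohort.sample_sheet, alpha_levels=(0.05,))
    assert len(res.combinations) == 72


def test_strong_spikes_survive_every_subset(small_cohort):
    """The intersection over subsets recovers the full-cohort top set."""
    beta = small_cohort.beta
    spiked = set(small_cohort.truth.loc[small_cohort.truth["is_spiked"],
                                        "probe_id"])
    # 5 vs 17 floor: 2 / C(22,5); use a level just above it
    alpha = 4 / math.comb(22, 5)
    res = subset_robustness(beta, small_cohort.sample_sheet,
                            alpha_levels=(alpha,))
    assert res.intersection[alpha] == spiked


def test_robustness_requires_family_ids(small_cohort):
    sheet = small_cohort.sample_sheet.copy()
    sheet.loc[sheet["group"] == "case", "family_id"] = ""
    with pytest.raises(ValueError):
        subset_robustness(small_cohort.beta.iloc[:3], sheet)
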