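"""Per-probe two-group nonparametric scan and subset-robustness analysis.

Each retained probe is compared between mutation cases and controls with
a two-sided Mann-Whitney U test — exact by enumeration for the small
group sizes of this design, where the smallest attainable p under
complete separation of 10 vs 19 is 2 / C(29,10) = 9.985e-8.  Effect
sizes are reported as delta beta (case mean - control mean; negative =
methylation loss) and delta Z, a standardized separation score.
Variant-of-unknown-significance samples are carried along descriptively
but never enter the test.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._mwu import mwu_exact_p, prepare_rank_scan, scan_p_for_labels

__all__ = ["mwu_exact_p", "probe_scan", "subset_robustness", "RobustnessResult"]


def _group_columns(sheet: pd.DataFrame, beta_cols) -> dict[str, list[str]]:
    sheet = sheet.set_index("sample_id") if "sample_id" in sheet else sheet
    out: dict[str, list[str]] = {"case": [], "control": [], "vus": []}
    for s in beta_cols:
        if s in sheet.index:
            g = sheet.loc[s, "group"]
            if g in out:
                out[g].append(s)
    return out


def probe_scan(
    beta: pd.DataFrame,
    sheet: pd.DataFrame,
    exact_threshold: int = 25,
    case_label: str = "case",
    control_label: str = "control",
) -> pd.DataFrame:
    """Mann-Whitney scan of every probe: case vs control.

    Returns one row per probe with p_value, group means (including the
    descriptive vus mean when vus samples exist), delta_beta and delta_z.
    Missing values are handled pairwise-complete per probe; a probe with
    fewer than 2 non-missing values in either group is flagged
    ``testable=False`` (p and delta_z NaN) rather than dropped.
    delta_z: betas are z-standardized across cases+controls per probe and
    delta_z = mean z(controls) - mean z(cases), positive for loss.
    """
    relabeled = sheet.copy()
    relabeled["group"] = relabeled["group"].map(
        {case_label: "case", control_label: "control"}
    ).fillna(relabeled["group"])
    groups = _group_columns(relabeled, beta.columns)
    cases, controls, vus = groups["case"], groups["control"], groups["vus"]
    if len(cases) < 2 or len(controls) < 2:
        raise ValueError("need >= 2 case and >= 2 control samples")

    X = beta[cases + controls].to_numpy(dtype=float)
    n1 = len(cases)
    K = X.shape[0]
    p = np.full(K, np.nan)
    testable = np.ones(K, dtype=bool)

    complete = ~np.isnan(X).any(axis=1)
    if complete.any():
        rs = prepare_rank_scan(X[complete], n1, exact_threshold)
        p[complete] = scan_p_for_labels(rs, np.arange(n1))
    for i in np.flatnonzero(~complete):
        a = X[i, :n1]
        b = X[i, n1:]
        a = a[~np.isnan(a)]
        b = b[~np.isnan(b)]
        if a.size < 2 or b.size < 2:
            testable[i] = False
            continue
        p[i] = mwu_exact_p(a, b, exact_threshold)
    p[~testable] = np.nan

    mean_case = np.nanmean(X[:, :n1], axis=1)
    mean_control = np.nanmean(X[:, n1:], axis=1)
    # standardized separation across cases+controls
    mu = np.nanmean(X, axis=1, keepdims=True)
    sd = np.nanstd(X, axis=1, ddof=1, keepdims=True)
    import warnings

    with np.errstate(invalid="ignore", divide="ignore"), \
            warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        Z = (X - mu) / sd
        delta_z = np.nanmean(Z[:, n1:], axis=1) - np.nanmean(Z[:, :n1], axis=1)
    delta_z[~testable] = np.nan
    delta_z[(sd == 0).ravel()] = 0.0
    out = pd.DataFrame(
        {
            "probe_id": beta.index,
            "p_value": p,
            "mean_case": mean_case,
            "mean_control": mean_control,
            "delta_beta": mean_case - mean_control,
            "delta_z": delta_z,
            "testable": testable,
        }
    )
    if vus:
        out.insert(4, "mean_vus", np.nanmean(beta[vus].to_numpy(dtype=float), axis=1))
    return out


@dataclass
class RobustnessResult:
    """Subset-robustness enumeration output."""

    combinations: list[dict]            # per-combination case/control ids
    significant: dict[float, list[set]]  # alpha -> per-combination probe sets
    intersection: dict[float, set]       # alpha -> probes significant in all


def subset_robustness(
    beta: pd.DataFrame,
    sheet: pd.DataFrame,
    alpha_levels: tuple[float, ...] = (1e-6,),
    exact_threshold: int = 25,
) -> RobustnessResult:
    """Enumerate unrelated-subset reanalyses and intersect their hits.

    The design: one case per family (Cartesian product over families)
    crossed with one control drawn from the unaffected-relative pool,
    alongside the fixed unrelated controls.  With family sizes
    (3,2,2,2,1) and 3 interchangeable relatives this yields the study's
    72 combinations of 5 cases vs 17 controls.  A probe is robust at a
    level when its p-value falls below that level in every combination.
    """
    s = sheet.set_index("sample_id") if "sample_id" in sheet else sheet
    s = s.loc[[c for c in beta.columns if c in s.index]]
    cases = s[s["group"] == "case"]
    if (cases["family_id"].astype(str) == "").any():
        raise ValueError("every case needs a family_id for robustness analysis")
    fam_groups = [list(g.index) for _, g in cases.groupby("family_id", sort=True)]
    if not fam_groups or any(len(g) == 0 for g in fam_groups):
        raise ValueError("each family must contain at least one case")
    controls = s[s["group"] == "control"]
    relatives = list(controls.index[controls["relative_pool"].astype(bool)])
    fixed = list(controls.index[~controls["relative_pool"].astype(bool)])
    if not relatives:
        raise ValueError("no relative-pool controls to enumerate")

    combos = []
    sig: dict[float, list[set]] = {a: [] for a in alpha_levels}
    for case_pick in itertools.product(*fam_groups):
        for rel in relatives:
            ctrl = fixed + [rel]
            sub_sheet = pd.DataFrame(
                {"sample_id": list(case_pick) + ctrl,
                 "group": ["case"] * len(case_pick) + ["control"] * len(ctrl)}
            )
            res = probe_scan(beta[list(case_pick) + ctrl], sub_sheet,
                             exact_threshold)
            combos.append({"cases": list(case_pick), "controls": ctrl})
            pv = res.set_index("probe_id")["p_value"]
            for a in alpha_levels:
                sig[a].append(set(pv.index[pv < a]))
    inter = {
        a: set.intersection(*sets) if sets else set()
        for a, sets in sig.items()
    }
    return RobustnessResult(combos, sig, inter)
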