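"""Loss/gain directionality of differential methylation by CpG-island context.

Among probes passing a significance threshold, loss (delta beta < 0) and
gain (delta beta > 0) are tallied within island and non-island strata;
association between context and direction is tested with Fisher's exact
test, and a single-stratum loss excess against the symmetric null with
an exact binomial sign test.  A genome-wide mean-methylation comparison
per stratum quantifies the diluted global shift.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._mwu import mwu_exact_p


@dataclass
class DirectionTally:
    """2x2 loss/gain counts by island context; zero deltas set aside."""

    counts: pd.DataFrame   # rows island/non_island, columns loss/gain
    n_zero: int

    @property
    def total(self) -> int:
        return int(self.counts.to_numpy().sum())


def direction_tally(
    diff: pd.DataFrame,
    annotation: pd.DataFrame,
    p_threshold: float,
) -> DirectionTally:
    """Tally loss vs gain among probes with p below threshold."""
    ann = annotation.set_index("probe_id") if "probe_id" in annotation else annotation
    d = diff.set_index("probe_id")
    island = ann["cpg_island"].astype(bool).reindex(d.index)
    if island.isna().any():
        raise ValueError("annotation does not cover all scanned probes")
    sig = d["p_value"] < p_threshold
    delta = d["delta_beta"]
    tab = pd.DataFrame(0, index=["island", "non_island"], columns=["loss", "gain"])
    for isl, name in ((True, "island"), (False, "non_island")):
        m = sig & (island == isl)
        tab.loc[name, "loss"] = int((delta[m] < 0).sum())
        tab.loc[name, "gain"] = int((delta[m] > 0).sum())
    n_zero = int((sig & (delta == 0)).sum())
    return DirectionTally(tab, n_zero)


def asymmetry_test(counts) -> float:
    """Fisher exact p for a 2x2 context-by-direction table."""
    tab = np.asarray(counts, dtype=int)
    if tab.shape != (2, 2):
        raise ValueError("expected a 2x2 table")
    if (tab < 0).any():
        raise ValueError("counts must be nonnegative")
    if tab.sum() == 0:
        raise ValueError("all-zero table: association undefined")
    return float(stats.fisher_exact(tab)[1])


def sign_test(n_loss: int, n_gain: int) -> float:
    """Exact two-sided binomial sign test of loss vs gain against 0.5.

    For 53 losses and 0 gains this is 2 * 0.5**53 ~ 2.22e-16.
    """
    n = n_loss + n_gain
    if n == 0:
        raise ValueError("no nonzero deltas to test")
    return float(stats.binomtest(n_loss, n, 0.5).pvalue)


@dataclass
class StratumComparison:
    mean_case: float
    mean_control: float
    difference: float
    p_value: float
    n_probes: int


def mean_methylation_compare(
    beta: pd.DataFrame,
    annotation: pd.DataFrame,
    sheet: pd.DataFrame,
) -> dict[str, StratumComparison]:
    """Case-vs-control comparison of per-sample mean beta per island stratum.

    Each sample is reduced to its mean beta over the stratum's probes;
    groups are compared with a Mann-Whitney test.  An empty stratum is
    skipped with a warning entry (NaN comparison).
    """
    ann = annotation.set_index("probe_id") if "probe_id" in annotation else annotation
    island = ann["cpg_island"].astype(bool).reindex(beta.index)
    s = sheet.set_index("sample_id") if "sample_id" in sheet else sheet
    cases = [c for c in beta.columns if c in s.index and s.loc[c, "group"] == "case"]
    controls = [c for c in beta.columns
                if c in s.index and s.loc[c, "group"] == "control"]
    out: dict[str, StratumComparison] = {}
    for isl, name in ((True, "island"), (False, "non_island")):
        probes = beta.index[island == isl]
        if len(probes) == 0:
            import warnings

            warnings.warn(f"empty stratum {name!r}; skipped", stacklevel=2)
            continue
        sub = beta.loc[probes]
        mc = sub[cases].mean(axis=0, skipna=True)
        mk = sub[controls].mean(axis=0, skipna=True)
        p = mwu_exact_p(mc.to_numpy(), mk.to_numpy())
        out[name] = StratumComparison(
            mean_case=float(mc.mean()),
            mean_control=float(mk.mean()),
            difference=float(mc.mean() - mk.mean()),
            p_value=p,
            n_probes=len(probes),
        )
    return out


def volcano_table(diff: pd.DataFrame, annotation: pd.DataFrame) -> pd.DataFrame:
    """Volcano-plot export: delta beta, -log10 p and island flag per probe."""
    ann = annotation.set_index("probe_id") if "probe_id" in annotation else annotation
    d = diff.set_index("probe_id")
    with np.errstate(divide="ignore"):
        neglog = -np.log10(d["p_value"])
    return pd.DataFrame(
        {
            "delta_beta": d["delta_beta"],
            "neg_log10_p": neglog,
            "cpg_island": ann["cpg_island"].astype(bool).reindex(d.index),
        }
    ).reset_index()
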