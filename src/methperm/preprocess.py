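"""Beta computation, sample QC and probe filtering for 27K-style arrays.

The beta value is Max(M,0) / [Max(M,0) + Max(U,0) + 100]: negative
background-subtracted intensities are clamped and the +100 offset
regularises low-intensity probes, so a value of exactly 1 is unreachable
from intensities.  Sample QC follows the two-gate rule (bisulfite
conversion control intensity and fraction of probes detected above
background); probe filtering removes the union of detection failures,
cross-reactive probes and probes with SNPs in the queried CpG.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .simulate import IntensityData


@dataclass(frozen=True)
class QcPolicy:
    """Sample QC gates.

    A sample passes iff its bisulfite-conversion control intensity is
    strictly above ``min_bs_control`` and at least ``min_detected_fraction``
    of its probes have detection p < ``detection_alpha``.
    """

    min_bs_control: float
    min_detected_fraction: float
    detection_alpha: float

    def __post_init__(self):
        if min(self.min_bs_control, self.min_detected_fraction,
               self.detection_alpha) <= 0:
            raise ValueError("all QC thresholds must be positive")


#: discovery-cohort gate: control intensity > 4000 and 99% of probes
#: detected at p < 0.01
STRICT_QC = QcPolicy(4000.0, 0.99, 0.01)
#: relaxed gate for external datasets: >= 95% of probes detected at p < 0.05
RELAXED_QC = QcPolicy(4000.0, 0.95, 0.05)


def compute_beta(M, U):
    """Beta value Max(M,0) / [Max(M,0) + Max(U,0) + 100].

    Accepts scalars or arrays; negative (background-subtracted) inputs are
    clamped to zero.  The result is always strictly below 1.
    """
    M = np.asarray(M, dtype=float)
    U = np.asarray(U, dtype=float)
    if not (np.isfinite(M).all() and np.isfinite(U).all()):
        raise ValueError("non-finite intensity values")
    m = np.maximum(M, 0.0)
    u = np.maximum(U, 0.0)
    beta = m / (m + u + 100.0)
    if beta.ndim == 0:
        return float(beta)
    return beta


def pyro_fraction(C_signal, T_signal):
    """Pyrosequencing methylation fraction C / (C + T)."""
    C = np.asarray(C_signal, dtype=float)
    T = np.asarray(T_signal, dtype=float)
    if (C < 0).any() or (T < 0).any():
        raise ValueError("signals must be nonnegative")
    tot = C + T
    if (tot == 0).any():
        raise ValueError("C + T is zero: methylation fraction undefined")
    frac = C / tot
    if frac.ndim == 0:
        return float(frac)
    return frac


def beta_from_intensities(data: IntensityData) -> pd.DataFrame:
    """Apply the beta formula to a whole intensity dataset."""
    beta = compute_beta(data.methylated.to_numpy(), data.unmethylated.to_numpy())
    return pd.DataFrame(beta, index=data.methylated.index,
                        columns=data.methylated.columns)


def sample_qc(data: IntensityData, policy: QcPolicy = STRICT_QC) -> pd.DataFrame:
    """Per-sample pass/fail table with failure reasons."""
    if data.detection_p.empty:
        raise ValueError("empty intensity matrix")
    det_frac = (data.detection_p < policy.detection_alpha).mean(axis=0)
    bs = data.bisulfite_control.reindex(data.detection_p.columns)
    bs_ok = bs > policy.min_bs_control
    det_ok = det_frac >= policy.min_detected_fraction
    reasons = []
    for s in data.detection_p.columns:
        r = []
        if not bs_ok[s]:
            r.append(f"bisulfite_control<={policy.min_bs_control:g}")
        if not det_ok[s]:
            r.append(f"detected_fraction<{policy.min_detected_fraction:g}")
        reasons.append(";".join(r))
    return pd.DataFrame(
        {
            "bisulfite_control": bs,
            "detected_fraction": det_frac,
            "passed": bs_ok & det_ok,
            "reasons": reasons,
        }
    )


@dataclass
class FilterReport:
    """Probe-exclusion accounting; reasons may overlap, the union rules."""

    n_input: int
    n_detection_fail: int
    n_cross_reactive: int
    n_snp_overlap: int
    n_removed: int
    n_retained: int


def filter_probes(
    beta: pd.DataFrame,
    annotation: pd.DataFrame,
    detection_p: pd.DataFrame | None = None,
    detection_alpha: float = 0.01,
    detection_mode: str = "any",
) -> tuple[pd.DataFrame, FilterReport]:
    """Remove cross-reactive, SNP-overlapping and detection-failing probes.

    ``detection_mode='any'`` (default) drops a probe whose detection p is
    >= ``detection_alpha`` in any sample; ``'mask'`` instead sets only the
    failing observations to NaN and drops probes that fail everywhere.
    The three exclusion reasons are combined as a set union; a probe
    flagged twice is removed once.  Idempotent.
    """
    ann = annotation.set_index("probe_id") if "probe_id" in annotation else annotation
    missing = beta.index.difference(ann.index)
    if len(missing):
        raise ValueError(
            f"{len(missing)} probes missing from annotation, e.g. {missing[0]!r}"
        )
    ann = ann.reindex(beta.index)
    cross = ann["cross_reactive"].astype(bool).to_numpy()
    snp = ann["snp_overlap"].astype(bool).to_numpy()

    beta_out = beta
    if detection_p is not None:
        det = detection_p.reindex(index=beta.index, columns=beta.columns)
        fails = (det >= detection_alpha).to_numpy()
        if detection_mode == "any":
            det_fail = fails.any(axis=1)
        elif detection_mode == "mask":
            masked = beta.to_numpy(dtype=float).copy()
            masked[fails] = np.nan
            beta_out = pd.DataFrame(masked, index=beta.index, columns=beta.columns)
            det_fail = fails.all(axis=1)
        else:
            raise ValueError(f"unknown detection_mode {detection_mode!r}")
    else:
        det_fail = np.zeros(len(beta), dtype=bool)

    remove = cross | snp | det_fail
    report = FilterReport(
        n_input=len(beta),
        n_detection_fail=int(det_fail.sum()),
        n_cross_reactive=int(cross.sum()),
        n_snp_overlap=int(snp.sum()),
        n_removed=int(remove.sum()),
        n_retained=int((~remove).sum()),
    )
    return beta_out.loc[~remove], report


def platform_concordance(x, y) -> float:
    """Squared Pearson correlation between paired methylation measurements."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need >= 3 paired observations")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("non-finite values")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance: R^2 undefined")
    r = np.corrcoef(x, y)[0, 1]
    return float(r * r)
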