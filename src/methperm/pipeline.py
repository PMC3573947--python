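"""End-to-end orchestration: simulate/load -> QC -> scan -> FDP -> reports.

The pipeline is configured by a flat nested dict (typically parsed from
YAML or JSON).  All randomness flows from the single top-level ``seed``,
which is recorded in the report.  A ``simulate`` block generates the
cohort in-process; alternatively an ``inputs`` block names a beta
matrix, sample sheet and annotation on disk.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import asymmetry as asym
from . import cohorts as coh
from . import diff, fdp, io, preprocess, structure
from .simulate import Cohort, CohortConfig, DosageConfig, simulate_cohort, \
    simulate_dosage_cohort

log = logging.getLogger("methperm")

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "simulate": {"n_probes": 4000, "n_spiked": 50, "spike_delta": -0.4},
    "qc": {"policy": "strict"},
    "fdp": {"B": 1000, "gammas": [0.0, 0.05, 0.1, 0.2],
            "alphas": [0.005, 0.05, 0.1]},
    "structure": {"pca_k": 10},
    "asymmetry": {},
    "dosage": {},
}


def _load_inputs(cfg: dict):
    inputs = cfg["inputs"]
    beta = io.read_beta_matrix(inputs["beta"])
    sheet = io.read_sample_sheet(inputs["sample_sheet"])
    ann = io.read_annotation(inputs["annotation"])
    return None, beta, sheet, ann


def _simulate_inputs(cfg: dict, seed: int):
    sim_kwargs = dict(cfg.get("simulate", {}))
    sim_kwargs.setdefault("seed", seed)
    cohort = simulate_cohort(CohortConfig(**sim_kwargs))
    return cohort, None, cohort.sample_sheet, cohort.annotation


def run_pipeline(config: dict | None = None, out_dir=None) -> dict:
    """Execute the configured stages and return a machine-readable report.

    When ``out_dir`` is given the intermediate tables (filtered beta
    matrix, scan table, FDP grid, dendrogram, volcano export) are written
    there alongside the JSON report.
    """
    cfg = dict(DEFAULT_CONFIG)
    if config:
        cfg.update(config)
    seed = int(cfg.get("seed", 0))
    report: dict = {"seed": seed, "stages": {}}

    cohort: Cohort | None
    if "inputs" in cfg:
        cohort, beta, sheet, ann = _load_inputs(cfg)
    else:
        cohort, beta, sheet, ann = _simulate_inputs(cfg, seed)

    tables: dict[str, pd.DataFrame] = {}

    if cohort is not None:
        policy = preprocess.STRICT_QC if cfg.get("qc", {}).get(
            "policy", "strict") == "strict" else preprocess.RELAXED_QC
        qc = preprocess.sample_qc(cohort.intensities, policy)
        keep = list(qc.index[qc["passed"]])
        log.info("sample QC: %d/%d passed", len(keep), len(qc))
        beta_full = preprocess.beta_from_intensities(cohort.intensities)
        beta, filt = preprocess.filter_probes(
            beta_full[keep], ann, cohort.intensities.detection_p[keep]
        )
        sheet = sheet[sheet["sample_id"].isin(keep)]
        report["stages"]["qc"] = {
            "n_samples_passed": len(keep),
            "filter": dataclasses.asdict(filt),
        }

    scan = diff.probe_scan(beta, sheet)
    tables["scan"] = scan
    report["stages"]["scan"] = {
        "n_probes": int(len(scan)),
        "n_testable": int(scan["testable"].sum()),
        "min_p": float(np.nanmin(scan["p_value"])),
        "min_p_formatted": io.format_p(float(np.nanmin(scan["p_value"]))),
    }

    fcfg = cfg.get("fdp", {})
    null = fdp.build_null(beta, sheet, B=int(fcfg.get("B", 1000)), seed=seed)
    res = fdp.call_significant(
        scan, null,
        gammas=tuple(fcfg.get("gammas", (0.0,))),
        alphas=tuple(fcfg.get("alphas", (0.05,))),
    )
    tables["fdp_grid"] = res.counts.reset_index()
    top_key = (min(g for g, _ in res.significant),
               min(a for _, a in res.significant))
    top_set = res.significant[top_key]
    report["stages"]["fdp"] = {
        "grid": {f"gamma={g},alpha={a}": n
                 for (g, a), n in ((k, len(v)) for k, v in res.significant.items())},
        "cutoffs": {f"gamma={g},alpha={a}": io.format_p(c)
                    for (g, a), c in res.cutoffs.items()},
        "top_set_size": len(top_set),
    }

    newick = None
    if len(top_set) >= 2:
        dend = structure.hclust_cosine_complete(beta.loc[sorted(top_set)].T)
        newick = dend.to_newick()
        report["stages"]["structure"] = {
            "two_group_sizes": dend.two_group_labels.value_counts().to_dict(),
        }
    pca = structure.pca_median_knn(
        beta, k=int(cfg.get("structure", {}).get("pca_k", 10)), n_components=2
    )
    report.setdefault("stages", {}).setdefault("structure", {})[
        "pc1_variance_ratio"] = float(pca.explained_variance_ratio[0])

    p_thr = res.cutoffs[top_key] if res.cutoffs[top_key] > 0 else 0.05
    tally = asym.direction_tally(scan, ann, p_thr)
    tables["volcano"] = asym.volcano_table(scan, ann)
    n_loss = int(tally.counts["loss"].sum())
    n_gain = int(tally.counts["gain"].sum())
    report["stages"]["asymmetry"] = {
        "counts": tally.counts.to_dict(),
        "sign_test_p": io.format_p(asym.sign_test(n_loss, n_gain))
        if (n_loss + n_gain) else None,
        "fisher_p": io.format_p(asym.asymmetry_test(tally.counts))
        if tally.counts.to_numpy().sum() else None,
    }

    dcfg = dict(cfg.get("dosage", {}))
    dcfg.setdefault("seed", seed)
    dbeta, dsheet = simulate_dosage_cohort(DosageConfig(**dcfg))
    trend = coh.dosage_trend(dbeta.iloc[0], dsheet, seed=seed)
    report["stages"]["dosage"] = {
        "spearman_rho": trend.spearman_rho,
        "jt_p": trend.jt_p,
        "group_means_by_dose": trend.group_means.to_dict(),
    }

    if out_dir is not None:
        out = Path(out_dir)
        io.write_results(tables, out)
        io.write_beta_matrix(beta, out / "beta_filtered.tsv")
        io.write_sample_sheet(sheet, out / "sample_sheet.csv")
        if newick:
            io.write_newick(newick, out / "dendrogram.nwk")
        io.write_report(report, out / "report.json")
    return report
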