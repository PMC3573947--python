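"""Synthetic methylation-cohort generators.

Emulates the study design the downstream pipeline expects: a small
family-structured case group against unrelated controls plus a relative
pool, beta values with probe-specific bimodal baselines (CpG-island probes
skewed low, non-island probes skewed high), a handful of spiked probes
with case-specific methylation loss concentrated at island probes, raw
intensity pairs from which the beta formula can be re-derived, and a
sex-chromosome-dosage cohort whose group means follow a saturating
dose-response in functional KDM5C/KDM5D copy number.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd


class ConfigError(ValueError):
    """Raised when a simulation config violates its invariants."""


@dataclass
class CohortConfig:
    """Parameters of the case/control cohort generator.

    Defaults mirror the study design: 10 cases over 5 families, 19
    controls of which 3 are unaffected relatives, 2 variant-of-unknown-
    significance carriers, ~24,000 retained probes with ~45% on CpG
    islands, and 50 spiked probes losing 0.4 methylation in cases.
    """

    n_probes: int = 24000
    n_cases: int = 10
    n_controls: int = 19
    n_vus: int = 2
    family_sizes: tuple[int, ...] = (3, 2, 2, 2, 1)
    n_relative_controls: int = 3
    frac_island: float = 0.45
    n_spiked: int = 50
    spike_delta: float = -0.4
    baseline_dispersion: float = 0.3
    sample_effect_sd: float = 0.15
    n_latent_factors: int = 3
    factor_sd: float = 0.15
    family_effect_sd: float = 0.0
    intensity_scale: float = 5000.0
    detection_fail_rate: float = 0.001
    seed: int = 0

    def validate(self) -> None:
        if sum(self.family_sizes) != self.n_cases:
            raise ConfigError(
                f"family_sizes sum {sum(self.family_sizes)} != n_cases {self.n_cases}"
            )
        if self.n_spiked > self.n_probes:
            raise ConfigError("n_spiked exceeds n_probes")
        if self.spike_delta > 0:
            raise ConfigError("spike_delta must be <= 0: this generator models loss only")
        if not (0.0 <= self.frac_island <= 1.0):
            raise ConfigError("frac_island must be in [0, 1]")
        if self.n_relative_controls > self.n_controls:
            raise ConfigError("n_relative_controls exceeds n_controls")


@dataclass
class IntensityData:
    """Raw methylated/unmethylated intensities with detection p-values."""

    methylated: pd.DataFrame
    unmethylated: pd.DataFrame
    detection_p: pd.DataFrame
    bisulfite_control: pd.Series  # per-sample green-channel control intensity


@dataclass
class Cohort:
    """One simulated cohort: intensities, true betas, labels and truth."""

    intensities: IntensityData
    beta: pd.DataFrame
    sample_sheet: pd.DataFrame
    annotation: pd.DataFrame
    truth: pd.DataFrame  # probe_id, is_spiked, true_delta


def _logit(p: np.ndarray) -> np.ndarray:
    return np.log(p / (1.0 - p))


def _expit(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def _mean_corrected_logit(target: np.ndarray, total_sd: float) -> np.ndarray:
    """Logit location a such that E[expit(a + N(0, total_sd^2))] == target.

    The naive expit(logit(m) + noise) has mean != m wherever the response
    curves; inverting the Gauss-Hermite expectation keeps the generator's
    expected beta exactly at the requested baseline (plus spike).
    """
    if total_sd <= 0:
        return _logit(target)
    nodes, weights = np.polynomial.hermite_e.hermegauss(41)
    a_grid = np.linspace(-14.0, 14.0, 4001)
    mean_grid = _expit(a_grid[:, None] + total_sd * nodes[None, :]) @ (
        weights / weights.sum()
    )
    return np.interp(target, mean_grid, a_grid)


def _make_sample_sheet(cfg: CohortConfig) -> pd.DataFrame:
    rows = []
    fam = 0
    for size in cfg.family_sizes:
        fam += 1
        for _ in range(size):
            rows.append(("case", f"F{fam}"))
    # relative controls are drawn from the first families
    for i in range(cfg.n_controls):
        if i < cfg.n_relative_controls:
            rows.append(("control", f"F{(i % len(cfg.family_sizes)) + 1}"))
        else:
            rows.append(("control", ""))
    for _ in range(cfg.n_vus):
        rows.append(("vus", ""))
    sheet = pd.DataFrame(rows, columns=["group", "family_id"])
    sheet["sample_id"] = [
        f"{g[:1].upper()}{i + 1:02d}" for i, g in enumerate(sheet["group"])
    ]
    sheet["relative_pool"] = (sheet["group"] == "control") & (sheet["family_id"] != "")
    sheet["sex"] = "M"
    sheet["karyotype"] = "46,XY"
    sheet["kdm5c_copies"] = np.where(sheet["group"] == "case", 0, 1)
    sheet["kdm5d_copies"] = 1
    return sheet[
        ["sample_id", "group", "family_id", "relative_pool", "sex",
         "karyotype", "kdm5c_copies", "kdm5d_copies"]
    ]


def simulate_cohort(config: CohortConfig) -> Cohort:
    """Generate a full intensity-level cohort with ground truth.

    Per-probe baseline betas are bimodal: island probes Beta(2, 5)
    (low/intermediate), non-island probes Beta(8, 2) (high). Observed
    betas are logit-normal around the (possibly spiked) target with scale
    ``baseline_dispersion``. Intensities satisfy
    beta = M / (M + U + 100) up to the total-signal draw:
    M = beta * S, U = (1 - beta) * S with S log-normal around
    ``intensity_scale``. Detection p-values are ~0 except for a
    ``detection_fail_rate`` fraction drawn uniform on [0, 1].
    Output is a pure function of the config, including its seed.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    K = config.n_probes
    sheet = _make_sample_sheet(config)
    n_samples = len(sheet)

    probe_ids = pd.Index([f"cg{i:08d}" for i in range(K)], name="probe_id")
    island = rng.random(K) < config.frac_island
    baseline = np.where(
        island, rng.beta(2.0, 5.0, size=K), rng.beta(8.0, 2.0, size=K)
    )
    baseline = np.clip(baseline, 0.02, 0.98)

    # spikes: island probes whose baseline survives the shift
    eligible = np.flatnonzero(island & (baseline + config.spike_delta >= 0.02))
    if config.n_spiked > 0:
        if eligible.size < config.n_spiked:
            raise ConfigError(
                "not enough island probes with baseline high enough for the spike"
            )
        spiked = rng.choice(eligible, size=config.n_spiked, replace=False)
    else:
        spiked = np.array([], dtype=int)
    is_spiked = np.zeros(K, dtype=bool)
    is_spiked[spiked] = True

    is_case = (sheet["group"] == "case").to_numpy()
    target = np.tile(baseline[:, None], (1, n_samples))
    target[np.ix_(is_spiked, is_case)] += config.spike_delta
    target = np.clip(target, 1e-4, 1 - 1e-4)

    # logit-scale noise: iid dispersion + sample-level structure emulating
    # unmodelled heterogeneity (global offsets and latent factors) that
    # dominates genome-wide ordination without breaking per-probe
    # exchangeability under the null
    noise = rng.normal(0.0, config.baseline_dispersion, size=(K, n_samples))
    if config.sample_effect_sd > 0:
        noise += rng.normal(0.0, config.sample_effect_sd, size=n_samples)[None, :]
    if config.n_latent_factors > 0 and config.factor_sd > 0:
        loadings = rng.normal(0.0, config.factor_sd,
                              size=(K, config.n_latent_factors))
        scores = rng.normal(0.0, 1.0, size=(config.n_latent_factors, n_samples))
        noise += loadings @ scores
    if config.family_effect_sd > 0:
        fams = sheet["family_id"].to_numpy()
        for f in np.unique(fams[fams != ""]):
            noise[:, fams == f] += rng.normal(0.0, config.family_effect_sd)
    total_sd = math.sqrt(
        config.baseline_dispersion**2
        + config.sample_effect_sd**2
        + config.n_latent_factors * config.factor_sd**2
    )
    beta = _expit(_mean_corrected_logit(target, total_sd) + noise)

    total = rng.lognormal(
        np.log(config.intensity_scale), 0.2, size=(K, n_samples)
    )
    meth = beta * total
    unmeth = (1.0 - beta) * total

    fails = rng.random((K, n_samples)) < config.detection_fail_rate
    det_p = rng.uniform(0.0, 1e-4, size=(K, n_samples))
    det_p[fails] = rng.uniform(0.0, 1.0, size=int(fails.sum()))

    cols = sheet["sample_id"].to_numpy()
    intensities = IntensityData(
        methylated=pd.DataFrame(meth, index=probe_ids, columns=cols),
        unmethylated=pd.DataFrame(unmeth, index=probe_ids, columns=cols),
        detection_p=pd.DataFrame(det_p, index=probe_ids, columns=cols),
        bisulfite_control=pd.Series(
            rng.uniform(6000, 12000, size=n_samples), index=cols, name="bs_control"
        ),
    )
    annotation = pd.DataFrame(
        {
            "probe_id": probe_ids,
            "gene_symbol": [f"GENE{i}" for i in range(K)],
            "chromosome": rng.choice([f"chr{c}" for c in range(1, 23)], size=K),
            "distance_to_tss": -rng.integers(50, 1500, size=K),
            "cpg_island": island,
            "cross_reactive": False,
            "snp_overlap": False,
        }
    )
    truth = pd.DataFrame(
        {
            "probe_id": probe_ids,
            "is_spiked": is_spiked,
            "true_delta": np.where(is_spiked, config.spike_delta, 0.0),
        }
    )
    beta_df = pd.DataFrame(beta, index=probe_ids, columns=cols)
    return Cohort(intensities, beta_df, sheet, annotation, truth)


# -- sex-chromosome dosage cohort ------------------------------------------

#: the seven karyotype/mutation groups of the dosage comparison, with
#: functional KDM5C and KDM5D copy numbers and study sample sizes.
DEFAULT_DOSAGE_GROUPS: tuple[tuple[str, int, int, int], ...] = (
    ("47,XXX", 3, 0, 3),
    ("47,XXY", 2, 1, 3),
    ("46,XX", 2, 0, 16),
    ("46,XY", 1, 1, 19),
    ("45,X", 1, 0, 11),
    ("carrier", 1, 0, 4),        # skewed XCI: wild-type allele on active X
    ("mutation_male", 0, 1, 10),
)


@dataclass
class DosageConfig:
    """Parameters of the dosage-cohort generator.

    Expected beta per group follows a saturating dose-response
    ``baseline_beta + max_beta_gain * dose / (dose + saturation_dose)``
    with effective dose = kdm5c_copies + kdm5d_weight * kdm5d_copies.
    ``kdm5d_weight`` < 1 encodes that the Y-linked homologue only
    partially compensates.
    """

    group_spec: tuple[tuple[str, int, int, int], ...] = DEFAULT_DOSAGE_GROUPS
    kdm5d_weight: float = 0.5
    saturation_dose: float = 2.0
    max_beta_gain: float = 0.6
    baseline_beta: float = 0.2
    noise_sd: float = 0.04
    n_probes: int = 3
    seed: int = 0

    def validate(self) -> None:
        if not self.group_spec:
            raise ConfigError("group_spec must be nonempty")
        for label, c, d, n in self.group_spec:
            if c < 0 or d < 0:
                raise ConfigError(f"negative copy count in group {label!r}")
            if n < 1:
                raise ConfigError(f"group {label!r} has no samples")
        if not (0.0 <= self.kdm5d_weight <= 1.0):
            raise ConfigError("kdm5d_weight must be in [0, 1]")
        if self.saturation_dose <= 0:
            raise ConfigError("saturation_dose must be positive")


def effective_dose(kdm5c: np.ndarray, kdm5d: np.ndarray, weight: float) -> np.ndarray:
    """Functional demethylase dose: KDM5C copies + weight * KDM5D copies."""
    return np.asarray(kdm5c, dtype=float) + weight * np.asarray(kdm5d, dtype=float)


def dosage_group_means(config: DosageConfig) -> pd.Series:
    """Closed-form expected beta per group under the dose-response."""
    labels = [g[0] for g in config.group_spec]
    dose = effective_dose(
        np.array([g[1] for g in config.group_spec]),
        np.array([g[2] for g in config.group_spec]),
        config.kdm5d_weight,
    )
    mean = config.baseline_beta + config.max_beta_gain * dose / (
        dose + config.saturation_dose
    )
    return pd.Series(mean, index=labels, name="expected_beta")


def simulate_dosage_cohort(config: DosageConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate a beta matrix and sample sheet for the dosage comparison."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    rows = []
    for label, c, d, n in config.group_spec:
        sex = "F" if (label.endswith("XX") or label.endswith("XXX")
                      or label in ("45,X", "carrier")) else "M"
        for _ in range(n):
            rows.append((label, c, d, sex))
    sheet = pd.DataFrame(rows, columns=["karyotype", "kdm5c_copies",
                                        "kdm5d_copies", "sex"])
    sheet["sample_id"] = [f"D{i + 1:03d}" for i in range(len(sheet))]
    sheet["group"] = sheet["karyotype"]
    dose = effective_dose(
        sheet["kdm5c_copies"].to_numpy(),
        sheet["kdm5d_copies"].to_numpy(),
        config.kdm5d_weight,
    )
    sheet["effective_dose"] = dose
    mean = config.baseline_beta + config.max_beta_gain * dose / (
        dose + config.saturation_dose
    )
    beta = mean[None, :] + rng.normal(
        0.0, config.noise_sd, size=(config.n_probes, len(sheet))
    )
    beta = np.clip(beta, 0.0, 1.0)
    probe_ids = [f"dosage_probe_{i + 1}" for i in range(config.n_probes)]
    beta_df = pd.DataFrame(beta, index=probe_ids,
                           columns=sheet["sample_id"].to_numpy())
    cols = ["sample_id", "group", "karyotype", "sex", "kdm5c_copies",
            "kdm5d_copies", "effective_dose"]
    return beta_df, sheet[cols]
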