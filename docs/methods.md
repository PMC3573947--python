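# Methods

## Beta values and preprocessing

Methylation at a CpG probe is summarized as
β = Max(M,0) / [Max(M,0) + Max(U,0) + 100], where M and U are the
methylated and unmethylated fluorescence intensities. Negative
(background-subtracted) intensities are clamped to zero and the +100
offset regularizes low-intensity probes, so β < 1 always holds for
intensity-derived values. Externally supplied beta matrices may
contain exact 1.0; the reader accepts the closed interval [0, 1] for
imported data.

Sample QC applies two gates: bisulfite-conversion control intensity
strictly above a threshold, and a minimum fraction of probes detected
above background. Two presets ship: the discovery gate
(control > 4000, ≥ 99% of probes at detection p < 0.01) and a relaxed
gate for external datasets (control > 4000, ≥ 95% at p < 0.05). The
boundary is strict (`>`), so a control intensity of exactly 4000
fails.

Probe filtering removes the set union of (a) probes failing the
detection rule, (b) cross-reactive probes, (c) probes with a SNP in
the queried CpG. Exclusion lists may overlap, so the filter report
always carries per-reason counts *and* the union count; the union is
what is removed. The detection rule is applied probe-wise: a probe is
excluded if its detection p ≥ 0.01 in **any** retained sample
(`detection_mode="any"`, the default, chosen because whole probes are
removed before testing); `detection_mode="mask"` instead masks only
the failing observations and relies on the scan's pairwise-complete
handling. Filtering is idempotent.

## Per-probe scan

Each retained probe is tested case vs control with a two-sided
Mann–Whitney U test. The p-value is exact — computed from the full
null distribution of U obtained by the standard counting recursion
over label assignments — whenever the smaller group has ≤ 25
observations (configurable) and the pooled values are tie-free. The
printed floor for the 10 vs 19 design under complete separation is
2 / C(29,10) = 9.985e-8. With ties, the tie-corrected normal
approximation is used, without continuity correction by default (the
exact tail, not the corrected approximation, is what the design's
reported floor corresponds to). Variant-of-unknown-significance
samples are excluded from the test but their group mean is reported
descriptively.

Effect sizes per probe:

- **delta beta** = mean(case β) − mean(control β); negative values are
  methylation loss in cases.
- **delta Z**: β values are z-standardized across cases + controls
  (sample sd), and delta Z = mean z(controls) − mean z(cases), i.e.
  positive for loss. This standardized-separation definition
  reproduces the ≈ 1.8–2.0 magnitudes that accompany strong negative
  deltas under clean separation; it is a package definition, adopted
  because the score is conventionally reported but not formally
  defined in this literature.

Missing values are handled pairwise-complete per probe; probes with
fewer than two non-missing observations in either group are flagged
untestable rather than dropped.

For efficiency, the scan and the permutation engine share one
observation: within a probe, ranks do not depend on the group labels.
Ranks are computed once; the U statistic of any labeling is a
gather-sum over the rank matrix, and exact p-values are table lookups
on integer U. This makes B = 1000 permutations over thousands of
probes a single matrix product.

## Permutation FDP control

The multiple-testing procedure controls the false discovery
proportion (FDP) γ at confidence 1 − α. B label permutations
preserving the group sizes are drawn (only case and control samples
are permuted; VUS samples never enter the null). For each permutation
all probe p-values are recomputed and sorted ascending.

- γ = 0: the cutoff is the ⌈αB⌉-th smallest value of the
  per-permutation minimum ("best") p-value. Observed p-values strictly
  below the cutoff are significant.
- γ > 0 (rank substitution): find the largest s such that the s-th
  smallest observed p lies strictly below the ⌈αB⌉-th smallest value
  of the per-permutation (⌊γs⌋+1)-th order statistic; declare the top
  s probes. Because the threshold is nondecreasing in s, the declared
  set equals {p < cutoff}, and γ = 0 recovers the best-p rule exactly.

Conventions: the order-statistic rule (no interpolation) keeps small-B
behaviour exact and reproducible; strict inequality at the cutoff is
conservative; α with αB < 1 is rejected with the minimum feasible α
named. The observed labeling is not counted among sampled
permutations; exhaustive mode enumerates every distinct assignment
exactly once (and therefore contains it), is seed-invariant, and is
entered automatically (with a warning) when B reaches the number of
distinct assignments.

The significant set is monotone nondecreasing in both α and γ. Under
a pure null the procedure guarantees P(any discovery at γ=0, α) ≤ α;
the acceptance suite verifies this on 200 simulated null cohorts.

## Unsupervised structure

Samples are clustered on selected probes by complete linkage over the
cosine distance d(x,y) = 1 − x·y/(‖x‖‖y‖) ∈ [0, 2]; sample order is
fixed lexicographically before agglomeration so distance ties break
deterministically. The two-group cut of the dendrogram is compared to
case/control labels (adjusted Rand index). Dendrograms serialize to
Newick with branch lengths derived from merge heights. K-means and
K-medians partitions are available behind the same interface with a
fixed seed. Clustering operates on raw beta values (not standardized),
matching the heatmap convention of beta-scaled displays.

Ordination: per-probe median centering, then k-nearest-neighbour
imputation of missing values (k = 10 by default; neighbours are
probes, using Euclidean distance over shared samples, the
transcriptomics convention — a switch selects sample-wise neighbours),
then standard PCA. Component signs are fixed by making each
component's largest-magnitude loading positive, so scores are fully
deterministic and invariant to probe order.

## Island asymmetry

Among probes significant at a threshold, loss (delta beta < 0) and
gain (> 0) are tallied within CpG-island and non-island strata; zero
deltas are set aside and reported. Context-by-direction association
uses Fisher's exact test; a single-stratum loss excess is tested
against the fair-coin null with the exact binomial sign test
(53 losses / 0 gains gives 2·2⁻⁵³ ≈ 2.22e-16). The genome-wide shift
is quantified by reducing each sample to its mean beta per stratum and
comparing groups with a Mann–Whitney test (the stratum test is a
package assumption; the comparison is conventional but the test
behind the reported stratum p is not named in this literature). With
n_spiked spikes of size δ among an island stratum of size K, the
expected stratum difference is n_spiked·δ/K — fractions of a percent
at realistic scales, which the tests verify by dilution arithmetic.

## Cohort comparisons

- **Kruskal–Wallis** across ≥ 2 groups with tie correction; chi-square
  p with g−1 df, or exact enumeration over all assignments of the
  pooled values to the group sizes for total n ≤ 10.
- **Sex scan**: per-probe female/male Mann–Whitney with
  Benjamini–Hochberg q-values ("q-value" here means BH adjusted p —
  a package assumption, documented because other estimators exist).
- **Dosage trend**: effective dose = KDM5C copies + w·KDM5D copies
  with w ∈ (0,1) (default 0.5, encoding partial compensation by the
  Y-linked homologue). Per-probe beta is related to dose by Spearman
  rho and a Jonckheere–Terpstra trend test across dose-ordered groups
  (two-sided permutation p, seeded). Female carriers of a KDM5C
  mutation with skewed X inactivation are encoded with one functional
  KDM5C copy.
- **Population outlier screen**: a query observation is flagged below
  the reference minimum minus a margin (default 0); the robust
  alternative flags below median − 5·MAD. The rule name is recorded in
  the output. A warning (not an error) is raised for references under
  30 samples.

## Synthetic cohorts

The case/control generator emulates the study design: 10 cases over
families (3,2,2,2,1), 16 unrelated controls plus 3 unaffected
relatives (the relative pool for robustness enumeration — this family
structure yields 24 case choices × 3 relatives = 72 subset
combinations), and 2 VUS samples. Probe baselines are bimodal:
island probes Beta(2,5) (low/intermediate), non-island Beta(8,2)
(high), with the island fraction 0.45. Spiked probes are drawn from
island probes whose baseline survives the shift; cases at spiked
probes have expected beta = baseline + spike_delta (default −0.4,
within the 0.2–0.5 loss range the design targets; only loss is
modelled).

Observed betas are logit-normal: logistic(a + ε) with ε the sum of
iid dispersion (sd 0.3), a per-sample global offset (sd 0.15), and
three latent factors (probe loadings sd 0.15, unit-normal sample
scores). The location a is chosen by inverting the Gauss–Hermite
expectation so that E[β] equals the target exactly — this keeps
delta-beta estimates unbiased for the spike size. The shared
sample-level components emulate the unmodelled heterogeneity of real
arrays: they dominate genome-wide ordination (so PCA on all probes
does not separate the groups at a 50/24,000 spike fraction) while
leaving samples exchangeable under the null, so permutation inference
stays valid. An optional shared family intercept exists and defaults
to off. Intensities are synthesized as M = βS, U = (1−β)S with S
log-normal around 5000 (sd 0.2 in log), so the beta formula re-derives
β up to the +100 offset (a ≈ 2% multiplicative shrinkage at this
intensity scale). Detection p-values are near zero except for a 0.1%
fraction drawn uniform on [0, 1]. All output is a pure function of the
config, including its seed.

What the generator does **not** emulate: batch effects across
studies, cell-type composition shifts, chromosomal position or probe
correlation along the genome, and age/ethnicity structure.
Consequently, passing tests demonstrate the statistical machinery's
correctness and calibration under the modelled design — not
robustness to those real-data complications.

The dosage generator draws seven karyotype groups
(47,XXX; 47,XXY; 46,XX; 46,XY; 45,X; carrier; mutation male with
N = 3/3/16/19/11/4/10) with expected beta following the saturating
dose–response base + gain·dose/(dose + s₀), defaults base 0.2,
gain 0.6, s₀ = 2.0, Gaussian noise sd 0.04 clipped to [0, 1], and
3 probes (the three validated genes). With w = 0.5 the effective
doses are 3, 2.5, 2, 1.5, 1, 1, 0.5 — strictly ordered expected means
except the intentional 45,X/carrier tie.

## Numerical choices and problem sizes

- Exact U distributions are computed once per (n₁, n₂) by the counting
  recursion and cached in the scan state; two-sided p = 2·min(cdf, sf)
  capped at 1.
- Tie handling: a probe row with any tied values uses the
  tie-corrected normal variance (label-invariant, precomputed per
  row); a pooled-constant row returns p = 1.
- p-values print in scientific notation with the mantissa truncated
  at three significant figures (9.985e-8 → 9.98E-08), matching the
  display style of the array reports this pipeline mirrors; stored
  values keep full precision.
- Simulation-backed checks run at 2,000 probes with B = 500–1000
  permutations and 20–200 replicates, and the structure contrast at
  the full 24,000-probe scale — sizes chosen so the whole suite
  completes in about a minute while keeping Monte-Carlo error well
  inside the asserted bounds.

## Known limitations

- The γ > 0 rule is one member of the family of FDP-confidence
  constructions; published cutoffs computed with a different
  percentile convention will differ in the last digit.
- The exact Mann–Whitney path requires tie-free data; heavily
  discretized beta values fall back to the normal approximation.
- The subset-robustness enumeration is exhaustive, so its cost grows
  as the product of family sizes times the relative pool.
- kNN imputation assumes missingness unrelated to the signal;
  detection-masked values violating this bias PCA mildly.
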