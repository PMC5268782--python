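# Methods

This note documents the models, parameter choices, numerical conventions and
known limitations of the serrsig pipeline.

## Factorial interaction model

Per gene, log2 expression is modelled as a fixed-effects one-way ANOVA over
the genotype groups: y_gij = μ_gj + ε_gij with ε ~ N(0, σ_g²), the variance
pooled across **all** fitted groups (including the Apc-null arm, not only the
factorial quartet) with residual df = N − G. Pooling across all groups uses
every sample to estimate σ² — at 3 samples per group the df gain (10 vs 8)
matters — and is the package's reading of an unqualified "one-way ANOVA over
five groups"; the design object accepts any group set, so quartet-only
pooling is available by fitting on a restricted design.

The interaction contrast is c = (μ_dm − μ_braf) − (μ_cdx2 − μ_ctrl) with
standard error √(s²·Σ_q 1/n_q), referred to the t distribution on the
residual df, two-sided. Its anti-log ρ = 2^c (the ratio of ratios) is the
effect size on the fold-change scale. Log base 2 is used everywhere, so
"anti-logarithm" always means 2^c; ρ is base-invariant provided the anti-log
matches the log.

Selection is strict on p (p < p_max) and inclusive on ρ (ρ ≥ ρ_min or
ρ ≤ 1/ρ_min). Defaults: p_max = 0.01; ρ_min = 10 for heatmap-style
shortlists, 1.3 for enrichment-bound lists. Zero-residual-variance genes get
no p-value: they are flagged degenerate, logged, and never selected, rather
than being assigned p = 0.

Probe-to-gene collapsing calls a gene up if at least one probe is up and
none is down (symmetrically for down); conflicting probes force "neither"
and are logged. This any-up-and-no-down rule is this package's own
convention — collapsing schemes differ between toolchains, and exact
reproduction of probe-level selection counts from other pipelines is not
promised.

PCA is computed on all genes with gene-wise centering only (no variance
filtering, no scaling), via SVD of the centered matrix; sample scores are
V·S, component variances s²/(n_samples − 1), and each component's sign is
fixed so its largest-magnitude sample loading is positive.

## Cohort signature

"Two-sample t-test" is implemented as the pooled equal-variance test
(two-sided) with a Welch option. Fold-change is geometric: 2^|Δ| for the
difference Δ of log2 group means, with strict cuts p < 0.01 and
Δ beyond ±log2(1.3). "Low CDX2" has no canonical threshold; the default rule
takes the lowest quartile of CDX2 expression across the cohort, is
configurable, and is always recorded in the design's provenance field.
Degenerate genes are those with zero pooled variance *and* zero difference;
zero variance with a nonzero difference is exact separation of the groups
and collapses the two-sided p to 0 (this keeps the noise-free limit
consistent: planted genes are called, flat genes are excluded).

## Cross-species concordance

Only homology groups with exactly one gene per species are carried (1-to-1
best homologs); any group with two or more genes on either side is dropped
entirely. The concordance table is 3×2 — rows = human call
{up, neither, down} scored {+1, 0, −1}, columns = mouse call {up, down}
scored {+1, −1} — over the population of mouse-selected, 1-to-1-mapped,
human-measured genes. This is the one orientation that yields a 3×2 table
containing both agreement and disagreement cells; it is recorded here as an
assumption. The Mantel-Haenszel statistic is Q_MH = (N − 1)·r² with r the
count-weighted Pearson correlation of the scores, referred to chi-square
with 1 df. Q_MH is invariant to affine increasing rescaling of either score
set and to transposition; r negates if one ordering is reversed. p-values
beyond double-precision range are reported as a log10 tail alongside p.

## Over-representation and permutation FDR

Gene sets are intersected with the universe before sizing. The one-sided
exact p is the upper hypergeometric tail P(X ≥ x), accumulated as a
logsumexp over log point masses so magnitudes near 1e-28 keep full relative
accuracy; it equals the one-sided Fisher exact p of the 2×2 overlap table
(verified against exact rational enumeration in the tests). Rows are ranked
by ascending p with ties broken by descending observed/expected then set
name.

The Q-value at rank k redraws the selected list as a uniform random
K-subset of the universe n_perm times (default 100) — equivalent to
permuting gene identifiers, but cheaper — recomputes all set p-values, and
takes the mean count of permuted sets with p ≤ p_(k), divided by k,
truncated at 1 and monotonized to be nondecreasing in rank. Whether the
published estimator thresholded on p_(k) or on rank count alone is not
documented anywhere we could check; the p-threshold form is used and the
permutation count is configurable. Q-values are bit-reproducible given
(seed, n_perm).

## Clinical statistics

* IHC positivity: strictly more than 10% of neoplastic cells stained.
* CIMP: low = 0–2 of 5 methylated promoters, high = 4–5; a count of exactly
  3 falls between the stated definitions and is assigned high by default
  (consistent with low = 0–2), switchable.
* MSI: ≥ 2 of 5 unstable markers.
* Fisher exact (two-sided): probability-ordering rule — the sum of point
  probabilities of all tables with the observed margins whose probability
  does not exceed the observed one, with ~1e-7 relative tie tolerance
  (scipy's convention, verified exhaustively against exact rational
  enumeration for all tables with N ≤ 20). Cases missing either marker of a
  pair are excluded from that pair's table and counted.
* Kaplan-Meier: product-limit estimator; the median is the smallest t with
  S(t) ≤ 0.5 (step-function convention) and is reported as "greater than"
  the end of follow-up when S never reaches 0.5. Log-rank uses the
  hypergeometric variance form with simultaneous risk-set accounting at
  ties. Marker-association p-values are not multiplicity-corrected; only
  enrichment Q-values are.

## Synthetic generators

The generators define the study conditions every test runs under:

* **Factorial**: 5 genotypes × 3 mice, baseline 7 log2 units, i.i.d.
  Gaussian noise on the log2 scale (default sd 0.5; the Gaussian-on-log
  model is the minimal assumption matching an ANOVA on log-transformed
  data). Interaction genes receive the signed contrast entirely on the
  double-mutant mean; marginal-only genes receive a Cdx2 main effect applied
  equally to both Cdx2-null groups so it cancels in the interaction
  contrast. Counts of planted genes are ⌊frac·n⌋.
* **Cohort**: 18 cases vs 104 controls; signature genes shifted ±effect
  (sign equiprobable) in cases.
* **Homolog map**: exactly ⌊frac·n⌋ 1-to-1 groups; the rest get 2–3 genes
  on one side. Mouse/human gene ids match the expression generators so
  calls join directly.
* **Gene sets**: uniform random subsets, sizes uniform on [36, 194] — the
  size range of a 50-set hallmark-style collection.
* **Marker cohort**: 36 cases; a latent class (prevalence 0.5) multiplies
  each marker's baseline odds, planting the CDX2-loss/BRAF-type
  co-occurrence structure.
* **Survival**: exponential event times per group, administratively
  censored at 480 days (the longest follow-up modelled); default hazards
  ln2/103 and ln2/158 for the two tumour-prone genotypes and 0 for the
  single mutants, with group sizes 7/5/6/5.

Same seed and config give bit-identical outputs; output files are written
with fixed numeric formatting. The generators emulate group structure,
effect sizes and censoring — not probe-level microarray intensities,
normalization artefacts, gene-gene correlation, or methylation chemistry.
Passing tests therefore demonstrate calibration and recovery under the
stated noise model, not robustness to real-array correlation structure.
Noise sd is a free parameter, not calibrated to any deposited array series
(no dispersion estimates were available to calibrate against).

## Problem sizes and numerical choices

Type-I error calibration uses 20,000 null genes (99% binomial band around
0.01). Contrast-recovery checks use 1,000 planted genes at sd 1 (2-standard-
error band). Fisher/hypergeometric enumeration checks run all 10,625 tables
with N ≤ 20 and ~500 tail instances with N ≤ 50 in exact rational
arithmetic. The Q_MH permutation-null check uses a population of 3,000
called genes and 1,000 permutations: Q_MH is asymptotically chi-square(1),
and at small N the permutation lattice's discreteness is visible to a KS
test, so the check is run at a size where the asymptotic reference is the
right yardstick. Log-rank level is estimated from 400 simulated
equal-hazard cohorts of 200+200 (99% band around 0.05), a size chosen to
keep the full suite fast while the band stays informative. Kaplan-Meier
median recovery uses n = 500 against the closed form median = ln 2/λ.

## Known limitations

* The ANOVA has no variance moderation or shrinkage; with 3 samples per
  group, per-gene variance estimates are noisy and the ρ ≥ 10 shortlist is
  conservative on weak effects (visible in the worked example's 60%
  recovery at the strict regime).
* The concordance-table orientation and population are a documented
  assumption, not an established convention.
* The permutation FDR redraws identifiers independently; it does not
  preserve gene-gene correlation.
* Exact reproduction of probe-level selection counts from other toolchains
  is out of scope (collapsing rules differ and are not documented there).
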