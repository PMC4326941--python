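# Methods

## Model and procedure

The package implements a two-stage association screen for a quantitative
trait (percent lean body mass) against a panel of biallelic SNPs, treating
each SNP marginally.

**Genotype coding.** Calls are counts of the coded allele in {0, 1, 2} with
a missing sentinel. Minor/major status is established *in-sample*: the
coded-allele frequency f = (n₁ + 2n₂)/2n determines MAF = min(f, 1−f), and
the VCF importer flips ALT-allele counts whenever the ALT allele is the
in-sample major allele, so code 2 always counts the minor allele. This
makes dominant/recessive collapsing independent of how the source file
ordered the alleles. Positions are 1-based; chromosome labels are opaque
strings (non-autosomal input passes through untouched).

**Quality control.** Three per-SNP filters, all with inclusive (≥)
comparisons: call rate ≥ 0.95, MAF ≥ 0.10, Hardy–Weinberg exact P ≥ 10⁻⁴.
QC is computed on the subjects remaining after genotype/phenotype
alignment, since that is the analysis set. The HWE test is the exact
conditional test — given the observed allele counts, the heterozygote
count h has fixed parity and probability ∝ 2ʰ n!/(n_rr! h! n_cc!); the P
value sums all configurations no more probable than the observed one. It is
evaluated in exact integer arithmetic (weights are integers, the only
rounding is the final division), which makes the test well-defined at all
counts, including the rare-genotype corner cases a MAF filter does not
fully exclude, and free of floating-point tie ambiguity. A 1-df chi-square
variant is available (`hwe_test="chisq"`) for comparison with legacy
pipelines; exact is the default.

**Age adjustment.** Lean mass is residualized on age by ordinary least
squares (intercept + linear term), with the sample mean added back so
values stay on the percent scale. Zero age variance is treated as slope 0.
A no-adjustment mode supports sensitivity analysis; the replication stage
compares raw traits by default.

**Threshold scan.** For each (SNP, model), non-missing subjects are
labelled carrier/reference (pairwise per-SNP exclusion of missing calls),
and the candidate thresholds are the midpoints between consecutive
distinct sorted trait values — the finest grid at which the 2×2 table can
change, so it attains any coarser grid's minimum. Thresholds leaving fewer
than `min_group_cells` (default 5) subjects in either phenotype category
are skipped, guarding against degenerate extreme tables. The "low"
category is strictly-below-threshold throughout. Each table is scored with
the two-sided Fisher exact test defined as the sum of hypergeometric
probabilities of tables (at fixed margins) whose probability is ≤ the
observed table's, with a 1e-7 relative tolerance on the comparison — the
convention of R's `fisher.test`, stated explicitly because two-sided
Fisher definitions vary. Ties in the minimum P are broken toward the
threshold nearest the trait median, then the smaller threshold, so results
are deterministic. A scan with no surviving threshold, a constant trait,
or a genotype group of fewer than two subjects returns a degenerate result
with min-P = 1 rather than an error.

The relative risk reported at the winning threshold is the risk of the
low-trait category in carriers relative to non-carriers; the direction is
a convention (the full table is emitted so readers can invert it), and the
95 % CI uses the log-scale normal approximation with z = 1.96, with the
Haldane–Anscombe 0.5-cell correction (flagged) when a zero numerator cell
would otherwise undefine the SE.

**Hit selection.** Screen hits satisfy min-P < 10⁻⁶ — strict inequality,
in contrast to the inclusive QC comparisons; both boundaries are tested.
No further multiplicity correction is applied: the cutoff plays that role,
and the anticonservatism of min-P (below) is deliberately left visible.

**Replication.** Unpaired t-tests, classical pooled-variance by default
("Student's"), Welch optional. From published summaries (n, mean, SE), the
Welch statistic is t = (m₂−m₁)/√(SE₁²+SE₂²) with Welch–Satterthwaite df;
the pooled variant reconstructs group SDs as SE·√n. Printed summaries are
rounded, so P values derived from them are bounds rather than exact
reproductions; the package checks both variants. Sign conventions differ
deliberately: raw-data t is oriented group1−group2 (the standard library
convention), summary-based t is group2−group1 (how a published
carrier-vs-reference table reads); the suites verify they agree up to
sign.

## Numerical implementation of the Fisher scan

The scan evaluates thousands of tables per SNP, so the hypergeometric pmf
is computed directly from a cached ln Γ table as a (cell value ×
threshold) matrix, and both the inclusion comparison and the summation run
in log space (log-sum-exp), keeping P values defined for extreme tables at
large n where the pmf underflows linearly. The scalar
`fisher_exact_2x2` is the single-column case of the same routine, so the
scan minimum and per-table P values are bitwise consistent. The
implementation is validated against an exact-integer enumeration oracle on
every table with total ≤ 40 (agreement ≤ 1e-10) and against an independent
library implementation on random tables.

## Synthetic cohorts

The generator emulates the replication-cohort template: default n = 1081,
lean mass 34.2 ± 3.5 %, age 65.1 ± 9.4 y, independent SNPs with HWE
genotypes (Binomial(2, q) per subject) at per-SNP allele frequencies drawn
uniformly from `maf_range` (default [0.10, 0.50], matching the post-QC
panel), i.i.d. missingness, and an optional causal SNP adding a fixed
shift `effect_beta` to its carrier group under a chosen model. The default
effect size used in the shipped presets, 0.7 % lean mass, echoes the
published carrier/non-carrier gap (34.5 vs 33.8); the preset allele
frequency q ≈ 0.35 reproduces the published carrier fraction 624/1081
under dominant collapsing. Age enters linearly with configurable slope
(default 0); the residual SD shrinks as age/genetic components grow so the
*marginal* trait SD stays at `trait_sd`, keeping cohorts comparable across
configurations. Secondary traits (fat mass 31.9 ± 7.7 %, BMD 0.98 ± 0.15
g cm⁻²) are generated independent of genotype, giving the replication
comparison a known null ground truth.

What the generator does **not** model — linkage disequilibrium, population
structure, relatedness, genotyping error, non-normal trait tails — bounds
what passing tests show: they validate the statistics and the pipeline
under the method's own assumptions, not robustness to real-data artefacts.

All randomness flows from a single integer seed through two named
`numpy` Generator streams (genotypes, phenotypes), so identical configs
give bit-identical cohorts.

## Operating characteristics (computed by the shipped studies)

`experiments.null_calibration` measures, on 2 000 null SNPs at the
screening-stage size n = 269, the empirical size at α = 0.05 of (a) the
Fisher test at a fixed median split — conservative, as an exact test — and
(b) the threshold-scan minimum P, which exceeds nominal size several-fold.
This anticonservatism is an inherent property of maximally selected
statistics used with nominal critical values; permutation calibration
would fix it but is out of scope, matching the screening design as
published (stringent cutoff + replication instead).

`experiments.recovery_study` measures how often a single causal SNP
(default shift 0.5·SD, dominant, MAF 0.35) among 1 000 null SNPs attains
the panel-wide minimum P across 50 seeded replicates. At these settings
the causal SNP's scan P is comparable in magnitude to the minimum of 1 000
anticonservative null statistics, so recovery is partial (roughly half of
replicates, seed-dependent); markedly larger effects are recovered
essentially always, as the pipeline test with a planted strong SNP shows.

## Problem sizes and defaults

| parameter | default | units | rationale |
|---|---|---|---|
| `min_call_rate` | 0.95 | fraction | screening filter, inclusive |
| `min_maf` | 0.10 | fraction | screening filter, inclusive |
| `min_hwe_p` | 1e-4 | probability | screening filter, exact test, inclusive |
| `screen_alpha` | 1e-6 | probability | stage-1 cutoff, strict < |
| `min_group_cells` | 5 | subjects | floor on either phenotype-category total |
| `n_subjects` | 1081 | subjects | replication-cohort template |
| calibration panel | 2 000 SNPs, n = 269 | — | screening-stage sample size |
| recovery study | 50 replicates × 1001 SNPs | — | keeps the full study under ~2 min on one CPU |

## Known limitations

- The scan's min-P is not a calibrated P value; compare it only to other
  scan P values or to simulation-based references.
- Summary-based t-tests inherit the rounding of the published summaries.
- Age adjustment is linear only; stratified or spline adjustment is not
  implemented.
- No additive/trend genetic model, no covariates beyond age, and no
  permutation-adjusted P values.
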