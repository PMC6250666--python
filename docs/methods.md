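# Methods

This note documents the statistical model behind each stage, the defaults
and why they were chosen, what the synthetic generator does and does not
emulate, and the numerical choices that matter for reproducing results.

## The synthetic two-cohort test-bed

The generator emulates the design the analysis chain targets: two cohorts of
180 and 100 samples genotyped on one shared variant panel, each with its own
expression matrix. All variants sit on a single synthetic chromosome in
`n_blocks` LD blocks of `snps_per_block` variants (defaults 50 × 10); blocks
are 150 kb apart with 5 kb SNP spacing, so a 1 Mb cis window spans a gene's
own block plus ~6 independent neighbours on each side.

**Genotypes.** Haplotypes within a block share one allele frequency (drawn
uniformly from `maf_range`, default (0.05, 0.5] to mimic a post-QC panel;
tight LD implies near-identical frequencies) and are generated from an
equicorrelated latent Gaussian thresholded at that frequency. Because
thresholding attenuates correlation, the latent correlation is calibrated by
bisection on the bivariate-normal orthant probability so that the *genotype*
correlation matches `within_block_r` (default 0.9). Summing two independent
haplotypes yields dosages in Hardy–Weinberg proportions by construction.
Variants in different blocks are independent.

**Expression.** Gene *g* sits at the centre of block *g*. On a latent scale,
expression = intercept + β·dosage (for the `frac_egenes` fraction of genes,
default 0.2, matching the roughly one-in-five genes under detectable cis
control) + age and sex effects + sparse loadings on `n_hidden_factors`
standard-normal factors + N(0, `noise_sd`²) noise. β is N(0, 0.5²) by
default, or pinned via `fixed_effect_size`; units are residual SDs per
alternate allele. With `expression_scale="tpm"` the emitted matrix is
2^latent (positive, skewed, exercising the full normalisation chain); with
`"sd"` the latent values are emitted directly so a regression recovers β
without the attenuation that any rank-normalisation necessarily introduces.
Recovery benchmarks therefore use the `"sd"` scale.

**Trait scenarios.** `shared`: trait = effect × (standardised driver-gene
expression) + noise, so trait and expression share the planted causal
variant. `distinct`: the trait is driven by a variant from a *different*
block inside the driver gene's cis window, verified to have r² below the
stated bound (default 0.2) with the eQTL variant; an error is raised if no
such variant exists. `null`: pure noise. GWAS summary statistics are
per-variant simple regressions of the trait on dosage.

**MR summary data.** True exposure effects ~ N(0.4, 0.1²) truncated at 0.1;
observed exposure effects add N(0, se_x²); outcome effects are generated
from the observed exposure effects (the standard NOME-satisfying shortcut)
as β_Y = θ·β_X + α + N(0, se_y²), with the pleiotropic intercept α ~
N(mean, sd²) applied to the first `invalid_frac` share of instruments.

**What is not emulated:** population structure and admixture, realistic
recombination maps or allele-frequency spectra, missing genotypes,
library-size and GC artefacts in expression, and trans effects. Passing
recovery tests on this generator therefore demonstrates the correctness of
the statistical machinery, not robustness to every failure mode of real
kidney data.

## QC and normalisation

Variant filters (defaults): MAF ≥ 0.05; Hardy–Weinberg exact test p ≥ a
caller-supplied threshold (0.001 for a genotyped panel, 1e-6 for an imputed
one — the appropriate value depends on the upstream pipeline, so it is an
explicit argument); call rate ≥ 0.95; imputation R² ≥ 0.4 when metadata
carry it; duplicated positions, non-SNPs and sex/MT variants removed. The
HWE test is the exact conditional test (summing probabilities of
heterozygote counts no more probable than the observed one given the allele
counts), the convention of standard genotype-QC toolchains; a chi-square
alternative was deliberately not added because the exact test is correct at
all counts. Each excluded variant is reported under its first failing rule,
so QC-report counts reconcile exactly with matrix dimensions.

Sample filters: genotype missingness > 5% and heterozygosity beyond ±3 SD of
the cohort mean. Relatedness, ancestry and sex-concordance exclusions are
consumed as a caller-provided list — computing them is out of scope.

Gene filter: a gene is kept iff strictly > 0.1 TPM in ≥ 50% of samples
within *every* batch (per-batch, not pooled, so a gene silent in one cohort
cannot ride in on the other), and sex-chromosome genes are dropped.

Normalisation chain, in fixed order (`ExpressionMatrix.stage` enforces it):

1. log₂(TPM + 1);
2. robust quantile normalisation: the target distribution is the per-rank
   *median* across samples (not the mean), making the target insensitive to
   single aberrant samples; tied values receive the mean of their ranks'
   targets;
3. per-gene outlier imputation: a Huber regression (tuning 1.345) of the
   gene on an intercept plus optional covariates; observations with
   residuals beyond Q1 − 3·IQR or Q3 + 3·IQR are replaced with fitted values
   from a refit without them;
4. per-gene rank-based inverse normal transform with Blom offsets,
   Φ⁻¹((r − 3/8)/(n + 1/4)); ties get average ranks, so tied inputs map to
   identical outputs; a zero-variance gene maps to zeros with a logged
   warning. The offset is configurable; Blom is the common default in eQTL
   pipelines.

Hidden expression factors are the top principal components of the expression
matrix after projecting out known covariates, returned orthogonal and
unit-variance. They play the adjustment role that learned latent-factor
models (PEER-style) play on real data; for the linear nuisance structure the
generator produces, PCA factors span the same space. The default factor
count follows the sample-size schedule common in large eQTL projects (15
below 150 samples, 30 below 250, 35 above). Genotype PCs are computed from
the centred, frequency-scaled dosage matrix; three are used downstream by
default.

## cis-eQTL mapping and meta-analysis

A SNP–gene pair is tested iff the SNP lies within 1 Mb of the nearest gene
boundary, boundaries inclusive, 1-based coordinates. Per study, OLS of
normalised expression on dosage with an intercept and the study covariates;
the p-value is two-sided from the t distribution at residual df. The batched
engine projects the covariates out of expression and dosage once per study
(Frisch–Waugh–Lovell) and is provably identical to per-pair OLS (tested to
1e-10). Cross-study combination is fixed-effect inverse variance on the
*betas*: w_k = 1/se_k², β = Σw_kβ_k/Σw_k, se = 1/√Σw_k, with the meta
p-value taken two-sided normal from z = β/se. ("Combining nominal p-values
with inverse-variance weights" is operationally this weighted-beta z; the
alternative z-score-combination reading was rejected because it discards the
effect-size scale.) A gene present in one study passes that study's
estimates through unchanged.

## Permutation calibration and eGene calling

At each of B permutations (default 2000) one random rearrangement of sample
labels per study is applied jointly to expression and the non-genetic
covariates, while genotypes and genotype PCs keep their order — one shared
permutation across all genes per iteration, preserving gene–gene
correlation. The full per-study regression + meta chain is re-run and the
smallest meta-p per gene recorded, giving the empirical null F_i. The
adjusted p is (1 + #{null ≤ observed})/(B + 1); the pseudocount avoids
exact zeros. Gene FDR uses Storey q-values with a cubic-spline-smoothed π₀
(evaluated at λ = 0.95); below 100 genes, or when the smoother misbehaves,
π₀ falls back to 1, which makes q identical to Benjamini–Hochberg. Genes
with q < 0.05 are eGenes. The genome-wide threshold P_t is the adjusted p of
the gene whose q is closest to 0.05 (ties → smaller adjusted p); the
per-gene nominal threshold is the type-1 (left-continuous) empirical
quantile P_t,i = F_i⁻¹(P_t). A pair is significant iff its gene is an eGene
and its nominal meta-p ≤ P_t,i; the best eSNP per eGene is the smallest
meta-p, ties broken by smaller bp position.

## RTC colocalisation

Pseudo-phenotype: residuals of expression on the GWAS variant's dosage (plus
the standard covariates by default — the covariate-free variant is an
argument away, but the covariate-inclusive form keeps the residual model
identical to the eQTL model). Every variant in the interval is regressed
against the pseudo-phenotype; variants are ranked by descending p (rank 0 =
highest p), average ranks on ties; the eQTL variant's score is (N − rank)/N,
colocalised iff ≥ 0.9 (inclusive). Intervals are supplied by the caller
(recombination coldspots on real data; the generator emits gene-window
intervals). This is the conditioning-on-the-GWAS-variant formulation; the
score is invariant to any monotone transform of the p-values.

## Mendelian randomisation

Instruments: greedy LD pruning of a gene's cis results — ascending p, keep a
variant iff p < 0.08 and r² < 0.2 with every kept variant. (0.08 is an
unusual threshold but is adopted as the default deliberately; both knobs are
arguments.) Harmonisation aligns outcome to exposure effect alleles,
flipping signs on allele swaps, resolving strand flips via complements and
dropping palindromic A/T–C/G variants by default.

Estimators (first-order weights 1/se_Y² throughout; se_X enters only the
median bootstrap):

- *robust IVW*: zero-intercept weighted regression of β_Y on β_X fitted by
  IRLS with a Tukey bisquare loss (c = 4.685), scale = MAD, standard errors
  from the Huber sandwich. The bisquare loss is redescending and non-convex,
  so the fit starts from a high-breakdown anchor — the weighted median of
  the ratio estimates — rather than from least squares;
- *penalised weighted median*: ratio estimates θ_j = β_Yj/β_Xj with weights
  w_j = β_Xj²/se_Yj², penalised by min(1, 20·P_χ²₁(Q_j)) where Q_j is the
  instrument's Q contribution **at the unpenalised weighted-median
  estimate** — anchoring the penalty at IVW would let a large invalid
  minority drag the anchor and penalise the valid instruments, destroying
  the ≤ 50%-invalid-weight breakdown property. The estimator interpolates
  the cumulative-weight percentile function at 0.5; its standard error is a
  seeded parametric bootstrap (default 2000 redraws of β_X, β_Y from their
  standard errors);
- *robust MR-Egger*: the same robust loss with an intercept, inputs
  orientated so β_X ≥ 0; the slope is the causal estimate, the intercept
  estimates directional pleiotropy. Requires ≥ 3 instruments (the median
  needs 3, Egger's two parameters make fewer unidentifiable).

Sensitivity: Cochran's Q = Σw_j(θ_j − θ̂)² on J − 1 df, plus the Egger
intercept test. Verdict: causal iff ≥ 2 of the 3 estimators have p below
0.05/m for the m-gene family (0.05/7 ≈ 0.0071 for a 7-gene family, 0.05/11
≈ 0.0045 for an 11-member isoform family).

Known limitation: under heavy mean-shift contamination (40% invalid weight)
the penalised median retains a small upward bias (≈ 0.05 at the benchmark
settings) because the single penalisation pass also clips the far tail of
the valid cluster; the estimate remains well within two standard errors of
the truth, which is the property the estimator promises.

## Overlap, enrichment, annotation

Proxies: r² computed from dosage correlation on the panel, window-limited to
1 Mb (the cis scale; unlimited search would be quadratic and biologically
meaningless here), proxy iff r² strictly > 0.8, sentinel always in its own
set. A GWAS sentinel overlaps the eSNP catalogue iff itself or any proxy is
in it. Matched random sets follow the SNPsnap recipe: per-SNP relative
tolerances (|x − x₀| ≤ tol·|x₀|) of ±10% on MAF and ±50% on LD-buddy count,
gene density and distance to the nearest gene; sampling without replacement
within a set, never from the input; unmatched inputs are skipped with a
warning and counted. Enrichment fold = observed/mean-null; the p-value
defaults to Fisher's exact test on the pooled 2×2 (input hits/misses vs
pooled matched hits/misses), with an empirical-rank alternative
((1 + #{null ≥ obs})/(n_sets + 1)) selectable — the pooled construction is
documented rather than assumed because the field reports Fisher p for
100-set comparisons without stating it. BED tracks are 0-based half-open;
a variant at 1-based position p hits [s, e) iff s ≤ p − 1 < e; all
conversions live in the I/O layer.

## Expression–phenotype meta-analysis

Case–control mode: per-study signed z from the two-sided p and the fold-
change direction, combined as Z = Σw_k z_k/√Σw_k² with w_k = √n_k. (The
weighting description in the source literature is ambiguous; sample-size
weighting is the standard signed-z construction and is the documented
default.) Correlation mode: the Olkin–Pratt approximately-unbiased
correlation G = r(1 + (1 − r²)/(2(n − 3))), pooled fixed-effect with weights
n_k − 1 (n_k − 3 selectable), p via Fisher z at the summed n. Heterogeneity:
Cochran's Q on the signed-z scale (unit variances) or the Fisher-z scale
(variance 1/(n − 3)). A gene call requires Bonferroni significance (α/m)
*and* no detected heterogeneity (Q p ≥ 0.05).

## Pipeline and determinism

`run_pipeline` executes simulate → QC/normalise → eQTL → calibration/eGenes
→ overlap → RTC → MR → expression meta, each stage reading only declared
TSV/JSON artefacts. The manifest records the full configuration and a
SHA-256 per artefact and contains no timestamps, so a rerun with the same
config is byte-identical; per-stage timings go to the log only. All
randomness flows from the single config seed through
`numpy.random.default_rng` with per-stage stream keys.

## Benchmark problem sizes

The calibration benchmark uses 200 null genes, 2000 permutations and
280 samples (the two-cohort design); effect recovery uses 200 replicates per
planted β ∈ {0.25, 0.5, 1} at MAF 0.3; RTC discrimination uses 100 seeded
replicates per scenario at a planted effect of 1.5 SD/allele; MR recovery
uses 500 replicates of 30 instruments. These sizes give Monte-Carlo standard
errors comfortably below the tolerances being checked while keeping the full
benchmark run around a minute.
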