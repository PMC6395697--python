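# Methods

`methylscape` re-implements, as a tested and reusable pipeline, a
multi-layer DNA-methylation analysis comparing fibroblast-like
synoviocytes from rheumatoid arthritis (RA) and osteoarthritis (OA)
patients: whole-genome bisulfite (WGBS) methylome segmentation,
disease-specific regulatory-region calling, single-CpG differential and
variability statistics, integration with mRNA and miRNA expression, and
rare-variant burden testing.  Because the original patient data are
restricted-access, every stage is validated on a synthetic cohort
generator that reproduces the statistical structure the analysis
assumes, with full ground truth.

## Methylome segmentation

**Alpha track.**  For each sample, beta values are posterior-smoothed as
`(meth + 0.5) / (cov + 1)` and a symmetric Beta(α, α) is fitted by
maximum likelihood to every sliding window of 101 consecutive CpGs.  The
score equation for the symmetric Beta reduces to
`ψ(2α) − ψ(α) = −mean(log β + log(1−β)) / 2`, whose left side decreases
monotonically from +∞ to log 2, so the MLE is obtained by vectorized
bisection (60 iterations on log α, α capped at 100).  α < 1 indicates a
polarized (bimodal) methylation landscape; α ≥ 1 the dispersed
intermediate methylation of partially methylated domains (PMDs).  The
estimator agrees with an exhaustive grid-search oracle to |Δα| ≤ 0.01
(tested).

**PMD decoding.**  A two-state Gaussian HMM on log α (hmmlearn, EM with
at most 100 iterations, tolerance 1e-6) is initialized
deterministically: state means are the averages of log α below and above
0 (the polarized/dispersed boundary), start probabilities 0.5/0.5,
sticky transitions 0.99/0.01.  Anchoring the initialization at α = 1
rather than at the sample median matters: hypomethylated regions create
a *low*-α tail that a median split can latch onto, leaving no state for
the dispersed PMD mode.  Decoding is by posterior probability > 0.5, and
a state is accepted as the PMD state only when its mean log α is
positive — so a fully polarized genome yields no PMDs and a fully
dispersed one yields a single PMD, without special-casing the EM.
Consecutive PMD windows are merged; segments with fewer CpGs than the
window size are dropped.

**Hypomethylated-region calling.**  Outside PMDs, betas are smoothed
over 3 consecutive CpGs (moving mean) and maximal runs of at least `n`
CpGs with smoothed beta below `m` become segments.  `(m, n)` is chosen
by permutation FDR on a grid m ∈ {0.30, 0.35, …, 0.70}, n ∈ {4, …, 10}:
the beta values of non-PMD CpGs are permuted genome-wide and
FDR(m, n) = (pooled permuted calls + 1) / (permutations × observed
calls), capped at 1.  Five permutations are pooled rather than one: on a
10⁵-CpG genome the null call count is Poisson-small, and a
single-permutation ratio is noisy enough to move the selected cutoff
between seeds; pooling stabilizes the estimator without touching the
data.  The largest `m` with FDR ≤ 0.05 at the fixed `n` (default 5) is
chosen.  Hypomethylated runs with ≥ 30 CpGs are classified UMR
(unmethylated region, CpG-island-like), smaller ones LMR (low-methylated
region, distal-regulatory-element-like).

**PMD sharing.**  A PMD is *shared* when it overlaps (≥ 1 bp) a PMD of
any sample of the other disease group, *specific* when it appears in
exactly one sample overall and overlaps no other-group PMD.

## Disease-specific LMRs

Per-sample LMRs are merged into consensus regions by single-linkage on
≥ 1 bp overlap; a consensus region is "detected in" a sample iff ≥ 1 bp
of that sample's LMRs overlaps it (the minimum-overlap rule is
configurable).  A region is group-specific when detected in more than
two samples of one group and in none of the other.  Specific LMRs are
profiled as mean beta in 100-bp bins over center ± 1.5 kb per group and
clustered by k-means (default k = 2 — the dominant pattern split is
RA-low vs OA-low — 50 seeded restarts, best inertia kept).  Samples are
clustered on pairwise Jaccard indexes computed on base pairs
(intersection bp / union bp of merged LMR sets; a count-based mode
exists), with average linkage on 1 − J.  Region midpoints are annotated
against gene models with precedence promoter > exon > intron >
intergenic; the promoter is TSS −1000/+100 bp strand-aware, intron
indexes count 5′→3′ on the transcript strand.  Enhancer overlap is
compared between RA- and OA-specific LMRs per cell type as a fraction
ratio with a 1-df Pearson chi-squared test (no continuity correction).

## Single-CpG statistics

**DMCs.**  Per CpG covered ≥ 5× in every retained sample (the coverage
default mirrors the ≥ 5× coverage statistic emphasized for WGBS QC),
a binomial logistic regression of (methylated, unmethylated) counts on
the group indicator is tested by likelihood ratio.  With one binary
covariate the MLE is the pooled per-group proportion, giving a closed
form evaluated vectorized across sites; `xlogy` keeps the deviance
finite under complete separation (flagged).  A CpG is a DMC when
|Δ mean beta| > 0.2 (unweighted per-sample means; a coverage-pooled mode
exists) and p < 0.05/N with N the number of CpGs actually tested.  On
null cohorts the empirical FWER is ≤ 0.05 over 20 replicates; a planted
Δ = 0.3 at 20× coverage, 6 vs 6, is detected with ≥ 0.9 power (both
tested).

**DVCs.**  Levene's test with group-mean centering (classic Levene;
median-centering Brown–Forsythe exposed) on per-sample betas, F(1, N−2)
reference, Benjamini–Hochberg FDR < 0.05.  Sites with zero within-group
deviations in both groups are skipped.  Known limitation: at sites
saturated near beta 1, the |deviation| distribution is highly discrete
and the F approximation is anticonservative at small n; calibration is
verified on equal-variance intermediate-methylation data at 20 vs 20,
where the nominal level is recovered.

**DMC/DVC overlap.**  One-sided Fisher's exact test on the 2×2 overlap
table (equal to the hypergeometric upper tail, tested exactly), plus a
permutation test that redraws one set uniformly from the tested-CpG
universe — the permuted overlap is then exactly hypergeometric and is
sampled directly; p uses the add-one rule, floored at 1/(n_perm+1).

**Classification.**  Feature sets (DMC-only, DVC-only, both) are
compared by leave-one-out nearest-centroid classification on beta
values; the balanced error rate (BER) is the mean of the two per-class
error rates.  Nearest centroid was chosen for determinism and zero
tuning.  BER distributions come from 100 seeded bootstrap resamples of
the features; the significance of a BER difference from 999 label
permutations.

## Expression and miRNA integration

Genes are ranked by signal-to-noise ratio (Δ group means over the sum
of group SDs, each SD floored at 0.2 |mean|).  The LMR-target set
contains genes overlapped by a specific LMR or whose TSS lies within
5 kb downstream (strand-aware) of one.  Enrichment uses the weighted
Kolmogorov–Smirnov running sum (weight exponent 1); ES is the signed
maximum deviation, the null is gene-label permutation (999, seeded), the
normalized ES divides by the mean same-sign permutation |ES|, and the
FDR q is the same-sign permutation exceedance fraction.  The running
sum matches an independent brute-force implementation to 1e-12
(tested).  Individual LMR–gene pairs (nearest TSS, ties to the smaller
start) are screened by Pearson r with sample-permutation p
(|r| > 0.5, p < 0.05).

miRNA differential expression is a documented simplification of the
classic DESeq procedure: median-of-ratios size factors, pooled
method-of-moments dispersion per miRNA, and an exact-style test that
sums the joint NB probabilities of all group-sum splits at least as
unlikely as the observed one.  Fold change is computed on size-factor-
normalized counts (composition shifts compress per-million fold
changes when many miRNAs move together).  A DEmiR needs fold change
> 2 in either direction, unadjusted p < 0.05, and nonzero counts in at
least 50% of samples ("expressed" = nonzero raw count).  For each
DEmiR, every CpG in the gene body or ≤ 5 kb strand-aware upstream is
screened by Spearman rho (average ranks) against normalized expression
with shared sample permutations (|rho| > 0.5, p < 0.05); predicted
miRNA–target mRNA pairs are retained on negative rho with permutation
p < 0.05.

## Rare variants

Candidate genes carry variants in ≥ 2 RA samples and no OA sample
("at least two" follows the concrete finding; the stricter "more than
two" reading is a flag).  Mutation excess per gene uses the de novo
expectation λ = 2·N·μ (diploid copies; per-consequence-class μ columns
are supported) with the upper Poisson tail P(X ≥ observed), significant
below the conservative 1e-8 threshold; the tail matches a term-by-term
series to 1e-12 (tested).  Independence of variant burden from
methylation is checked by point-biserial correlation between carrier
status and mean gene-body beta with a two-sided permutation p.

## Synthetic cohort generator

One synthetic chromosome; CpG spacings i.i.d. geometric with mean
100 bp.  Default study conditions: 3 RA vs 3 OA samples, 10⁵ CpGs,
coverage Poisson(22) truncated ≥ 1 (zero-coverage CpGs carry no
information), methylated counts Binomial(cov, β).  All randomness flows
from one seed through fixed-purpose substreams, so every output is
byte-reproducible.

Emission model: background CpGs carry a high mode Beta(20, 2) with 5%
scattered unmethylated CpGs Beta(2, 20); UMRs (40 CpGs) emit
Beta(2, 38) (mean ≈ 0.05); LMRs (10 CpGs) emit Beta(μκ, (1−μ)κ) with
region mean μ ~ U(0.15, 0.35) and κ = 50; PMDs (1500 CpGs) emit
dispersed Beta(1.5, 1.5) independently per sample.  The scattered-low
fraction is kept at 5% deliberately: low-methylation CpGs in real
genomes cluster into islands and valleys (planted here explicitly as
UMRs/LMRs), and an i.i.d. high-low mixture with a large low fraction
would seed spurious hypomethylated runs that no caller could separate
from true LMRs.  Group-specific regions are hypomethylated only in
carrier samples of the target group (penetrance 1.0 by default).

Planted single-CpG effects: DMCs shift one group from an unmethylated
baseline (β ≈ 0.03) by Δ = 0.3, alternating hyper/hypo; DVCs hold both
group means at 0.5 with a planted across-sample variance ratio of 100
(at 22× coverage the binomial noise floor, sd ≈ 0.11 at β = 0.5,
compresses observable ratios, so smaller planted ratios are invisible
to Levene at these sample sizes).

Couplings: each coupled gene sits 1–4 kb downstream of an RA-specific
LMR and its log2 intensity is linear in the region's per-sample mean
methylation (slope −4, Gaussian noise sd 0.25); coupled miRNAs sit at
the downstream end of dedicated broad (65-CpG) RA-specific
hypomethylated regions so that the tested window (gene body + 5 kb
upstream) lies almost entirely inside the truly coupled region, and
their NB means scale as 2^(−3·(β − 0.5)); library-size factors vary at
most two-fold; dispersion 0.05.  Variant counts are Poisson(2μ) per
gene and sample (μ = 1e-5) with planted excess genes inflated 2·10⁵-fold
in RA only (per-sample rate 4, so excess genes reliably recur in ≥ 2 RA
samples).

What the generator does **not** emulate — and hence what passing tests
do not show about real data: sequence context and CpG islands as
sequence features, cell-type heterogeneity within a biopsy, batch and
conversion-efficiency artifacts, correlated (read-level) methylation
noise, realistic gene structure/expression distributions, and
linkage/population structure in variants.  Recovery rates measured here
are upper bounds relative to patient data.

## Problem sizes and runtime

The validation suite runs segmentation on 6 × 10⁵ CpGs (a few seconds
per sample), DMC calibration on 20 replicate 2000-CpG null cohorts,
power on a 10⁴-CpG universe, and miRNA integration on a 10 vs 7 cohort
with 2 × 10⁴ CpGs — sizes chosen so the full suite and the acceptance
script each complete in well under a minute per block on one CPU while
keeping every statistical check adequately powered.

## Numerical conventions

Coordinates are 0-based half-open everywhere; Bismark coverage input is
1-based and shifted on read; chromosome names are taken verbatim.
Permutation p values always use the add-one rule.  Ties in top-variable
CpG selection break by genomic order; k-means degeneracies (duplicate
rows) resolve to the lowest-index centroid; interval merging requires a
shared base (abutting intervals stay separate).
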