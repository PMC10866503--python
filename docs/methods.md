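# Methods

`parevol` implements an end-to-end analysis of parallel adaptive
gene-expression evolution: how much of the expression divergence between an
evolved and an ancestral lineage is cis- versus trans-regulated, how that
relates to tissue specificity, and whether the same genes carry signatures
of positive selection in wild populations. Every stage runs on synthetic
data with known ground truth, so the whole pipeline is testable without any
external download.

## Regulatory-mode classification (P/H/T trio)

In an F1 hybrid the two parental alleles are exposed to one shared cellular
environment, so trans-acting differences affect both alleles equally and
cancel from the allelic ratio, while cis-acting differences do not. Three
tests per gene formalize this:

* **P** — negative-binomial Wald test of differential expression between the
  parental strains;
* **H** — the same Wald test between the two allele pools of the F1 hybrids,
  with a paired design (both pools of one individual share a size factor
  equal to half the individual's total, normalized to unit geometric mean),
  so allelic imbalance is tested within individuals;
* **T** — a likelihood-ratio test of the generation x strain-of-origin
  interaction in the combined NB model over parents and F1 pools (1 df):
  a significant interaction means the F1 allelic ratio does not recapitulate
  the parental ratio, i.e. a trans effect.

Significance at FDR 5% (Benjamini-Hochberg within each test family) maps
each gene to one of seven categories:

| P | H | T | category |
|---|---|---|----------|
| + | + | − | cis-only |
| + | − | + | trans-only |
| + | + | + | cis + trans (P and H directions agree) |
| + | + | + | cis x trans (directions differ) |
| − | + | + | compensatory |
| − | − | − | conserved |
| any other pattern | | | ambiguous |

Direction is the sign of the log2 fold change with a dead zone of 1e-8
mapped to "no direction"; an all-significant gene with a zero direction
resolves to cis + trans deterministically.

### NB model and small-sample calibration

Counts are modeled NB with Var = mu + alpha mu^2. Size factors are
median-of-ratios (geometric-mean reference over everywhere-positive genes,
falling back to total-count scaling). Dispersion is a per-gene
method-of-moments estimate on normalized counts, pooled over replicate
groups, floored at 1e-8, with no shrinkage toward a trend — a deliberate
simplification that keeps the estimator transparent and testable; the
acceptance standard is parameter recovery on simulations, not replication of
any particular DE tool's internals. Models are fit by Fisher-scoring IRLS
vectorized across genes; the Wald statistic is beta/SE from the inverse
Fisher information.

With ~6 replicates per group and a plug-in dispersion, the asymptotic
normal reference for the Wald statistic rejects at ~8% for a nominal 5%
(we measured 7.0–8.4% across the three test families on a 3,000-gene null
simulation — essentially the normal-vs-t(10) discrepancy). The default
reference is therefore Student-t with residual degrees of freedom
(samples − parameters) for Wald tests and F(1, residual df) for the LRT,
which restores 4.9–5.6% empirical size under the null. The asymptotic
references remain available (`small_sample=False`).

Genes with zero counts everywhere get NaN p-values and are excluded from
the BH denominator. A gene expressed in only one group converges to a
clipped linear predictor; its enormous Wald SE makes the test conservative
rather than anti-conservative there.

## ASE-informative SNPs

A SNP informs allele-specific expression when the parent strains are fixed
for opposite alleles (call rate >= 85% per parent group among called
genotypes, one group all hom-ref, the other all hom-alt) and every F1
individual is called heterozygous. The phasing table records which parent
carries the reference allele; SNP-level allelic read counts are summed over
a gene's informative SNPs into per-individual, per-parental-origin pools.
A SNP inside two overlapping genes is assigned to the smaller interval
(deterministic, and rare in synthetic data). Genes without informative SNPs
are untestable and absent from the trio results.

The mapping-bias diagnostic reports, per F1 individual, the fraction of
reads from a designated pool (reference-allele pools in the analysis
scripts, where per-gene alternating phase cancels biological imbalance)
with a one-sample t-test against 0.5.

## Tissue specificity

Expression is normalized to RPKM, 1e9 * count / (length * effective library
size), with TMM scaling factors (trim 30% on M, 5% on A,
precision-weighted, unit geometric mean; reference sample chosen by the
upper-quartile-closest-to-mean rule). Specificity uses tau =
sum_i (1 − x_i/x_max) / (n − 1) on linear values (a log2(x+1) option
exists but is off by default, matching the index's original formulation).

A gene is tissue-specific at tau > 0.85 with the peak in that tissue, and
broad at tau < 0.35 — both strict inequalities, so boundary values are
intermediate. Because the liver appears in both the locally profiled and
the published-style reference data, tau is computed twice (swapping the
liver column) and liver-specific calls require agreement of both
calculations; the broad call uses the calculation with the local liver
(the choice was open; it is the calculation every gene is guaranteed to
have). The Pearson correlation between the two liver columns is reported
as a diagnostic, not used as a gate.

## Selection scan (PBSn1)

Per-SNP pairwise Weir & Cockerham (1984) theta-hat is computed from allele
counts, with heterozygote frequencies at Hardy-Weinberg expectation when
only allele counts are available (observed heterozygosity is used when
genotypes are supplied). SNPs pass QC at pooled call rate >= 80%
(per-population mode available) and pooled minor allele frequency >= 5%
(strictly smaller frequencies excluded).

Within non-overlapping blocks of 5 consecutive same-chromosome SNPs
(trailing remainders dropped; blocks never span chromosomes), per-SNP FST
is averaged per population pair (NaN SNPs skipped, count recorded) and
transformed to branch lengths T = −ln(1 − FST) — natural log, the
literature's convention; the base only rescales PBSn1 monotonically.
Negative FST clamps to 0 and FST = 1 to 1 − 1e−9 to keep T finite. Then
PBS1 = (T12 + T13 − T23)/2 with the focal population as 1 (PBS2, PBS3 by
rotation) and PBSn1 = PBS1/(1 + PBS1 + PBS2 + PBS3). Averaging FST per SNP
then per block (rather than a ratio-of-averages across the block) was an
open choice; it follows the block-scan formulation this statistic comes
from.

Outliers are blocks at or above the empirical (1 − f) quantile of PBSn1
(type-7 linear interpolation; ties at the cutoff included), annotated with
the closest gene (0-based half-open interval arithmetic, SNP position p
occupying [p−1, p); distance 0 on overlap; ties broken by leftmost gene
start). The nested design repeats the scan with the focal lineage's sister
population as an outgroup: outlier genes retained across both scans
indicate lineage-specific selection rather than shared ancestry, and the
retention fraction |primary ∩ nested| / |primary| quantifies it.

## Permutation enrichment

The null for "is this overlap larger than chance" draws two independent
uniform subsets of the observed sizes from the background universe
(10,000 iterations by default) and records their intersection. The
intersection of two independent uniform subsets is exactly hypergeometric
(condition on either set), so `hypergeom_overlap_moments` is an exact
oracle for the null mean and variance, used in cross-checks at 3
Monte-Carlo standard errors. Tail p-values carry an add-one correction,
p = (k + 1)/(m + 1), never exactly zero; observations outside the whole
null distribution are reported at the floor with a flag (the "p = ~0"
convention). Fold enrichment is observed / null mean. Under-enrichment
(e.g. broadly expressed genes depleted of DEGs) requires opting into the
"less" alternative. The comparison of shared proportions between cis- and
trans-regulated genes is a pooled 2x2 chi-square (pooling across
comparisons was an open choice; the per-comparison counts are also
available from the suite output).

## Synthetic data

The generator defines the study conditions. Defaults: baseline mean 500
counts, NB dispersion 0.05, 6 replicates per group, cis and trans effects
|log2fc| = 2 with random signs, library sizes log-normal (sigma 0.15)
around 1 with both pools of one F1 sharing the individual's factor.
Effects split symmetrically across strains (strain A gets 2^(+e/2), B gets
2^(−e/2)) so that random effect signs keep total read flow balanced —
otherwise the mapping-bias diagnostic would flag the asymmetry of the
generator itself. Per regulatory mode, (cis c, trans t) are: cis-only
(c, 0); trans-only (0, t); cis+trans (same sign); cis x trans (t opposing
and exceeding c, so parental and allelic divergence point opposite ways);
compensatory (t = −c, parental means equal); conserved (0, 0).

Tissue profiles place a stated fraction of genes in exactly one tissue
(true tau 1), a stated fraction uniform (true tau 0; by default all
non-specific genes, so that the two boundary settings are pure), and any
remainder on a geometric-decay profile with analytically known tau, noise
free. The published-style dataset is emulated by a second liver column
with multiplicative log-normal noise (sigma 0.2).

Populations drift from a shared ancestral frequency p0 ~ Uniform(0.05,
0.95) by additive Gaussian noise with sd drift_scale * p0(1−p0), clamped to
[0, 1]; planted sweeps displace the focal population (optionally also named
others, to model selection predating a split) proportionally toward
fixation of its major allele; diploid sample counts are binomial. This is
a moment-matched caricature, not a coalescent: it gives tunable FST with no
linkage, no site-frequency-spectrum realism, and no migration, which is
sufficient for validating the scan's ranking behavior but says nothing
about demographic robustness on real data. Similarly, the expression
generator has no GC/length biases, no outlier samples and no correlated
genes, so passing tests demonstrate correctness of the estimators under
the stated model, not robustness to real-data artifacts.

Sizes used by the committed analyses: 1,000 genes for the narrative
scripts; 2,000 genes (6+6 replicates) for regulatory-mode recovery; 10,000
SNPs / 2,000 genes / 50 sweeps for sweep detection; these keep every run
in seconds to a few minutes on one core while leaving estimator noise well
below the acceptance margins.

## Reproducibility

Every stochastic component takes a seed; the pipeline derives per-stage
seeds deterministically from one global seed via `SeedSequence`, and the
run manifest records config hash, per-output checksums and timings, so a
re-run with the same seed is checksum-identical. Stage handoffs inside
`run_all` are in-memory for speed, but each stage also writes its full
output table, and each analysis script re-reads only files, so every stage
is reproducible in isolation from its inputs on disk.

## Known limitations

* Dispersion is per-gene method-of-moments with no information sharing;
  at very low counts or 2–3 replicates the t-referenced Wald test loses
  power relative to shrinkage-based tools (it stays calibrated, not
  optimal).
* The trans LRT fixes the dispersion at its method-of-moments value in
  both models rather than profiling it.
* WC FST from allele counts assumes within-population Hardy-Weinberg for
  heterozygosity; inbred populations bias the estimate (supply observed
  heterozygosity to avoid this).
* `closest_gene` is exact but O(genes-per-chromosome) per block; fine at
  this scale, an interval tree would be the next step for genome-scale
  annotations.
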