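# parevol

Analysis pipeline for **parallel adaptive gene-expression evolution**: when
two lineages independently adapt to similar environments, how much of their
expression divergence is shared, is it driven by *cis*- or *trans*-acting
regulatory changes, how does it relate to tissue specificity, and do the
same genes show allele-frequency signatures of positive selection in wild
populations?

It is written for evolutionary geneticists working with a classic design:
bulk RNA-seq of two parental strains plus their F1 hybrids (allele-specific
expression), multi-tissue expression references, and population-level SNP
data for a focal population with outgroups. Every stage also runs on a
built-in synthetic-data generator with known ground truth, so the full
pipeline is testable end to end without any external data.

## What it computes

* **Differential expression** — NB Wald tests between strains
  (median-of-ratios normalization, per-gene method-of-moments dispersion,
  BH/FDR 5%), with a split-reference control against spurious fold-change
  correlations.
* **Regulatory modes** — the three hierarchical tests per gene:
  *P* (parents), *H* (F1 allele pools, paired within individuals), and
  *T* (LRT on the generation x strain-of-origin interaction — does the
  allelic ratio recapitulate the parental ratio?), classified into
  cis-only, trans-only, cis+trans, cis x trans, compensatory, conserved,
  or ambiguous.
* **Tissue specificity** — TMM/RPKM normalization and
  tau = Σᵢ(1 − xᵢ/x_max)/(n − 1), with tissue-specific calls at tau > 0.85
  (agreeing in both liver calculations) and broad calls at tau < 0.35.
* **Selection scans** — per-SNP Weir–Cockerham F_ST, branch lengths
  T = −ln(1 − F_ST), PBS = (T₁₂ + T₁₃ − T₂₃)/2 and
  PBSn1 = PBS₁/(1 + PBS₁ + PBS₂ + PBS₃) in non-overlapping 5-SNP blocks,
  top-tail outliers with closest-gene annotation, and nested-outgroup
  retention to separate lineage-specific selection from shared ancestry.
* **Permutation enrichment** — observed gene-set overlaps against a
  10,000-iteration random-subsets null, with add-one p-values ("p = ~0"
  floor flag) and fold = observed / null mean; exact hypergeometric
  moments as the analytic cross-check.

## Worked example

The numbered scripts under `analysis/` run the whole study on synthetic
data (seed 20, 1,000 genes), writing tables under `results/`:

```sh
python analysis/01_simulate.py
python analysis/02_differential_expression.py
python analysis/03_regulatory_modes.py
python analysis/04_tissue_specificity.py
python analysis/05_selection_scan.py
python analysis/06_enrichment.py
```

Step 03 prints, for example:

```
2000 ASE-informative SNPs of 2196 called
1000 genes testable for ASE
category
conserved          528
trans_only         151
cis_only           148
cis_plus_trans      53
cis_times_trans     51
compensatory        50
ambiguous           19
agreement with simulated truth: 97.4%
mapping bias check: mean reference-allele fraction 0.500, p = 0.609
```

i.e. the P/H/T classifier recovers 97% of the generator's planted
regulatory modes, and the reference-allele read fraction across F1s sits at
0.500 — no mapping bias, as the generator constructs. Step 05 reports that
6 of the 10 top-1% PBSn1 outlier genes are planted sweeps (uniform
expectation 0.5), and step 06 that the two split-reference DEG sets overlap
2.4-fold more than chance (p at the permutation floor) while the
desk-scale DEG overlaps reproduce fold enrichments of 1.68 (liver) and
1.72 (BAT).

The same stages are available as a CLI (`parevol simulate|de|ase|tau|scan|
enrich|run-all`) and as one call:

```python
from parevol import RunConfig, run_all
manifest = run_all(RunConfig(outdir="run", seed=0))
```

## Layout

```
src/parevol/        library: simulate, diffexpr, ase, tau, pbs,
                    enrichment, stats, nbglm, io, pipeline, cli
analysis/           numbered narrative drivers (synthetic study)
tests/              pytest suite incl. acceptance properties
scripts/            acceptance.py
docs/methods.md     models, assumptions, numerical choices, limitations
```
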