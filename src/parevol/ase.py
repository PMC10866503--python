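"""Allele-specific expression and cis/trans regulatory-mode classification.

In an F1 hybrid the two parental alleles share one cellular (trans) milieu,
so any allelic expression imbalance must be cis-acting, while divergence
between the parental strains reflects cis and trans effects combined.  Three
hierarchical NB tests per gene exploit this:

* P — differential expression between the parental strains (Wald),
* H — differential expression between the two allele pools of the F1
  hybrids (Wald, paired within individuals),
* T — a likelihood-ratio test for a trans effect: does the parental
  expression ratio differ from the F1 allelic ratio? (generation x
  strain-of-origin interaction, 1 df, F reference with residual df for
  small-sample calibration).

Significance patterns at an FDR threshold map each gene onto one of seven
regulatory categories: cis-only, trans-only, cis+trans, cis*trans,
compensatory, conserved, or ambiguous.

The module also selects ASE-informative SNPs (fixed-and-different between
parents, heterozygous in every F1), aggregates SNP-level allelic read counts
to gene level, and provides the mapping-bias diagnostic and the cis-vs-trans
effect-size comparison.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import nbglm
from .diffexpr import LOG2, CountMatrix, nb_wald
from .stats import TestResult, bh_adjust, welch_t

CATEGORIES = (
    "cis_only",
    "trans_only",
    "cis_plus_trans",
    "cis_times_trans",
    "compensatory",
    "conserved",
    "ambiguous",
)

# genotype codes
HOM_REF, HET, HOM_ALT, MISSING = 0, 1, 2, -1

DIRECTION_DEAD_ZONE = 1e-8


@dataclass
class GenotypeMatrix:
    """Biallelic SNP genotypes for a panel of samples.

    ``snps`` has columns chrom, pos (1-based), ref, alt; ``genotypes`` is an
    integer matrix (SNPs x samples) coded 0 = hom-ref, 1 = het, 2 = hom-alt,
    -1 = missing; ``sample_groups`` maps sample id to its group (a parental
    strain name or 'F1').
    """

    snps: pd.DataFrame
    genotypes: pd.DataFrame
    sample_groups: pd.Series

    def __post_init__(self) -> None:
        if len(self.snps) != len(self.genotypes):
            raise ValueError("snps and genotypes row counts differ")
        if not self.genotypes.columns.equals(self.sample_groups.index):
            raise ValueError("sample_groups index must match genotype columns")
        dup = self.snps.duplicated(subset=["chrom", "pos"])
        if dup.any():
            raise ValueError("duplicate SNP positions within a chromosome")

    def subset_samples(self, sample_ids) -> "GenotypeMatrix":
        return GenotypeMatrix(
            self.snps, self.genotypes[list(sample_ids)],
            self.sample_groups.loc[list(sample_ids)],
        )


def select_informative_snps(
    genotypes: GenotypeMatrix,
    parent_a: str,
    parent_b: str,
    parent_call_rate: float = 0.85,
) -> pd.DataFrame:
    """ASE-informative SNPs: fixed-and-different in parents, het in every F1.

    A SNP is retained when (a) each parent group has a call rate of at least
    ``parent_call_rate``, (b) among called genotypes one parent group is
    fixed hom-ref and the other fixed hom-alt, and (c) every F1 individual
    is called and heterozygous.

    Returns the phasing table: one row per informative SNP with columns
    chrom, pos, ref, alt, ref_parent, alt_parent (which parent strain
    carries the reference allele).
    """
    g = genotypes.genotypes.to_numpy()
    groups = genotypes.sample_groups.to_numpy()
    masks = {name: groups == name for name in (parent_a, parent_b)}
    f1_mask = groups == "F1"
    if f1_mask.sum() == 0:
        raise ValueError("no F1 samples in genotype matrix")

    def group_state(mask):
        sub = g[:, mask]
        called = sub != MISSING
        rate = called.mean(axis=1)
        all_ref = np.all((sub == HOM_REF) | ~called, axis=1) & (called.sum(axis=1) > 0)
        all_alt = np.all((sub == HOM_ALT) | ~called, axis=1) & (called.sum(axis=1) > 0)
        return rate, all_ref, all_alt

    rate_a, aref, aalt = group_state(masks[parent_a])
    rate_b, bref, balt = group_state(masks[parent_b])
    f1 = g[:, f1_mask]
    f1_all_het = np.all(f1 == HET, axis=1)

    fixed_diff = (aref & balt) | (aalt & bref)
    keep = (
        (rate_a >= parent_call_rate)
        & (rate_b >= parent_call_rate)
        & fixed_diff
        & f1_all_het
    )
    if not keep.any():
        warnings.warn("no ASE-informative SNPs survive filtering")
    out = genotypes.snps.loc[keep, ["chrom", "pos", "ref", "alt"]].copy()
    out["ref_parent"] = np.where(aref[keep], parent_a, parent_b)
    out["alt_parent"] = np.where(aref[keep], parent_b, parent_a)
    return out.reset_index(drop=True)


def _locate_gene(chrom: str, pos: int, annotation: pd.DataFrame) -> str | None:
    """Gene containing the 1-based SNP position; smallest interval on overlap."""
    sub = annotation[annotation["chrom"] == chrom]
    # SNP at 1-based pos occupies [pos-1, pos) in BED coordinates
    hit = sub[(sub["start"] <= pos - 1) & (pos - 1 < sub["end"])]
    if hit.empty:
        return None
    if len(hit) > 1:
        warnings.warn(f"SNP {chrom}:{pos} overlaps {len(hit)} genes; smallest kept")
        hit = hit.assign(_len=hit["end"] - hit["start"]).sort_values(
            ["_len", "start"]
        )
    return str(hit.iloc[0]["gene_id"])


def allele_counts_per_gene(
    snp_allele_counts: pd.DataFrame,
    informative: pd.DataFrame,
    annotation: pd.DataFrame,
) -> CountMatrix:
    """Aggregate SNP-level allelic read counts to per-gene, per-parent pools.

    ``snp_allele_counts`` is long-format with columns chrom, pos, individual,
    ref_reads, alt_reads (one row per informative SNP per F1 individual).
    Reads are assigned a parental origin from the phasing table and summed
    over a gene's informative SNPs. Genes without informative SNPs are absent
    from the result (untestable).

    Returns a CountMatrix with one sample per (individual, parental allele),
    sample ids ``{individual}|{parent}``, metadata generation='F1'.
    """
    inf = informative.merge(
        snp_allele_counts, on=["chrom", "pos"], how="inner", validate="1:m"
    )
    if inf.empty:
        raise ValueError("no overlap between informative SNPs and allele counts")
    keymap = {
        (c, p): _locate_gene(c, p, annotation)
        for c, p in inf[["chrom", "pos"]].drop_duplicates().itertuples(index=False)
    }
    inf["gene_id"] = [keymap[(c, p)] for c, p in zip(inf["chrom"], inf["pos"])]
    inf = inf.dropna(subset=["gene_id"])

    rows = []
    for (gene, indiv), grp in inf.groupby(["gene_id", "individual"], sort=True):
        for parent_col, reads_col in (("ref_parent", "ref_reads"),
                                      ("alt_parent", "alt_reads")):
            for parent, sub in grp.groupby(parent_col):
                rows.append((gene, f"{indiv}|{parent}", int(sub[reads_col].sum())))
    long = pd.DataFrame(rows, columns=["gene_id", "sample", "reads"])
    counts = (
        long.pivot_table(index="gene_id", columns="sample", values="reads",
                         aggfunc="sum", fill_value=0)
        .astype(int)
    )
    counts.columns.name = None
    meta = pd.DataFrame(index=counts.columns)
    meta["individual"] = [s.split("|")[0] for s in counts.columns]
    meta["allele_of_origin"] = [s.split("|")[1] for s in counts.columns]
    meta["strain"] = meta["allele_of_origin"]
    meta["generation"] = "F1"
    return CountMatrix(counts, meta)


def paired_size_factors(f1_cm: CountMatrix) -> np.ndarray:
    """Per-individual size factors shared by an F1's two allele pools.

    The two pools of one hybrid come from a single library, so allelic
    imbalance is tested within individuals: both pools get the factor
    (individual total / 2) scaled to unit geometric mean.
    """
    totals = f1_cm.counts.sum(axis=0)
    indiv = f1_cm.sample_meta["individual"]
    per_indiv = totals.groupby(indiv).sum() / 2.0
    sf = indiv.map(per_indiv).to_numpy(dtype=float)
    return sf / np.exp(np.mean(np.log(sf)))


def trio_tests(
    parental_cm: CountMatrix,
    f1_allele_cm: CountMatrix,
    contrast: tuple[str, str],
    min_mean: float = 10.0,
) -> pd.DataFrame:
    """Run the P, H and T tests for every testable gene.

    Genes are testable when present in both matrices (i.e. they carry
    informative SNPs) with mean count strictly greater than ``min_mean``
    across all samples pooled. BH adjustment runs within each test family
    over all genes with a finite p-value.

    Returns a DataFrame indexed by gene id with columns P_log2fc, P_pvalue,
    P_padj, H_log2fc, H_pvalue, H_padj, T_stat, T_pvalue, T_padj.
    """
    strain_a, strain_b = contrast
    shared = parental_cm.gene_ids.intersection(f1_allele_cm.gene_ids)
    par = parental_cm.subset_genes(shared)
    hyb = f1_allele_cm.subset_genes(shared)
    pooled_mean = np.concatenate(
        [par.counts.to_numpy(), hyb.counts.to_numpy()], axis=1
    ).mean(axis=1)
    testable = shared[pooled_mean > min_mean]
    par = par.subset_genes(testable)
    hyb = hyb.subset_genes(testable)

    res = pd.DataFrame(index=testable)
    # P: parental Wald
    p_res = nb_wald(par, contrast)
    res["P_log2fc"] = p_res["log2FoldChange"]
    res["P_pvalue"] = p_res["pvalue"]
    # H: F1 allelic Wald with paired per-individual offsets
    sf_h = paired_size_factors(hyb)
    h_res = nb_wald(
        hyb, contrast, size_factors=sf_h,
        groups=hyb.sample_meta["allele_of_origin"].to_numpy(),
    )
    res["H_log2fc"] = h_res["log2FoldChange"]
    res["H_pvalue"] = h_res["pvalue"]
    # T: interaction LRT on the combined 2x2 layout
    t_stat, t_p = _trans_lrt(par, hyb, contrast, sf_h)
    res["T_stat"] = t_stat
    res["T_pvalue"] = t_p
    for fam in ("P", "H", "T"):
        res[f"{fam}_padj"] = bh_adjust(res[f"{fam}_pvalue"].to_numpy())
    return res[
        ["P_log2fc", "P_pvalue", "P_padj", "H_log2fc", "H_pvalue", "H_padj",
         "T_stat", "T_pvalue", "T_padj"]
    ]


def _trans_lrt(par: CountMatrix, hyb: CountMatrix, contrast, sf_hyb):
    """LRT comparing parental vs F1-allelic expression ratios (df = 1).

    Full model: log mu = b0 + b1*strain + b2*generation + b3*strain:generation
    with sample offsets; the interaction b3 is the log ratio-of-ratios, i.e.
    the trans effect. The reduced model drops it.
    """
    strain_a, _ = contrast
    k = np.concatenate([par.counts.to_numpy(), hyb.counts.to_numpy()], axis=1)
    sf = np.concatenate(
        [nbglm.size_factors_median_of_ratios(par.counts.to_numpy()), sf_hyb]
    )
    strain = np.concatenate(
        [par.sample_meta["strain"].to_numpy(),
         hyb.sample_meta["allele_of_origin"].to_numpy()]
    )
    gen = np.concatenate(
        [np.zeros(par.counts.shape[1]), np.ones(hyb.counts.shape[1])]
    )
    is_a = (strain == strain_a).astype(float)
    cells = np.char.add(np.where(is_a > 0, "A", "B"), gen.astype(int).astype(str))
    alpha = nbglm.mom_dispersion(k, sf, cells)
    x_full = np.column_stack([np.ones_like(gen), is_a, gen, is_a * gen])
    x_red = x_full[:, :3]
    _, _, llf_full, _ = nbglm.fit_nb_glm(k, x_full, sf, alpha)
    _, _, llf_red, _ = nbglm.fit_nb_glm(k, x_red, sf, alpha)
    return nbglm.lr_test(llf_full, llf_red, df=1,
                         resid_df=k.shape[1] - x_full.shape[1])


def _direction(log2fc: float) -> int:
    if not np.isfinite(log2fc) or abs(log2fc) < DIRECTION_DEAD_ZONE:
        return 0
    return 1 if log2fc > 0 else -1


def classify_regulatory(trio: pd.DataFrame, fdr: float = 0.05) -> pd.Series:
    """Map each gene's (P, H, T) significance pattern to a regulatory category.

    Decision table at the given FDR on the adjusted p-values::

        P  H  T   category
        +  +  -   cis_only
        +  -  +   trans_only
        +  +  +   cis_plus_trans  (directions of P and H agree)
        +  +  +   cis_times_trans (directions differ)
        -  +  +   compensatory
        -  -  -   conserved
        (any other pattern, or missing tests)  ambiguous

    A zero direction (|log2fc| below the dead zone) counts as agreeing, so
    all-significant ties resolve to cis_plus_trans deterministically.
    """
    cats = []
    for _, row in trio.iterrows():
        ps = (row["P_padj"], row["H_padj"], row["T_padj"])
        if any(not np.isfinite(p) for p in ps):
            cats.append("ambiguous")
            continue
        sp, sh, st = (p < fdr for p in ps)
        if sp and sh and not st:
            cat = "cis_only"
        elif sp and not sh and st:
            cat = "trans_only"
        elif sp and sh and st:
            dp, dh = _direction(row["P_log2fc"]), _direction(row["H_log2fc"])
            same = dp == dh or dp == 0 or dh == 0
            cat = "cis_plus_trans" if same else "cis_times_trans"
        elif not sp and sh and st:
            cat = "compensatory"
        elif not sp and not sh and not st:
            cat = "conserved"
        else:
            cat = "ambiguous"
        cats.append(cat)
    return pd.Series(pd.Categorical(cats, categories=CATEGORIES),
                     index=trio.index, name="category")


def mapping_bias_check(f1_allele_cm: CountMatrix, ref_parent: str):
    """Per-individual reference-allele read fraction and a t-test against 0.5.

    Balanced mapping of the two parental alleles gives per-individual ratios
    centred on 0.5; a systematic departure indicates reference mapping bias.

    Returns (per-individual ratio Series, TestResult vs 0.5).
    """
    meta = f1_allele_cm.sample_meta
    totals = f1_allele_cm.counts.sum(axis=0)
    ratios = {}
    for indiv, grp in meta.groupby("individual"):
        tot = totals[grp.index].sum()
        if tot == 0:
            continue
        ref_ids = grp.index[grp["allele_of_origin"] == ref_parent]
        ratios[indiv] = float(totals[ref_ids].sum() / tot)
    ratio = pd.Series(ratios, name="ref_fraction")
    arr = ratio.to_numpy()
    if len(arr) >= 2 and np.ptp(arr) > 0:
        from scipy import stats as sps

        t, p = sps.ttest_1samp(arr, 0.5)
        df = len(arr) - 1
        result = TestResult(float(t), float(df), float(p))
    else:
        result = TestResult(0.0, max(len(arr) - 1, 1), 1.0)
    return ratio, result


def effect_size_compare(
    calls: pd.Series, de: pd.DataFrame, group_a: str, group_b: str
) -> TestResult:
    """Welch t-test of parental |log2fc| between two regulatory categories."""
    for g in (group_a, group_b):
        if (calls == g).sum() < 2:
            raise ValueError(f"category {g!r} has fewer than 2 genes")
    shared = calls.index.intersection(de.index)
    calls = calls.loc[shared]
    mags = de.loc[shared, "log2FoldChange"].abs()
    x = mags[calls == group_a].dropna().to_numpy()
    y = mags[calls == group_b].dropna().to_numpy()
    return welch_t(x, y)
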