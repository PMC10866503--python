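"""Differential expression between strains from bulk RNA-seq counts.

Provides the count container used across the pipeline, the expressed-gene
filter (mean raw count strictly greater than a threshold), a negative-binomial
Wald test between two strains with median-of-ratios normalization and per-gene
method-of-moments dispersion, DEG calling at an FDR threshold, and the
fold-change parallelism analyses (Spearman correlation plus a reduced major
axis line), including the split-reference control against spurious
shared-denominator correlations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import nbglm
from .stats import bh_adjust, rma_fit, spearman_r

LOG2 = np.log(2.0)

DE_COLUMNS = ["baseMean", "log2FoldChange", "lfcSE", "pvalue", "padj"]


@dataclass
class CountMatrix:
    """Gene x sample integer counts with per-sample metadata.

    ``counts`` is a genes-by-samples DataFrame; ``sample_meta`` is indexed by
    sample id with columns ``strain``, ``generation`` ('parent' or 'F1'),
    ``allele_of_origin`` (strain name or None), ``tissue``, and optionally
    ``individual`` for pairing the two allele pools of one F1.
    """

    counts: pd.DataFrame
    sample_meta: pd.DataFrame = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.sample_meta is None:
            self.sample_meta = pd.DataFrame(index=self.counts.columns)
        if not self.counts.columns.equals(self.sample_meta.index):
            raise ValueError("sample_meta index must match count columns")
        if self.counts.columns.duplicated().any():
            raise ValueError("duplicate sample ids")
        vals = self.counts.to_numpy()
        if np.any(vals < 0) or not np.allclose(vals, np.round(vals)):
            raise ValueError("counts must be nonnegative integers")

    @property
    def gene_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.counts.columns

    def subset_samples(self, mask) -> "CountMatrix":
        cols = self.sample_meta.index[mask]
        return CountMatrix(self.counts[cols], self.sample_meta.loc[cols])

    def subset_genes(self, gene_ids) -> "CountMatrix":
        return CountMatrix(self.counts.loc[gene_ids], self.sample_meta)


@dataclass(frozen=True)
class GeneSet:
    """A named set of unique gene identifiers."""

    name: str
    gene_ids: frozenset

    def __init__(self, name: str, gene_ids) -> None:
        ids = list(gene_ids)
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate gene ids in gene set")
        object.__setattr__(self, "name", name)
        object.__setattr__(self, "gene_ids", frozenset(ids))

    def __len__(self) -> int:
        return len(self.gene_ids)

    def __contains__(self, gid) -> bool:
        return gid in self.gene_ids


def filter_expressed(cm: CountMatrix, min_mean: float = 10.0) -> CountMatrix:
    """Retain genes whose mean raw count across all samples exceeds ``min_mean``.

    The boundary is strict: a gene whose mean equals the threshold is removed.
    Gene order is preserved.
    """
    means = cm.counts.mean(axis=1)
    keep = means > min_mean
    if not keep.any():
        warnings.warn("expression filter removed every gene")
    return CountMatrix(cm.counts.loc[keep], cm.sample_meta)


def nb_wald(
    cm: CountMatrix,
    contrast: tuple[str, str],
    size_factors: np.ndarray | None = None,
    groups: np.ndarray | None = None,
    small_sample: bool = True,
) -> pd.DataFrame:
    """Negative-binomial Wald test of strain A vs strain B.

    Counts are normalized internally with median-of-ratios size factors
    (a precomputed vector may be supplied, e.g. the paired per-individual
    factors of the allele-specific design). Per-gene dispersions come from a
    method-of-moments estimate on normalized counts, floored at 1e-8; the
    Wald statistic is beta/SE from the NB GLM fit. The two-sided reference
    is Student-t with residual degrees of freedom (``small_sample=True``,
    default — calibrated at typical replicate numbers given the plug-in
    dispersion) or asymptotic normal. BH adjustment runs across all genes
    with a finite p-value.

    Returns a DataFrame indexed by gene id with columns baseMean,
    log2FoldChange (A over B), lfcSE, pvalue, padj.
    """
    strain_a, strain_b = contrast
    if groups is None:
        groups = cm.sample_meta["strain"].to_numpy()
    groups = np.asarray(groups)
    sel = np.isin(groups, [strain_a, strain_b])
    if sel.sum() != len(groups):
        cm = cm.subset_samples(sel)
        if size_factors is not None:
            size_factors = np.asarray(size_factors)[sel]
        groups = groups[sel]
    for g in (strain_a, strain_b):
        if (groups == g).sum() < 2:
            raise ValueError(f"need >= 2 replicates in group {g!r}")

    k = cm.counts.to_numpy(dtype=float)
    if size_factors is None:
        size_factors = nbglm.size_factors_median_of_ratios(k)
    size_factors = np.asarray(size_factors, dtype=float)

    testable = k.sum(axis=1) > 0
    res = pd.DataFrame(
        index=cm.gene_ids, columns=DE_COLUMNS, dtype=float
    )
    res["baseMean"] = (k / size_factors).mean(axis=1)
    if testable.any():
        kt = k[testable]
        alpha = nbglm.mom_dispersion(kt, size_factors, groups)
        design = np.column_stack(
            [np.ones(len(groups)), (groups == strain_a).astype(float)]
        )
        beta, cov, _, _ = nbglm.fit_nb_glm(kt, design, size_factors, alpha)
        resid_df = len(groups) - design.shape[1] if small_sample else None
        est, se, _, p = nbglm.wald_test(beta, cov, coef=1, resid_df=resid_df)
        res.loc[testable, "log2FoldChange"] = est / LOG2
        res.loc[testable, "lfcSE"] = se / LOG2
        res.loc[testable, "pvalue"] = p
    res["padj"] = bh_adjust(res["pvalue"].to_numpy())
    return res


def call_degs(results: pd.DataFrame, fdr: float = 0.05, name: str = "DEGs") -> GeneSet:
    """Genes with BH-adjusted p below the FDR threshold."""
    sig = results.index[results["padj"] < fdr]
    return GeneSet(name, list(sig))


def fold_change_parallelism(
    res_a: pd.DataFrame, res_b: pd.DataFrame, subset: GeneSet | None = None
):
    """Spearman correlation and RMA line of log2 fold changes across comparisons.

    Intersects the two result tables on gene id (optionally restricted to a
    gene set) and correlates their log2 fold changes — the parallelism
    measure for two independent evolved-vs-ancestral comparisons.

    Returns (spearman_r, (rma_slope, rma_intercept), n_genes).
    """
    shared = res_a.index.intersection(res_b.index)
    if subset is not None:
        shared = shared.intersection(pd.Index(subset.gene_ids))
    a = res_a.loc[shared, "log2FoldChange"]
    b = res_b.loc[shared, "log2FoldChange"]
    keep = a.notna() & b.notna()
    a, b = a[keep], b[keep]
    if len(a) < 3:
        raise ValueError("fewer than 3 shared genes with fold changes")
    r = spearman_r(a.to_numpy(), b.to_numpy())
    line = rma_fit(a.to_numpy(), b.to_numpy())
    return r, line, int(len(a))


def split_reference_check(
    cm: CountMatrix,
    strain_a: str,
    strain_b: str,
    reference: str,
    seed: int | None = None,
):
    """Parallelism with disjoint reference-strain subsets per comparison.

    Re-runs the two Wald contrasts using non-overlapping halves of the shared
    reference strain's replicates (A vs reference[first half], B vs
    reference[second half]) so the two fold-change vectors share no samples.
    A surviving correlation cannot be an artifact of the common denominator.

    Returns (results_a, results_b, (spearman_r, rma_line, n)).
    """
    meta = cm.sample_meta
    ref_ids = list(meta.index[meta["strain"] == reference])
    if len(ref_ids) < 4:
        raise ValueError("reference strain needs >= 4 replicates to split")
    half = len(ref_ids) // 2
    ref1, ref2 = ref_ids[:half], ref_ids[half:]
    assert not set(ref1) & set(ref2)

    def run(strain: str, refs: list) -> pd.DataFrame:
        ids = list(meta.index[meta["strain"] == strain]) + refs
        sub = cm.subset_samples(meta.index.isin(ids))
        return nb_wald(sub, (strain, reference))

    res_a = run(strain_a, ref1)
    res_b = run(strain_b, ref2)
    return res_a, res_b, fold_change_parallelism(res_a, res_b)
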