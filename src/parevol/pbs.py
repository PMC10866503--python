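"""Population-branch-statistic selection scans over SNP blocks.

From per-population biallelic allele counts: QC filtering (call rate, minor
allele frequency), per-SNP Weir & Cockerham (1984) FST for each population
pair, branch lengths T = -ln(1 - FST), the population branch statistic
PBS = (T12 + T13 - T23)/2 for each population as focal, and its normalized
form PBSn1 = PBS1 / (1 + PBS1 + PBS2 + PBS3), computed in non-overlapping
blocks of consecutive SNPs (default 5).  Outlier blocks in the upper PBSn1
tail are annotated with their closest gene, and a nested-design retention
statistic compares outlier gene sets between a primary and a nested scan
(sister population as outgroup) to separate lineage-specific selection from
shared ancestry.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

POP_COLUMNS = ("chrom", "pos", "ref", "alt")


def snp_qc(
    counts: pd.DataFrame,
    populations: list[str],
    pop_sizes: dict[str, int],
    call_rate: float = 0.80,
    maf: float = 0.05,
    per_population: bool = False,
) -> pd.DataFrame:
    """Filter SNPs on call rate and pooled minor allele frequency.

    ``counts`` carries, per population ``p``, columns ``{p}_n`` (called
    alleles, an even number) and ``{p}_alt``. A SNP is kept when the overall
    call rate is at least ``call_rate`` (per-population with
    ``per_population=True``) and the pooled minor allele frequency is at
    least ``maf`` (strictly smaller frequencies are excluded).
    """
    n_cols = [f"{p}_n" for p in populations]
    alt_cols = [f"{p}_alt" for p in populations]
    n = counts[n_cols].to_numpy(dtype=float)
    alt = counts[alt_cols].to_numpy(dtype=float)
    capacity = np.array([2 * pop_sizes[p] for p in populations], dtype=float)
    if per_population:
        rate_ok = np.all(n / capacity >= call_rate, axis=1)
    else:
        rate_ok = n.sum(axis=1) / capacity.sum() >= call_rate
    with np.errstate(invalid="ignore", divide="ignore"):
        pooled = alt.sum(axis=1) / n.sum(axis=1)
    minor = np.minimum(pooled, 1.0 - pooled)
    keep = rate_ok & (minor >= maf) & np.isfinite(minor)
    return counts.loc[keep].reset_index(drop=True)


def wc_fst(n_a, alt_a, n_b, alt_b, het_a=None, het_b=None):
    """Weir & Cockerham (1984) theta-hat for one biallelic locus, two pops.

    ``n_*`` are called allele counts (2x diploids), ``alt_*`` alternate-allele
    counts. Heterozygote frequencies default to the Hardy-Weinberg expectation
    2pq when genotype-level observations are unavailable; pass ``het_*``
    (observed heterozygote proportions) to use them instead.

    Vectorized over loci. Returns NaN where the estimator is undefined (both
    populations monomorphic for the same allele, or insufficient samples).
    """
    n_a = np.asarray(n_a, dtype=float)
    n_b = np.asarray(n_b, dtype=float)
    alt_a = np.asarray(alt_a, dtype=float)
    alt_b = np.asarray(alt_b, dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        p1, p2 = alt_a / n_a, alt_b / n_b
        nd1, nd2 = n_a / 2.0, n_b / 2.0  # diploid sample sizes
        h1 = 2 * p1 * (1 - p1) if het_a is None else np.asarray(het_a, dtype=float)
        h2 = 2 * p2 * (1 - p2) if het_b is None else np.asarray(het_b, dtype=float)

        r = 2.0
        nbar = (nd1 + nd2) / r
        nc = (r * nbar - (nd1**2 + nd2**2) / (r * nbar)) / (r - 1.0)
        pbar = (nd1 * p1 + nd2 * p2) / (r * nbar)
        s2 = (nd1 * (p1 - pbar) ** 2 + nd2 * (p2 - pbar) ** 2) / ((r - 1.0) * nbar)
        hbar = (nd1 * h1 + nd2 * h2) / (r * nbar)

        a = (nbar / nc) * (
            s2
            - (pbar * (1 - pbar) - ((r - 1.0) / r) * s2 - hbar / 4.0) / (nbar - 1.0)
        )
        b = (nbar / (nbar - 1.0)) * (
            pbar * (1 - pbar)
            - ((r - 1.0) / r) * s2
            - ((2.0 * nbar - 1.0) / (4.0 * nbar)) * hbar
        )
        c = hbar / 2.0
        denom = a + b + c
        theta = np.where(denom != 0.0, a / denom, np.nan)
    bad = (n_a <= 0) | (n_b <= 0) | (nd1 < 1) | (nd2 < 1)
    theta = np.where(bad, np.nan, theta)
    return theta if theta.ndim else float(theta)


def branch_transform(fst):
    """Branch length T = -ln(1 - FST), with FST clamped into [0, 1 - 1e-9].

    Negative FST estimates (common sampling noise) clamp to zero; FST = 1
    clamps just below one to keep T finite. NaN propagates.
    """
    f = np.asarray(fst, dtype=float)
    clamped = np.clip(f, 0.0, 1.0 - 1e-9)
    out = np.where(np.isnan(f), np.nan, -np.log1p(-clamped))
    return out if out.ndim else float(out)


def pbs_from_fst(fst12: float, fst13: float, fst23: float) -> dict:
    """Branch lengths, PBS trio and PBSn1 from three pairwise FST values.

    Population 1 is the focal population; 2 and 3 are the outgroups.
    T_ij = -ln(1 - FST_ij); pbs1 = (t12 + t13 - t23)/2, pbs2 and pbs3 by
    rotating which population is focal; pbsn1 = pbs1/(1 + pbs1 + pbs2 + pbs3).
    """
    t12 = branch_transform(fst12)
    t13 = branch_transform(fst13)
    t23 = branch_transform(fst23)
    pbs1 = (t12 + t13 - t23) / 2.0
    pbs2 = (t12 + t23 - t13) / 2.0
    pbs3 = (t13 + t23 - t12) / 2.0
    denom = 1.0 + pbs1 + pbs2 + pbs3
    pbsn1 = pbs1 / denom if denom > 0 else np.nan
    return {
        "t12": t12, "t13": t13, "t23": t23,
        "pbs1": pbs1, "pbs2": pbs2, "pbs3": pbs3, "pbsn1": pbsn1,
    }


def pbs_block_scan(
    snps: pd.DataFrame,
    focal: str,
    out1: str,
    out2: str,
    block_size: int = 5,
    annotation: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """PBSn1 over non-overlapping blocks of consecutive SNPs per chromosome.

    Per-SNP pairwise FST is averaged within each block (NaN SNPs skipped,
    the count recorded), then transformed to branch lengths and combined:
    pbs1 = (t12 + t13 - t23)/2 with the focal population as pop1, pbs2 and
    pbs3 analogously with each outgroup as focal, and
    pbsn1 = pbs1 / (1 + pbs1 + pbs2 + pbs3). Trailing blocks with fewer than
    ``block_size`` SNPs on a chromosome are dropped. Blocks never span
    chromosomes.

    ``snps`` must already be QC-filtered, with per-population ``{pop}_n`` /
    ``{pop}_alt`` columns. If ``annotation`` (BED-style DataFrame with
    chrom, start, end, gene_id) is given, each block is annotated with its
    nearest gene and distance.
    """
    df = snps.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)
    pairs = [(focal, out1), (focal, out2), (out1, out2)]
    fst_per_snp = {}
    for x, y in pairs:
        fst_per_snp[(x, y)] = wc_fst(
            df[f"{x}_n"], df[f"{x}_alt"], df[f"{y}_n"], df[f"{y}_alt"]
        )

    records = []
    for chrom, idx in df.groupby("chrom", sort=True).groups.items():
        idx = np.asarray(idx)
        n_blocks = len(idx) // block_size
        if n_blocks == 0:
            warnings.warn(f"chromosome {chrom}: fewer than {block_size} SNPs")
            continue
        for bi in range(n_blocks):
            sel = idx[bi * block_size : (bi + 1) * block_size]
            means, nvalid = {}, []
            for pair in pairs:
                vals = np.asarray(fst_per_snp[pair])[sel]
                finite = np.isfinite(vals)
                nvalid.append(int(finite.sum()))
                means[pair] = float(vals[finite].mean()) if finite.any() else np.nan
            stats = pbs_from_fst(
                means[(focal, out1)], means[(focal, out2)],
                means[(out1, out2)],
            )
            records.append(
                {
                    "block_id": f"{chrom}:{bi}",
                    "chrom": chrom,
                    "start_pos": int(df.loc[sel[0], "pos"]),
                    "end_pos": int(df.loc[sel[-1], "pos"]),
                    "n_snps": block_size,
                    "n_valid_fst": min(nvalid),
                    "fst12": means[(focal, out1)],
                    "fst13": means[(focal, out2)],
                    "fst23": means[(out1, out2)],
                    **stats,
                }
            )
    blocks = pd.DataFrame(records)
    if annotation is not None and not blocks.empty:
        genes, dists = [], []
        for _, row in blocks.iterrows():
            g, d = closest_gene(
                row["chrom"], int(row["start_pos"]), int(row["end_pos"]), annotation
            )
            genes.append(g)
            dists.append(d)
        blocks["nearest_gene"] = genes
        blocks["distance"] = dists
    return blocks


def closest_gene(
    chrom: str, start_pos: int, end_pos: int, annotation: pd.DataFrame
):
    """Nearest gene to a SNP block span; ties broken by leftmost gene start.

    SNP positions are 1-based; a SNP at position p occupies [p-1, p) in the
    0-based half-open BED convention, so the block spans
    [start_pos - 1, end_pos). Distance is 0 for overlap, otherwise the gap
    in bp between the block span and the gene interval.
    """
    sub = annotation[annotation["chrom"] == chrom]
    if sub.empty:
        warnings.warn(f"no annotation on chromosome {chrom}")
        return None, np.nan
    b_start, b_end = start_pos - 1, end_pos
    g_start = sub["start"].to_numpy()
    g_end = sub["end"].to_numpy()
    dist = np.maximum(0, np.maximum(g_start - b_end, b_start - g_end))
    overlap = (g_start < b_end) & (b_start < g_end)
    dist = np.where(overlap, 0, dist)
    best = dist.min()
    cand = sub[dist == best].sort_values("start")
    return str(cand.iloc[0]["gene_id"]), int(best)


def call_outliers(
    blocks: pd.DataFrame, top_fraction: float = 0.01
) -> tuple[pd.DataFrame, set]:
    """Blocks in the upper PBSn1 tail and the union of their nearest genes.

    The cutoff is the empirical (1 - top_fraction) quantile (linear
    interpolation); ties at the cutoff are all included.
    """
    vals = blocks["pbsn1"].to_numpy(dtype=float)
    finite = np.isfinite(vals)
    if not finite.any():
        raise ValueError("no finite PBSn1 values")
    cutoff = np.quantile(vals[finite], 1.0 - top_fraction)
    if np.nanmin(vals[finite]) == np.nanmax(vals[finite]):
        warnings.warn("all PBSn1 values equal: every block is an outlier")
    outliers = blocks.loc[finite & (vals >= cutoff)]
    genes = (
        set(outliers["nearest_gene"].dropna()) if "nearest_gene" in outliers else set()
    )
    return outliers, genes


def nested_retention(primary_genes: set, nested_genes: set):
    """Outlier genes shared between the primary and nested scans.

    Returns (retained set, |intersection| / |primary|). A high retention
    fraction indicates the primary signal survives conditioning on the
    sister population, i.e. lineage-specific rather than shared-ancestry
    differentiation.
    """
    primary_genes, nested_genes = set(primary_genes), set(nested_genes)
    retained = primary_genes & nested_genes
    frac = len(retained) / len(primary_genes) if primary_genes else float("nan")
    return retained, frac
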