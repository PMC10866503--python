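"""Tissue-specificity analysis: TMM normalization, RPKM, and the tau index.

tau summarizes how concentrated a gene's expression is across tissues:

    tau = sum_i (1 - x_i / x_max) / (n - 1)

over n tissues on linear expression values, ranging from 0 (uniform across
tissues) to 1 (expressed in a single tissue). Genes are called
tissue-specific at tau > 0.85 with the peak tissue being the tissue of
interest, and broadly expressed at tau < 0.35.

Because the liver appears both in the locally profiled data and in the
published multi-tissue reference, tau is computed twice — once with each
liver column — and liver-specific status requires agreement of both
calculations (the dual-liver rule).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

SPECIFIC_THRESHOLD = 0.85
BROAD_THRESHOLD = 0.35


def tmm_normalize(
    counts: pd.DataFrame, trim_m: float = 0.30, trim_a: float = 0.05
) -> pd.Series:
    """Trimmed-mean-of-M-values scaling factors, geometric mean 1.

    The reference sample is the one whose 75th count percentile (relative to
    library size) is closest to the mean across samples. For every other
    sample, genes with the most extreme ``trim_m`` fraction of log-ratios
    (M) and ``trim_a`` fraction of average log-expression (A) are trimmed,
    and the factor is the precision-weighted mean of the remaining M values.
    """
    k = counts.to_numpy(dtype=float)
    if k.shape[1] < 2:
        raise ValueError("TMM needs at least 2 samples")
    lib = k.sum(axis=0)
    if np.any(lib == 0):
        raise ValueError("sample with all-zero counts")
    uq = np.array([np.quantile(k[:, j][k[:, j] > 0], 0.75) for j in range(k.shape[1])])
    uq = uq / lib
    ref_j = int(np.argmin(np.abs(uq - uq.mean())))
    ref = k[:, ref_j]

    logfac = np.zeros(k.shape[1])
    for j in range(k.shape[1]):
        if j == ref_j:
            continue
        obs = k[:, j]
        ok = (obs > 0) & (ref > 0)
        if ok.sum() < 2:
            continue
        p_obs = obs[ok] / lib[j]
        p_ref = ref[ok] / lib[ref_j]
        m = np.log2(p_obs / p_ref)
        a = 0.5 * np.log2(p_obs * p_ref)
        # asymptotic (delta-method) variance of M
        w = (1 - obs[ok] / lib[j]) / obs[ok] + (1 - ref[ok] / lib[ref_j]) / ref[ok]
        lo_m, hi_m = np.quantile(m, [trim_m, 1 - trim_m])
        lo_a, hi_a = np.quantile(a, [trim_a, 1 - trim_a])
        keep = (m >= lo_m) & (m <= hi_m) & (a >= lo_a) & (a <= hi_a)
        if keep.sum() == 0:
            continue
        logfac[j] = np.sum(m[keep] / w[keep]) / np.sum(1.0 / w[keep])
    fac = 2.0**logfac
    fac = fac / np.exp(np.mean(np.log(fac)))
    return pd.Series(fac, index=counts.columns, name="tmm_factor")


def rpkm(
    counts: pd.DataFrame,
    gene_lengths: pd.Series,
    effective_lib_sizes: pd.Series | np.ndarray | None = None,
) -> pd.DataFrame:
    """Reads per kilobase per million mapped reads.

    RPKM = 1e9 * count / (gene length in bp * effective library size).
    Effective library sizes default to column sums; pass
    ``lib_size * tmm_factor`` for TMM-adjusted values. Genes without a
    length are skipped with a warning.
    """
    lengths = gene_lengths.reindex(counts.index)
    missing = lengths.isna()
    if missing.any():
        import warnings

        warnings.warn(f"{int(missing.sum())} genes lack a length; skipped")
        counts = counts.loc[~missing]
        lengths = lengths[~missing]
    if (lengths <= 0).any():
        raise ValueError("gene lengths must be positive")
    if effective_lib_sizes is None:
        effective_lib_sizes = counts.sum(axis=0)
    lib = np.asarray(effective_lib_sizes, dtype=float)
    return 1e9 * counts.div(lengths, axis=0) / lib


def tau(profile) -> float:
    """Tissue-specificity index of one expression profile (linear scale)."""
    x = np.asarray(profile, dtype=float)
    if x.size < 2:
        raise ValueError("tau needs at least 2 tissues")
    if np.any(x < 0):
        raise ValueError("negative expression value")
    xmax = x.max()
    if xmax == 0:
        return float("nan")
    return float(np.sum(1.0 - x / xmax) / (x.size - 1))


def tau_table(profiles: pd.DataFrame, log_transform: bool = False) -> pd.DataFrame:
    """Per-gene tau and peak tissue for a genes-by-tissues matrix.

    ``log_transform`` applies log2(x+1) before tau (off by default; the
    index is conventionally computed on linear values).
    """
    x = profiles.to_numpy(dtype=float)
    if log_transform:
        x = np.log2(x + 1.0)
    xmax = x.max(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = np.sum(1.0 - x / xmax[:, None], axis=1) / (x.shape[1] - 1)
    t = np.where(xmax > 0, t, np.nan)
    argmax = profiles.columns.to_numpy()[np.argmax(x, axis=1)]
    return pd.DataFrame(
        {"tau": t, "argmax_tissue": np.where(xmax > 0, argmax, None)},
        index=profiles.index,
    )


def classify_specificity(
    profiles_local: pd.DataFrame,
    profiles_published: pd.DataFrame,
    dual_tissues: tuple[str, ...] = ("liver",),
    specific_threshold: float = SPECIFIC_THRESHOLD,
    broad_threshold: float = BROAD_THRESHOLD,
) -> pd.DataFrame:
    """Specificity classes from the two tau calculations.

    ``profiles_local`` includes the locally measured liver column;
    ``profiles_published`` swaps in the published-style liver column. A gene
    is ``specific_<t>``:

    * for a tissue in ``dual_tissues`` (shared between calculations): tau
      strictly above the threshold AND peak tissue t in BOTH calculations;
    * for any other tissue (present in only one calculation, e.g. BAT):
      the single calculation containing it decides.

    ``broad`` requires tau < ``broad_threshold`` in the calculation with the
    local liver; anything else is ``intermediate``; all-zero profiles are
    ``unclassified``. Thresholds are strict inequalities, so tau exactly at
    a boundary is intermediate.
    """
    shared = profiles_local.index.intersection(profiles_published.index)
    t1 = tau_table(profiles_local.loc[shared])
    t2 = tau_table(profiles_published.loc[shared])
    out = pd.DataFrame(
        {
            "tau_local": t1["tau"],
            "argmax_local": t1["argmax_tissue"],
            "tau_published": t2["tau"],
            "argmax_published": t2["argmax_tissue"],
        },
        index=shared,
    )
    cls = np.full(len(shared), "intermediate", dtype=object)
    cls[t1["tau"].isna().to_numpy()] = "unclassified"

    spec1 = (t1["tau"] > specific_threshold).to_numpy()
    spec2 = (t2["tau"] > specific_threshold).to_numpy()
    for tissue in profiles_local.columns:
        if tissue in dual_tissues:
            hit = (
                spec1
                & spec2
                & (t1["argmax_tissue"] == tissue).to_numpy()
                & (t2["argmax_tissue"] == tissue).to_numpy()
            )
        else:
            hit = spec1 & (t1["argmax_tissue"] == tissue).to_numpy()
        cls[hit] = f"specific_{tissue}"
    broad = (t1["tau"] < broad_threshold).to_numpy() & ~t1["tau"].isna().to_numpy()
    cls[broad] = "broad"
    out["class"] = cls
    return out


def liver_cross_check(local_liver: pd.Series, published_liver: pd.Series) -> float:
    """Pearson correlation of the two liver expression columns (diagnostic)."""
    shared = local_liver.index.intersection(published_liver.index)
    a = local_liver.loc[shared].to_numpy(dtype=float)
    b = published_liver.loc[shared].to_numpy(dtype=float)
    return float(np.corrcoef(a, b)[0, 1])
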