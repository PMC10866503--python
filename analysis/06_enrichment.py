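#!/usr/bin/env python
"""Permutation enrichment suite over the earlier stages' outputs.

Runs (a) the desk-scale DEG-overlap fold enrichments at the published
set sizes, (b) DEG parallelism between the split-reference comparisons,
(c) overlap of significant-ASE genes with PBSn1 outlier genes, and
(d) DEG enrichment within tissue-specific and broad gene classes.
Outputs under results/enrichment/.
"""

from pathlib import Path

import pandas as pd

from parevol import io
from parevol.diffexpr import call_degs
from parevol.enrichment import (
    OverlapTest,
    degs_in_set_enrichment,
    parallelism_suite,
    permutation_overlap,
)

ROOT = Path(__file__).resolve().parent.parent / "results"
OUT = ROOT / "enrichment"
SEED = 21
ITERS = 10_000

if __name__ == "__main__":
    OUT.mkdir(parents=True, exist_ok=True)

    # (a) published-scale DEG overlaps: fold = observed / null mean
    desk = {}
    for name, (n, m1, m2, obs) in {
        "liver_deg_overlap": (14514, 4121, 4936, 2361),
        "bat_deg_overlap": (14703, 4160, 4585, 2231),
    }.items():
        res = permutation_overlap(
            OverlapTest(n, m1, m2, obs, iterations=ITERS, seed=SEED)
        )
        desk[name] = res.as_row()
        print(f"{name}: fold {res.fold:.2f}, p "
              f"{'~0 (floor)' if res.p_is_floor else f'{res.p_value:.3g}'}")

    # (b) DEG parallelism between the split-reference comparisons
    expressed = list(io.read_table(ROOT / "de" / "de_results.tsv").index)
    da = call_degs(io.read_table(ROOT / "de" / "de_results_refsplit_a.tsv"))
    db = call_degs(io.read_table(ROOT / "de" / "de_results_refsplit_b.tsv"))
    calls = io.read_table(ROOT / "ase" / "regulatory_calls.tsv")
    scan = io.read_table(ROOT / "scan" / "pbs_primary.tsv", index_col=None)
    sig_ase = set(calls.index[calls["H_padj"] < 0.05])
    outlier_genes = set(io.read_gene_list(
        ROOT / "scan" / "outlier_genes_primary.txt"
    ))
    scan_genes = set(scan["nearest_gene"].dropna())
    bg_sel = sorted(set(calls.index) & scan_genes)

    suite = parallelism_suite(
        {
            "deg_parallelism_split_reference": {
                "background": expressed, "set_a": set(da.gene_ids),
                "set_b": set(db.gene_ids), "iterations": ITERS,
            },
            "ase_x_pbsn1": {
                "background": bg_sel,
                "set_a": sig_ase & set(bg_sel),
                "set_b": outlier_genes & set(bg_sel),
                "iterations": ITERS,
            },
        },
        seed=SEED,
    )
    for name, row in suite.iterrows():
        print(f"{name}: observed {row['observed']}, fold {row['fold']:.2f}, "
              f"p {row['p']:.3g}")

    # (d) DEGs within tissue-specificity classes
    degs = set(io.read_gene_list(ROOT / "de" / "degs.txt"))
    tau_table = io.read_table(ROOT / "tau" / "tau_table.tsv")
    bg_tau = sorted(set(tau_table.index) & set(expressed))
    rows = []
    for cls, alt in (("specific_liver", "greater"), ("broad", "less")):
        genes = set(tau_table.index[tau_table["class"] == cls]) & set(bg_tau)
        if len(genes) < 2:
            continue
        res = degs_in_set_enrichment(genes, degs & set(bg_tau), bg_tau,
                                     iterations=ITERS, seed=SEED + 1,
                                     alternative=alt)
        rows.append({"test_name": f"degs_in_{cls}", **res.as_row()})
        print(f"degs_in_{cls} ({alt}): observed {res.observed}, "
              f"fold {res.fold:.2f}, p {res.p_value:.3g}")

    table = pd.concat([
        pd.DataFrame.from_dict(desk, orient="index"),
        suite,
        pd.DataFrame(rows).set_index("test_name") if rows else pd.DataFrame(),
    ])
    table.index.name = "test_name"
    io.write_table(table, OUT / "enrichment.tsv")
    print(f"wrote {len(table)} enrichment tests to {OUT/'enrichment.tsv'}")
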