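"""End-to-end orchestration of the analysis on synthetic or user data.

``run_all`` chains the stages — simulate, differential expression, ASE /
regulatory classification, tissue specificity, selection scans (primary and
nested), enrichment suite — with files as stage boundaries under a run
directory, and writes a manifest recording the configuration hash, seeds,
per-output checksums and timings. A single global seed determines every
stochastic stage (stage seeds are derived from it deterministically).
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import ase, diffexpr, enrichment, io, pbs, simulate, tau

__version__ = "0.1.0"


@dataclass
class RunConfig:
    """All thresholds of the analysis, defaulting to the published values."""

    outdir: str = "run"
    seed: int = 0
    # simulation scenario (set n_genes to 0 to skip simulation)
    n_genes: int = 800
    n_replicates: int = 6
    baseline_mean: float = 500.0
    dispersion: float = 0.05
    cis_effect_log2: float = 2.0
    trans_effect_log2: float = 2.0
    mode_fractions: dict = field(
        default_factory=lambda: {
            "cis_only": 0.15, "trans_only": 0.15, "cis_plus_trans": 0.05,
            "cis_times_trans": 0.05, "compensatory": 0.05, "conserved": 0.55,
        }
    )
    # stage thresholds
    de_fdr: float = 0.05
    expression_min_mean: float = 10.0
    tau_specific: float = 0.85
    tau_broad: float = 0.35
    snp_call_rate: float = 0.80
    parent_call_rate: float = 0.85
    maf: float = 0.05
    block_size: int = 5
    outlier_top_fraction: float = 0.01
    permutation_iterations: int = 10_000
    n_sweeps: int = 50
    sweep_shift: float = 0.9
    drift_scale: float = 0.05

    def validate(self) -> None:
        for name in ("de_fdr", "tau_specific", "tau_broad", "snp_call_rate",
                     "parent_call_rate", "maf", "outlier_top_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.block_size < 1 or self.permutation_iterations < 1:
            raise ValueError("block size and iterations must be positive")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        cfg = cls(**data)
        cfg.validate()
        return cfg

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


class StageError(RuntimeError):
    """A stage failed; the message names the stage and offending input."""


def run_all(config: RunConfig) -> dict:
    """Execute the full synthetic analysis; returns the run manifest."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config.to_yaml(outdir / "config.yaml")
    manifest: dict = {
        "config_sha256": _sha256(outdir / "config.yaml"),
        "version": __version__,
        "seed": config.seed,
        "stages": {},
    }
    state: dict = {}
    stages = [
        ("simulate", _stage_simulate),
        ("diffexpr", _stage_diffexpr),
        ("ase", _stage_ase),
        ("tau", _stage_tau),
        ("scan", _stage_scan),
        ("enrich", _stage_enrich),
    ]
    for name, fn in stages:
        t0 = time.monotonic()
        try:
            outputs = fn(config, outdir, state)
        except Exception as exc:  # noqa: BLE001 - reported with stage name
            raise StageError(f"stage {name!r} failed: {exc}") from exc
        manifest["stages"][name] = {
            "seconds": round(time.monotonic() - t0, 3),
            "outputs": {p.name: _sha256(p) for p in outputs},
        }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def _stage_simulate(cfg: RunConfig, outdir: Path, state: dict) -> list[Path]:
    scenario = simulate.RegulatoryScenario(
        n_genes=cfg.n_genes,
        n_replicates_per_group=cfg.n_replicates,
        baseline_mean=cfg.baseline_mean,
        dispersion=cfg.dispersion,
        mode_fractions=cfg.mode_fractions,
        cis_effect_log2=cfg.cis_effect_log2,
        trans_effect_log2=cfg.trans_effect_log2,
        seed=cfg.seed,
    )
    study = simulate.simulate_study(
        scenario, n_sweeps=cfg.n_sweeps, sweep_shift=cfg.sweep_shift,
        drift_scale=cfg.drift_scale,
    )
    state["study"] = study
    state["scenario"] = scenario
    d = outdir / "inputs"
    d.mkdir(exist_ok=True)
    io.write_counts_tsv(study.parental_counts, d / "parental_counts.tsv",
                        d / "parental_meta.tsv")
    io.write_counts_tsv(study.f1_allele_counts, d / "f1_allele_counts.tsv",
                        d / "f1_meta.tsv")
    io.write_vcf(study.genotypes, d / "genotypes.vcf")
    io.write_bed(study.annotation, d / "annotation.bed")
    io.write_pop_counts(study.populations, d / "populations.tsv")
    io.write_table(study.tissue_profiles, d / "tissue_profiles.tsv")
    io.write_table(study.tissue_profiles_published,
                   d / "tissue_profiles_published.tsv")
    io.write_table(study.true_modes.to_frame(), d / "true_modes.tsv")
    for name, genes in study.gene_sets.items():
        io.write_gene_list(genes, d / f"geneset_{name}.txt")
    return sorted(d.iterdir())


def _stage_diffexpr(cfg: RunConfig, outdir: Path, state: dict) -> list[Path]:
    study = state["study"]
    scenario = state["scenario"]
    filtered = diffexpr.filter_expressed(study.parental_counts,
                                         cfg.expression_min_mean)
    res = diffexpr.nb_wald(filtered, (scenario.strain_a, scenario.strain_b))
    degs = diffexpr.call_degs(res, cfg.de_fdr)
    state["de_results"] = res
    state["degs"] = degs
    state["expressed"] = list(filtered.gene_ids)
    split = diffexpr.split_reference_check(
        filtered, scenario.strain_a, scenario.strain_a, scenario.strain_b
    ) if cfg.n_replicates >= 4 else None
    state["split"] = split
    p = outdir / "de_results.tsv"
    io.write_table(res, p)
    p2 = outdir / "degs.txt"
    io.write_gene_list(sorted(degs.gene_ids), p2)
    return [p, p2]


def _stage_ase(cfg: RunConfig, outdir: Path, state: dict) -> list[Path]:
    study = state["study"]
    scenario = state["scenario"]
    informative = ase.select_informative_snps(
        study.genotypes, scenario.strain_a, scenario.strain_b,
        cfg.parent_call_rate,
    )
    gene_counts = ase.allele_counts_per_gene(
        study.snp_allele_counts, informative, study.annotation
    )
    trio = ase.trio_tests(
        study.parental_counts, gene_counts,
        (scenario.strain_a, scenario.strain_b), cfg.expression_min_mean,
    )
    calls = ase.classify_regulatory(trio, cfg.de_fdr)
    out = trio.copy()
    out["category"] = calls.astype(str)
    state["trio"] = trio
    state["calls"] = calls
    ratio, bias = ase.mapping_bias_check(gene_counts, scenario.strain_a)
    state["mapping_bias"] = (ratio, bias)
    p = outdir / "regulatory_calls.tsv"
    io.write_table(out, p)
    return [p]


def _stage_tau(cfg: RunConfig, outdir: Path, state: dict) -> list[Path]:
    study = state["study"]
    table = tau.classify_specificity(
        study.tissue_profiles, study.tissue_profiles_published,
        dual_tissues=("liver",),
        specific_threshold=cfg.tau_specific, broad_threshold=cfg.tau_broad,
    )
    table["liver_pearson_r"] = tau.liver_cross_check(
        study.tissue_profiles["liver"], study.tissue_profiles_published["liver"]
    )
    state["tau_table"] = table
    p = outdir / "tau_table.tsv"
    io.write_table(table, p)
    return [p]


def _stage_scan(cfg: RunConfig, outdir: Path, state: dict) -> list[Path]:
    study = state["study"]
    if study.annotation is None:
        raise StageError("selection scan: annotation is missing")
    pops = ["focal", "sister", "southern", "out1", "out2"]
    sizes = {p: int(study.populations[f"{p}_n"].iloc[0] // 2) for p in pops}
    qc = pbs.snp_qc(study.populations, pops, sizes, cfg.snp_call_rate, cfg.maf)
    primary = pbs.pbs_block_scan(
        qc, "focal", "out1", "out2", cfg.block_size, study.annotation
    )
    nested = pbs.pbs_block_scan(
        qc, "focal", "sister", "out2", cfg.block_size, study.annotation
    )
    _, primary_genes = pbs.call_outliers(primary, cfg.outlier_top_fraction)
    _, nested_genes = pbs.call_outliers(nested, cfg.outlier_top_fraction)
    retained, frac = pbs.nested_retention(primary_genes, nested_genes)
    state["scan_primary"] = primary
    state["outlier_genes"] = primary_genes
    state["nested_genes"] = nested_genes
    state["retention"] = frac
    primary = primary.copy()
    primary["outlier_flag"] = primary["nearest_gene"].isin(primary_genes) & (
        primary["pbsn1"] >= np.quantile(
            primary["pbsn1"].dropna(), 1 - cfg.outlier_top_fraction
        )
    )
    p = outdir / "pbs_scan.tsv"
    io.write_table(primary, p, index=False)
    p2 = outdir / "nested_retention.txt"
    p2.write_text(
        f"retained\t{len(retained)}\nprimary\t{len(primary_genes)}\n"
        f"fraction\t{frac:.4f}\n"
    )
    return [p, p2]


def _stage_enrich(cfg: RunConfig, outdir: Path, state: dict) -> list[Path]:
    study = state["study"]
    degs = set(state["degs"].gene_ids)
    expressed = state["expressed"]
    calls = state["calls"]
    tau_table = state["tau_table"]
    iters = cfg.permutation_iterations

    tests = {}
    split = state.get("split")
    if split is not None:
        res_a, res_b, _ = split
        da = set(diffexpr.call_degs(res_a, cfg.de_fdr).gene_ids)
        db = set(diffexpr.call_degs(res_b, cfg.de_fdr).gene_ids)
        tests["deg_parallelism_split_reference"] = {
            "background": expressed, "set_a": da, "set_b": db,
            "iterations": iters,
        }
    ase_genes = set(calls.index)
    scan_genes = set(state["scan_primary"]["nearest_gene"].dropna())
    background_sel = sorted(ase_genes & scan_genes)
    sig_ase = set(calls.index[calls.isin(["cis_only", "cis_plus_trans",
                                          "cis_times_trans", "compensatory"])])
    outliers = state["outlier_genes"]
    if background_sel:
        tests["ase_x_pbsn1"] = {
            "background": background_sel,
            "set_a": sig_ase & set(background_sel),
            "set_b": outliers & set(background_sel),
            "iterations": iters,
        }
    suite = enrichment.parallelism_suite(tests, seed=cfg.seed)

    spec_cols = [c for c in tau_table["class"].unique()
                 if str(c).startswith("specific_")]
    rows = []
    bg_tau = list(tau_table.index)
    for cls in spec_cols + ["broad"]:
        genes = set(tau_table.index[tau_table["class"] == cls]) & set(expressed)
        if not genes:
            continue
        alt = "less" if cls == "broad" else "greater"
        res = enrichment.degs_in_set_enrichment(
            genes, degs & set(bg_tau), bg_tau, iterations=iters,
            seed=cfg.seed + 1, alternative=alt,
        )
        rows.append({"test_name": f"degs_in_{cls}", **res.as_row()})
    if rows:
        extra = pd.DataFrame(rows).set_index("test_name")
        suite = pd.concat([suite, extra])
    p = outdir / "enrichment.tsv"
    io.write_table(suite, p)
    state["enrichment"] = suite
    return [p]
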