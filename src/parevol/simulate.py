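"""Synthetic data with known ground truth for every pipeline stage.

Generates (a) negative-binomial RNA-seq counts for two parental strains and
paired F1 allele pools under designated regulatory modes, (b) multi-tissue
expression profiles with controlled tau, (c) biallelic SNP allele counts for
a focal population plus outgroups with planted allele-frequency sweeps, and
(d) a non-overlapping gene annotation tying SNPs to genes — everything the
end-to-end analysis consumes, with truth labels recorded.

Generative model for the expression study: with per-gene cis effect c and
trans effect t (log2 scale, signs drawn per gene),

* parental means:  strain A = baseline * 2^((c+t)/2),  strain B =
  baseline * 2^(-(c+t)/2);
* F1 allele-pool means:  allele A = (baseline/2) * 2^(c/2),  allele B =
  (baseline/2) * 2^(-c/2) — trans effects act on both alleles of the
  shared hybrid milieu and cancel from the allelic ratio, cis effects do
  not.

Effects are split symmetrically across the two strains so that, with
random effect signs, neither strain's reads are systematically inflated
(total read flow stays balanced, as the mapping-bias diagnostic expects).

Regulatory modes set (c, t): cis_only (c != 0, t = 0), trans_only (c = 0,
t != 0), cis_plus_trans (same sign), cis_times_trans (t opposing and
exceeding c, so parental and allelic divergence point opposite ways),
compensatory (t = -c, parental means equal), conserved (c = t = 0).
Counts are NB with Var = mu + alpha*mu^2; library sizes vary log-normally
(sigma = 0.15) around 1, shared between the two pools of one F1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ase import GenotypeMatrix, HET, HOM_ALT, HOM_REF
from .diffexpr import CountMatrix

MODES = (
    "cis_only",
    "trans_only",
    "cis_plus_trans",
    "cis_times_trans",
    "compensatory",
    "conserved",
)

LIBSIZE_SIGMA = 0.15


@dataclass(frozen=True)
class RegulatoryScenario:
    """Parameters of a simulated two-strain / F1 expression study."""

    n_genes: int
    n_replicates_per_group: int = 6
    baseline_mean: float = 500.0
    dispersion: float = 0.05
    mode_fractions: dict = field(
        default_factory=lambda: {"cis_only": 0.25, "trans_only": 0.25,
                                 "conserved": 0.5}
    )
    cis_effect_log2: float = 2.0
    trans_effect_log2: float = 2.0
    strain_a: str = "NORTH"
    strain_b: str = "SOUTH"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.baseline_mean <= 0 or self.dispersion <= 0:
            raise ValueError("baseline mean and dispersion must be positive")
        if self.n_replicates_per_group < 2:
            raise ValueError("need at least 2 replicates per group")
        unknown = set(self.mode_fractions) - set(MODES)
        if unknown:
            raise ValueError(f"unknown regulatory modes: {sorted(unknown)}")
        total = sum(self.mode_fractions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"mode fractions sum to {total}, not 1")


@dataclass
class SimulatedStudy:
    """Bundle of all synthetic inputs plus their truth labels."""

    parental_counts: CountMatrix
    f1_allele_counts: CountMatrix
    true_modes: pd.Series
    true_effects: pd.DataFrame  # per-gene cis/trans log2 effects
    genotypes: GenotypeMatrix | None = None
    informative_truth: pd.DataFrame | None = None
    snp_allele_counts: pd.DataFrame | None = None
    annotation: pd.DataFrame | None = None
    tissue_profiles: pd.DataFrame | None = None
    tissue_profiles_published: pd.DataFrame | None = None
    tissue_truth: pd.DataFrame | None = None
    populations: pd.DataFrame | None = None
    gene_sets: dict = field(default_factory=dict)


def _nb_draw(rng: np.random.Generator, mean, alpha: float) -> np.ndarray:
    """NB samples with Var = mu + alpha*mu^2 (Poisson limit for tiny alpha)."""
    mean = np.asarray(mean, dtype=float)
    if alpha < 1e-8:
        return rng.poisson(mean)
    r = 1.0 / alpha
    p = r / (r + mean)
    return rng.negative_binomial(r, p)


def _draw_effects(rng, modes, cis, trans) -> pd.DataFrame:
    """Per-gene (c, t) log2 effects implied by each regulatory mode."""
    c = np.zeros(len(modes))
    t = np.zeros(len(modes))
    sign = rng.choice([-1.0, 1.0], size=len(modes))
    for i, mode in enumerate(modes):
        s = sign[i]
        if mode == "cis_only":
            c[i] = s * cis
        elif mode == "trans_only":
            t[i] = s * trans
        elif mode == "cis_plus_trans":
            c[i], t[i] = s * cis, s * trans
        elif mode == "cis_times_trans":
            # trans opposes and overwhelms cis: parental and allelic
            # divergence point in opposite directions
            c[i], t[i] = s * cis, -s * (cis + trans)
        elif mode == "compensatory":
            c[i], t[i] = s * cis, -s * cis
    return pd.DataFrame({"cis_log2": c, "trans_log2": t})


def simulate_expression_study(scenario: RegulatoryScenario) -> SimulatedStudy:
    """Parental and F1 allele-pool counts under the scenario's modes.

    Deterministic for a fixed seed. Gene ids are g000000, g000001, ...;
    sample ids encode strain/replicate for parents and individual|allele
    for F1 pools (matching the output of gene-level ASE aggregation).
    """
    rng = np.random.default_rng(scenario.seed)
    n = scenario.n_genes
    gene_ids = pd.Index([f"g{i:06d}" for i in range(n)], name="gene_id")

    frac_items = sorted(scenario.mode_fractions.items())
    counts_per_mode = {m: int(round(f * n)) for m, f in frac_items}
    drift = n - sum(counts_per_mode.values())
    if drift != 0:  # rounding: adjust the largest class
        biggest = max(counts_per_mode, key=counts_per_mode.get)
        counts_per_mode[biggest] += drift
    modes = np.concatenate(
        [np.full(k, m) for m, k in counts_per_mode.items()]
    )
    rng.shuffle(modes)
    true_modes = pd.Series(modes, index=gene_ids, name="true_mode")

    eff = _draw_effects(rng, modes, scenario.cis_effect_log2,
                        scenario.trans_effect_log2)
    eff.index = gene_ids
    base = scenario.baseline_mean
    total = (eff["cis_log2"] + eff["trans_log2"]).to_numpy()
    cis = eff["cis_log2"].to_numpy()
    mean_pa = base * 2.0 ** (total / 2.0)
    mean_pb = base * 2.0 ** (-total / 2.0)
    mean_ha = (base / 2.0) * 2.0 ** (cis / 2.0)
    mean_hb = (base / 2.0) * 2.0 ** (-cis / 2.0)

    reps = scenario.n_replicates_per_group
    sa, sb = scenario.strain_a, scenario.strain_b
    lib_par = rng.lognormal(0.0, LIBSIZE_SIGMA, size=2 * reps)
    par_cols, par_counts, par_meta = [], [], []
    for j in range(reps):
        par_cols.append(f"{sa}_P{j+1}")
        par_counts.append(_nb_draw(rng, mean_pa * lib_par[j], scenario.dispersion))
        par_meta.append((sa, "parent", None, None))
    for j in range(reps):
        par_cols.append(f"{sb}_P{j+1}")
        par_counts.append(
            _nb_draw(rng, mean_pb * lib_par[reps + j], scenario.dispersion)
        )
        par_meta.append((sb, "parent", None, None))
    parental = CountMatrix(
        pd.DataFrame(np.column_stack(par_counts), index=gene_ids,
                     columns=par_cols),
        pd.DataFrame(par_meta, index=pd.Index(par_cols),
                     columns=["strain", "generation", "allele_of_origin",
                              "individual"]),
    )

    lib_f1 = rng.lognormal(0.0, LIBSIZE_SIGMA, size=reps)
    f1_cols, f1_counts, f1_meta = [], [], []
    for j in range(reps):
        indiv = f"F1_{j+1}"
        for strain, mean in ((sa, mean_ha), (sb, mean_hb)):
            f1_cols.append(f"{indiv}|{strain}")
            f1_counts.append(_nb_draw(rng, mean * lib_f1[j], scenario.dispersion))
            f1_meta.append((strain, "F1", strain, indiv))
    f1 = CountMatrix(
        pd.DataFrame(np.column_stack(f1_counts), index=gene_ids,
                     columns=f1_cols),
        pd.DataFrame(f1_meta, index=pd.Index(f1_cols),
                     columns=["strain", "generation", "allele_of_origin",
                              "individual"]),
    )
    return SimulatedStudy(parental, f1, true_modes, eff)


def simulate_tissue_profiles(
    n_genes: int,
    n_tissues: int,
    spec_fraction: float,
    seed: int = 0,
    uniform_fraction: float | None = None,
    tissues: list[str] | None = None,
    base_level: float = 100.0,
    decay: float = 0.5,
):
    """Expression profiles with controlled tissue specificity.

    A ``spec_fraction`` of genes is expressed in exactly one (random) tissue
    (true tau = 1); ``uniform_fraction`` (default: all remaining genes) is
    constant across tissues (true tau = 0); any remainder follows a
    geometric-decay profile with an intermediate, analytically known tau.

    Returns (profiles DataFrame genes x tissues, truth DataFrame with
    true_class and true_tau).
    """
    if not 0.0 <= spec_fraction <= 1.0:
        raise ValueError("spec_fraction must lie in [0, 1]")
    if n_tissues < 2:
        raise ValueError("need at least 2 tissues")
    if uniform_fraction is None:
        uniform_fraction = 1.0 - spec_fraction
    if spec_fraction + uniform_fraction > 1.0 + 1e-9:
        raise ValueError("class fractions exceed 1")
    rng = np.random.default_rng(seed)
    if tissues is None:
        tissues = [f"tissue{j+1}" for j in range(n_tissues)]
    gene_ids = pd.Index([f"g{i:06d}" for i in range(n_genes)], name="gene_id")

    n_spec = int(round(spec_fraction * n_genes))
    n_unif = min(int(round(uniform_fraction * n_genes)), n_genes - n_spec)
    profiles = np.zeros((n_genes, n_tissues))
    classes = np.empty(n_genes, dtype=object)
    true_tau = np.empty(n_genes)

    for i in range(n_spec):
        j = rng.integers(n_tissues)
        profiles[i, j] = base_level
        classes[i] = "specific"
        true_tau[i] = 1.0
    for i in range(n_spec, n_spec + n_unif):
        profiles[i, :] = base_level
        classes[i] = "uniform"
        true_tau[i] = 0.0
    ranks = np.arange(n_tissues)
    inter_tau = float(np.sum(1.0 - decay**ranks) / (n_tissues - 1))
    for i in range(n_spec + n_unif, n_genes):
        prof = base_level * decay**ranks
        rng.shuffle(prof)
        profiles[i, :] = prof
        classes[i] = "intermediate"
        true_tau[i] = inter_tau

    perm = rng.permutation(n_genes)
    profiles = profiles[perm]
    truth = pd.DataFrame(
        {"true_class": classes[perm], "true_tau": true_tau[perm]},
        index=gene_ids,
    )
    return pd.DataFrame(profiles, index=gene_ids, columns=tissues), truth


def simulate_populations(
    n_snps: int,
    pops: dict[str, int] | None = None,
    drift_scale: float = 0.05,
    sweep_loci=(),
    sweep_shift: float = 0.9,
    seed: int = 0,
    positions: pd.DataFrame | None = None,
    sweep_populations: tuple[str, ...] | None = None,
) -> pd.DataFrame:
    """Biallelic allele counts for several populations with planted sweeps.

    Neutral model: ancestral frequency p0 ~ Uniform(0.05, 0.95) per SNP;
    each population's frequency is p0 + Normal(0, drift_scale * p0*(1-p0)),
    clamped to [0, 1]. Sweep loci are additionally displaced in the focal
    population only (or in every population named in ``sweep_populations``,
    to model selection predating a population split), proportionally toward
    fixation of the currently major allele: p <- p + sweep_shift *
    (target - p) with target 1 if p >= 0.5 else 0. Diploid sample allele
    counts are Binomial(2*n, p).

    ``pops`` maps population name to diploid sample size; the first key is
    the focal population. Default design: focal, sister, southern, out1,
    out2 with 20 diploids each. ``positions`` optionally supplies chrom/pos
    per SNP (e.g. from :func:`place_snps_in_genes`); otherwise SNPs sit at
    consecutive positions on one chromosome.
    """
    if pops is None:
        pops = {"focal": 20, "sister": 20, "southern": 20,
                "out1": 20, "out2": 20}
    if any(n <= 0 for n in pops.values()):
        raise ValueError("every population needs at least one diploid")
    sweep_loci = np.asarray(sorted(set(int(i) for i in sweep_loci)), dtype=int)
    if sweep_loci.size and not (0 < sweep_shift <= 1):
        raise ValueError("sweep_shift must lie in (0, 1] when sweeps are planted")
    if sweep_loci.size and (sweep_loci.min() < 0 or sweep_loci.max() >= n_snps):
        raise ValueError("sweep_loci outside SNP index range")
    rng = np.random.default_rng(seed)
    p0 = rng.uniform(0.05, 0.95, size=n_snps)
    names = list(pops)
    focal = names[0]
    freqs = {}
    for name in names:
        noise = rng.normal(0.0, drift_scale * p0 * (1.0 - p0))
        freqs[name] = np.clip(p0 + noise, 0.0, 1.0)
    if sweep_loci.size:
        # a sweep displaces the focal population only, unless an explicit
        # list of swept populations models selection predating a split
        swept = sweep_populations if sweep_populations is not None else (focal,)
        target = None
        for name in swept:
            p = freqs[name]
            if target is None:  # same target allele in every swept population
                target = np.where(p[sweep_loci] >= 0.5, 1.0, 0.0)
            p[sweep_loci] = p[sweep_loci] + sweep_shift * (target - p[sweep_loci])
            freqs[name] = np.clip(p, 0.0, 1.0)

    if positions is None:
        positions = pd.DataFrame(
            {"chrom": "chr1", "pos": np.arange(1, n_snps + 1) * 100}
        )
    if len(positions) != n_snps:
        raise ValueError("positions must have one row per SNP")
    out = positions.reset_index(drop=True).copy()
    out["ref"] = "A"
    out["alt"] = "T"
    for name in names:
        n_alleles = 2 * pops[name]
        out[f"{name}_n"] = n_alleles
        out[f"{name}_alt"] = rng.binomial(n_alleles, freqs[name])
    flags = np.zeros(n_snps, dtype=bool)
    flags[sweep_loci] = True
    out["is_sweep"] = flags
    return out


def simulate_annotation(
    n_genes: int,
    chrom_layout: list[tuple[str, int]] | None = None,
    seed: int = 0,
    gene_length: tuple[int, int] = (1000, 3000),
    min_gap: int = 200,
) -> pd.DataFrame:
    """Non-overlapping, sorted gene intervals (BED convention).

    Genes are distributed across chromosomes proportionally to length and
    placed left to right with random gaps. Raises when the requested genes
    cannot fit.

    Returns a DataFrame with columns chrom, start (0-based), end (half-open),
    gene_id, score, strand.
    """
    rng = np.random.default_rng(seed)
    if chrom_layout is None:
        per_chrom_len = n_genes * (gene_length[1] + 2 * min_gap)
        chrom_layout = [("chr1", max(per_chrom_len, 10_000))]
    total_len = sum(length for _, length in chrom_layout)
    if n_genes * (gene_length[0] + min_gap) > total_len:
        raise ValueError("gene footprint does not fit the chromosomes")

    alloc = []
    remaining = n_genes
    for idx, (name, length) in enumerate(chrom_layout):
        if idx == len(chrom_layout) - 1:
            k = remaining
        else:
            k = int(round(n_genes * length / total_len))
            k = min(k, remaining)
        alloc.append((name, length, k))
        remaining -= k

    rows = []
    gi = 0
    for name, length, k in alloc:
        if k == 0:
            continue
        lens = rng.integers(gene_length[0], gene_length[1] + 1, size=k)
        slack = length - int(lens.sum()) - k * min_gap
        if slack < 0:
            raise ValueError(f"genes do not fit on {name}")
        gaps = rng.multinomial(slack, np.ones(k) / k) if slack > 0 else np.zeros(k, int)
        cursor = 0
        for j in range(k):
            start = cursor + min_gap + int(gaps[j])
            end = start + int(lens[j])
            rows.append((name, start, end, f"g{gi:06d}", 0, "+"))
            cursor = end
            gi += 1
    ann = pd.DataFrame(
        rows, columns=["chrom", "start", "end", "gene_id", "score", "strand"]
    )
    return ann.sort_values(["chrom", "start"], kind="mergesort").reset_index(
        drop=True
    )


def place_snps_in_genes(
    annotation: pd.DataFrame, snps_per_gene: int = 5
) -> pd.DataFrame:
    """Evenly spaced 1-based SNP positions inside every gene interval.

    Returns chrom/pos rows ordered by the annotation, ``snps_per_gene`` per
    gene, plus the host gene id — the geometry for selection-scan blocks
    whose nearest gene is known by construction.
    """
    rows = []
    for _, g in annotation.iterrows():
        span = g["end"] - g["start"]
        if span < snps_per_gene:
            raise ValueError(f"gene {g['gene_id']} too short for SNP placement")
        offsets = (np.arange(snps_per_gene) + 1) * span // (snps_per_gene + 1)
        for off in offsets:
            rows.append((g["chrom"], int(g["start"] + off + 1), g["gene_id"]))
    return pd.DataFrame(rows, columns=["chrom", "pos", "gene_id"])


def simulate_genotypes_for_ase(
    study: SimulatedStudy,
    annotation: pd.DataFrame,
    strain_a: str,
    strain_b: str,
    n_parents_per_strain: int = 6,
    snps_per_gene: int = 2,
    decoy_fraction: float = 0.2,
    seed: int = 0,
):
    """Genotypes and SNP-level allelic read counts consistent with the study.

    Per gene: ``snps_per_gene`` informative SNPs (fixed-and-different in
    parents, het in every F1), with the reference-carrying parent drawn at
    random per SNP. A ``decoy_fraction`` of genes also receives one
    non-informative SNP (segregating in one parent, or homozygous in an F1)
    to exercise the filters. Gene-level F1 allele counts are split across a
    gene's informative SNPs multinomially, so SNP-level counts aggregate
    back to the gene-level truth exactly.

    Attaches ``genotypes``, ``informative_truth`` and ``snp_allele_counts``
    to the study and returns it.
    """
    rng = np.random.default_rng(seed)
    f1_meta = study.f1_allele_counts.sample_meta
    individuals = list(dict.fromkeys(f1_meta["individual"]))
    sample_ids = (
        [f"{strain_a}_G{j+1}" for j in range(n_parents_per_strain)]
        + [f"{strain_b}_G{j+1}" for j in range(n_parents_per_strain)]
        + individuals
    )
    groups = pd.Series(
        [strain_a] * n_parents_per_strain
        + [strain_b] * n_parents_per_strain
        + ["F1"] * len(individuals),
        index=pd.Index(sample_ids),
    )
    n_samples = len(sample_ids)
    a_mask = (groups == strain_a).to_numpy()
    b_mask = (groups == strain_b).to_numpy()
    f1_mask = (groups == "F1").to_numpy()

    snp_rows, geno_rows, truth_rows = [], [], []
    ann = annotation.set_index("gene_id")
    for gene in study.parental_counts.gene_ids:
        if gene not in ann.index:
            continue
        g = ann.loc[gene]
        span = g["end"] - g["start"]
        offsets = (np.arange(snps_per_gene) + 1) * span // (snps_per_gene + 1)
        # alternate which parent carries the reference allele within a
        # gene (random start): reference read flow then balances per gene,
        # so the mapping-bias diagnostic is not confounded by cis effects
        first = strain_a if rng.random() < 0.5 else strain_b
        second = strain_b if first == strain_a else strain_a
        for si, off in enumerate(offsets):
            pos = int(g["start"] + off + 1)
            ref_parent = first if si % 2 == 0 else second
            geno = np.full(n_samples, HET)
            ref_is_a = ref_parent == strain_a
            geno[a_mask] = HOM_REF if ref_is_a else HOM_ALT
            geno[b_mask] = HOM_ALT if ref_is_a else HOM_REF
            snp_rows.append((g["chrom"], pos, "A", "T"))
            geno_rows.append(geno)
            truth_rows.append((g["chrom"], pos, gene, ref_parent, True))
        if rng.random() < decoy_fraction:
            pos = int(g["start"] + span // 2 + 1)
            while any(r[0] == g["chrom"] and r[1] == pos for r in snp_rows[-snps_per_gene:]):
                pos += 1
            geno = np.full(n_samples, HET)
            if rng.random() < 0.5:  # segregating in parent A
                half = a_mask.nonzero()[0]
                geno[a_mask] = HOM_REF
                geno[half[: len(half) // 2]] = HET
                geno[b_mask] = HOM_ALT
            else:  # an F1 homozygous
                geno[a_mask] = HOM_REF
                geno[b_mask] = HOM_ALT
                geno[f1_mask.nonzero()[0][0]] = HOM_ALT
            snp_rows.append((g["chrom"], pos, "A", "T"))
            geno_rows.append(geno)
            truth_rows.append((g["chrom"], pos, gene, None, False))

    snps = pd.DataFrame(snp_rows, columns=["chrom", "pos", "ref", "alt"])
    genotypes = GenotypeMatrix(
        snps,
        pd.DataFrame(np.vstack(geno_rows), columns=groups.index),
        groups,
    )
    truth = pd.DataFrame(
        truth_rows, columns=["chrom", "pos", "gene_id", "ref_parent",
                             "informative"]
    )

    # split gene-level allele counts over the gene's informative SNPs
    counts = study.f1_allele_counts.counts
    inf = truth[truth["informative"]]
    ac_rows = []
    for gene, snp_grp in inf.groupby("gene_id", sort=True):
        k = len(snp_grp)
        share = np.ones(k) / k
        for indiv in individuals:
            per_strain = {}
            for strain in (strain_a, strain_b):
                col = f"{indiv}|{strain}"
                total = int(counts.loc[gene, col]) if col in counts else 0
                per_strain[strain] = rng.multinomial(total, share)
            for j, (_, snp) in enumerate(snp_grp.iterrows()):
                ref_p = snp["ref_parent"]
                alt_p = strain_b if ref_p == strain_a else strain_a
                ac_rows.append(
                    (snp["chrom"], snp["pos"], indiv,
                     int(per_strain[ref_p][j]), int(per_strain[alt_p][j]))
                )
    study.snp_allele_counts = pd.DataFrame(
        ac_rows, columns=["chrom", "pos", "individual", "ref_reads",
                          "alt_reads"]
    )
    study.genotypes = genotypes
    study.informative_truth = truth
    study.annotation = annotation
    return study


def simulate_study(
    scenario: RegulatoryScenario,
    n_tissues: int = 8,
    tissue_spec_fraction: float = 0.2,
    n_pop_snps: int | None = None,
    n_sweeps: int = 50,
    sweep_shift: float = 0.9,
    drift_scale: float = 0.05,
    snps_per_gene: int = 5,
    body_size_set_fraction: float = 0.05,
) -> SimulatedStudy:
    """End-to-end synthetic study: expression, genotypes, tissues, populations.

    All stage seeds derive deterministically from ``scenario.seed``.
    """
    ss = np.random.SeedSequence(scenario.seed)
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(6)]

    study = simulate_expression_study(scenario)
    annotation = simulate_annotation(scenario.n_genes, seed=seeds[0])
    simulate_genotypes_for_ase(
        study, annotation, scenario.strain_a, scenario.strain_b,
        n_parents_per_strain=scenario.n_replicates_per_group, seed=seeds[1],
    )

    tissues = [f"tissue{j+1}" for j in range(n_tissues - 1)] + ["liver"]
    profiles, tissue_truth = simulate_tissue_profiles(
        scenario.n_genes, n_tissues, tissue_spec_fraction, seed=seeds[2],
        tissues=tissues,
    )
    study.tissue_profiles = profiles
    study.tissue_truth = tissue_truth
    # emulate the cross-dataset merge: a second, published-style liver
    # column correlated with the local one (multiplicative log-normal noise)
    rng_liver = np.random.default_rng(seeds[2] + 1)
    published = profiles.copy()
    published["liver"] = profiles["liver"] * rng_liver.lognormal(
        0.0, 0.2, size=len(profiles)
    )
    study.tissue_profiles_published = published

    if n_pop_snps is None:
        n_pop_snps = scenario.n_genes * snps_per_gene
    placement = place_snps_in_genes(annotation, snps_per_gene)
    placement = placement.iloc[:n_pop_snps]
    rng = np.random.default_rng(seeds[3])
    gene_order = list(dict.fromkeys(placement["gene_id"]))
    sweep_genes = rng.choice(len(gene_order), size=min(n_sweeps, len(gene_order)),
                             replace=False)
    sweep_gene_ids = {gene_order[i] for i in sweep_genes}
    sweep_loci = [
        i for i, gid in enumerate(placement["gene_id"]) if gid in sweep_gene_ids
    ]
    # one displaced SNP per sweep gene (the middle one)
    per_gene = {}
    chosen = []
    for i in sweep_loci:
        gid = placement["gene_id"].iloc[i]
        per_gene.setdefault(gid, []).append(i)
    for gid, idxs in per_gene.items():
        chosen.append(idxs[len(idxs) // 2])
    study.populations = simulate_populations(
        n_pop_snps,
        drift_scale=drift_scale,
        sweep_loci=chosen,
        sweep_shift=sweep_shift,
        seed=seeds[4],
        positions=placement[["chrom", "pos"]],
    )
    study.populations["gene_id"] = placement["gene_id"].to_numpy()
    study.gene_sets["sweep_genes"] = sorted(sweep_gene_ids)

    rng_sets = np.random.default_rng(seeds[5])
    n_body = max(int(round(body_size_set_fraction * scenario.n_genes)), 1)
    body = rng_sets.choice(scenario.n_genes, size=n_body, replace=False)
    study.gene_sets["increased_body_size"] = sorted(
        f"g{i:06d}" for i in body
    )
    return study
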