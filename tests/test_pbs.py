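"""Tests of SNP QC, Weir-Cockerham FST, PBS/PBSn1 blocks and outlier calls."""

import numpy as np
import pandas as pd
import pytest

from parevol.pbs import (
    branch_transform,
    call_outliers,
    closest_gene,
    nested_retention,
    pbs_block_scan,
    pbs_from_fst,
    snp_qc,
    wc_fst,
)
from parevol.simulate import simulate_populations

from oracles import wc_fst_bruteforce


def _pop_df(rows, pops=("p1", "p2", "p3")):
    cols = ["chrom", "pos", "ref", "alt"]
    for p in pops:
        cols += [f"{p}_n", f"{p}_alt"]
    return pd.DataFrame(rows, columns=cols)


class TestSnpQC:
    SIZES = {"p1": 10, "p2": 10, "p3": 10}

    def test_monomorphic_removed(self):
        df = _pop_df([("chr1", 1, "A", "T", 20, 0, 20, 0, 20, 0)])
        assert len(snp_qc(df, ["p1", "p2", "p3"], self.SIZES)) == 0

    def test_maf_boundary_retained(self):
        # pooled MAF exactly 0.05: only frequencies < 5% are excluded
        df = _pop_df([("chr1", 1, "A", "T", 20, 1, 20, 1, 20, 1)])
        out = snp_qc(df, ["p1", "p2", "p3"], self.SIZES, maf=0.05)
        assert len(out) == 1

    def test_low_call_rate_removed(self):
        df = _pop_df([("chr1", 1, "A", "T", 10, 5, 10, 5, 10, 5)])
        assert len(snp_qc(df, ["p1", "p2", "p3"], self.SIZES,
                          call_rate=0.80)) == 0

    def test_per_population_mode_stricter(self):
        # one population at 50% call rate, others complete
        df = _pop_df([("chr1", 1, "A", "T", 10, 5, 20, 10, 20, 10)])
        pooled = snp_qc(df, ["p1", "p2", "p3"], self.SIZES, call_rate=0.80)
        per_pop = snp_qc(df, ["p1", "p2", "p3"], self.SIZES, call_rate=0.80,
                         per_population=True)
        assert len(pooled) == 1 and len(per_pop) == 0


class TestWcFst:
    def test_fixed_difference_is_one(self):
        assert wc_fst(20, 0, 20, 20) == pytest.approx(1.0)
        assert wc_fst(50, 50, 50, 0) == pytest.approx(1.0)

    def test_shared_monomorphism_is_nan(self):
        assert np.isnan(wc_fst(20, 0, 20, 0))
        assert np.isnan(wc_fst(20, 20, 20, 20))

    def test_worked_instance_matches_oracle(self):
        got = wc_fst(20, 8, 20, 2)
        assert got == pytest.approx(wc_fst_bruteforce(20, 8, 20, 2),
                                    abs=1e-12)

    def test_random_instances_match_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(200):
            n1 = 2 * int(rng.integers(2, 40))
            n2 = 2 * int(rng.integers(2, 40))
            a1 = int(rng.integers(0, n1 + 1))
            a2 = int(rng.integers(0, n2 + 1))
            ours = wc_fst(n1, a1, n2, a2)
            ref = wc_fst_bruteforce(n1, a1, n2, a2)
            if np.isnan(ref):
                assert np.isnan(ours)
            else:
                assert ours == pytest.approx(ref, abs=1e-12)

    def test_observed_heterozygosity_override(self):
        # passing the HWE heterozygosities explicitly reproduces the
        # default exactly; a different observed value changes the estimate
        p1, p2 = 10 / 40, 30 / 40
        hwe = wc_fst(40, 10, 40, 30)
        explicit = wc_fst(40, 10, 40, 30, het_a=2 * p1 * (1 - p1),
                          het_b=2 * p2 * (1 - p2))
        assert explicit == pytest.approx(hwe, abs=1e-15)
        assert wc_fst(40, 10, 40, 30, het_a=0.0, het_b=0.0) != hwe


class TestBranchTransform:
    @pytest.mark.parametrize(
        "fst, expected",
        [(0.0, 0.0), (0.5, np.log(2.0)), (-0.02, 0.0)],
    )
    def test_values(self, fst, expected):
        assert branch_transform(fst) == pytest.approx(expected, abs=1e-12)

    def test_complete_fixation_finite(self):
        assert np.isfinite(branch_transform(1.0))

    def test_nan_propagates(self):
        assert np.isnan(branch_transform(np.nan))


class TestPbsFromFst:
    def test_zero_fst_gives_zero(self):
        out = pbs_from_fst(0.0, 0.0, 0.0)
        assert out["pbs1"] == 0.0 and out["pbsn1"] == 0.0

    def test_worked_formula_evaluation(self):
        # T = (ln2, ln2, 0); pbs1 = ln2, pbs2 = pbs3 = 0;
        # pbsn1 = ln2 / (1 + ln2)
        out = pbs_from_fst(0.5, 0.5, 0.0)
        assert out["pbs1"] == pytest.approx(np.log(2), abs=1e-12)
        assert out["pbs2"] == pytest.approx(0.0, abs=1e-12)
        assert out["pbsn1"] == pytest.approx(np.log(2) / (1 + np.log(2)),
                                             abs=1e-9)


def _scan_input(n, rng, pops=("p1", "p2", "p3"), chrom="chr1"):
    rows = []
    for i in range(n):
        row = [chrom, 100 * (i + 1), "A", "T"]
        for _ in pops:
            row += [40, int(rng.integers(5, 36))]
        rows.append(row)
    return _pop_df(rows, pops)


class TestBlockScan:
    def test_identical_populations_give_zero_pbs(self):
        rows = []
        for i in range(10):
            alt = 10 + i
            rows.append(["chr1", 100 * (i + 1), "A", "T",
                         40, alt, 40, alt, 40, alt])
        blocks = pbs_block_scan(_pop_df(rows), "p1", "p2", "p3")
        # identical allele counts: FST <= 0 everywhere, clamped to T = 0
        assert len(blocks) == 2
        np.testing.assert_allclose(blocks["pbsn1"], 0.0, atol=1e-12)

    def test_trailing_snps_dropped(self):
        rng = np.random.default_rng(8)
        blocks = pbs_block_scan(_scan_input(12, rng), "p1", "p2", "p3")
        assert len(blocks) == 2

    def test_short_chromosome_warns(self):
        rng = np.random.default_rng(9)
        with pytest.warns(UserWarning):
            blocks = pbs_block_scan(_scan_input(4, rng), "p1", "p2", "p3")
        assert blocks.empty

    def test_blocks_never_span_chromosomes(self):
        rng = np.random.default_rng(10)
        df = pd.concat(
            [_scan_input(7, rng, chrom="chr1"),
             _scan_input(8, rng, chrom="chr2")]
        )
        blocks = pbs_block_scan(df, "p1", "p2", "p3")
        assert list(blocks["chrom"]) == ["chr1", "chr2"]

    def test_population_permutation_consistency(self):
        rng = np.random.default_rng(11)
        df = _scan_input(10, rng)
        b1 = pbs_block_scan(df, "p1", "p2", "p3")
        b2 = pbs_block_scan(df, "p2", "p1", "p3")
        np.testing.assert_allclose(b1["pbs2"], b2["pbs1"], atol=1e-12)
        np.testing.assert_allclose(b1["pbs1"], b2["pbs2"], atol=1e-12)

    def test_input_order_invariance(self):
        rng = np.random.default_rng(12)
        df = _scan_input(15, rng)
        shuffled = df.sample(frac=1, random_state=1)
        pd.testing.assert_frame_equal(
            pbs_block_scan(df, "p1", "p2", "p3"),
            pbs_block_scan(shuffled, "p1", "p2", "p3"),
        )

    def test_pbs_identity_per_block(self):
        rng = np.random.default_rng(13)
        blocks = pbs_block_scan(_scan_input(25, rng), "p1", "p2", "p3")
        lhs = blocks["pbs1"]
        rhs = (blocks["t12"] + blocks["t13"] - blocks["t23"]) / 2.0
        np.testing.assert_allclose(lhs, rhs, atol=1e-14)


ANNOT = pd.DataFrame(
    {"chrom": ["chr1", "chr1", "chr2"], "start": [200, 1000, 0],
     "end": [300, 1200, 500], "gene_id": ["gA", "gB", "gC"]}
)


class TestClosestGene:
    def test_overlapping_block(self):
        gene, dist = closest_gene("chr1", 250, 260, ANNOT)
        assert (gene, dist) == ("gA", 0)

    def test_halfopen_distance_arithmetic(self):
        # block [100,110) (positions 101..110), gene [200,300): gap 90
        gene, dist = closest_gene("chr1", 101, 110, ANNOT)
        assert (gene, dist) == ("gA", 90)

    def test_equidistant_tie_leftmost(self):
        # block centred between gA (end 300) and gB (start 1000)
        gene, dist = closest_gene("chr1", 646, 655, ANNOT)
        # gaps: 645-300 = 345 to gA, 1000-655 = 345 to gB
        assert gene == "gA" and dist == 345

    def test_missing_chromosome_warns(self):
        with pytest.warns(UserWarning):
            gene, dist = closest_gene("chrX", 1, 10, ANNOT)
        assert gene is None


class TestOutliersAndRetention:
    def test_top_fraction_with_ties(self):
        rng = np.random.default_rng(14)
        blocks = pd.DataFrame({"pbsn1": rng.uniform(size=100)})
        out, _ = call_outliers(blocks, 0.05)
        assert len(out) >= 5

    def test_all_equal_selects_everything(self):
        blocks = pd.DataFrame({"pbsn1": np.full(20, 0.3)})
        with pytest.warns(UserWarning):
            out, _ = call_outliers(blocks, 0.05)
        assert len(out) == 20

    def test_retention_bounds(self):
        assert nested_retention({"a", "b"}, {"a", "b"})[1] == 1.0
        assert nested_retention({"a", "b"}, {"c"})[1] == 0.0
        assert np.isnan(nested_retention(set(), {"a"})[1])

    def test_shared_ancestry_lowers_nested_retention(self):
        # sweeps confined to the focal lineage survive the nested test;
        # sweeps predating the focal/sister split do not
        def retention(sweep_pops):
            pop = simulate_populations(
                3000, drift_scale=0.05, sweep_loci=range(0, 300, 10),
                sweep_shift=0.95, seed=15, sweep_populations=sweep_pops,
            )
            pops = ["focal", "sister", "out1", "out2"]
            primary = pbs_block_scan(pop, "focal", "out1", "out2")
            nested = pbs_block_scan(pop, "focal", "sister", "out2")
            po, _ = call_outliers(primary, 0.02)
            no, _ = call_outliers(nested, 0.02)
            return nested_retention(set(po["block_id"]),
                                    set(no["block_id"]))[1]

        focal_only = retention(("focal",))
        predating = retention(("focal", "sister"))
        assert focal_only > predating
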