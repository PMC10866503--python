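"""Tests of informative-SNP selection, trio tests and regulatory calls."""

import itertools

import numpy as np
import pandas as pd
import pytest

from parevol import ase, simulate
from parevol.ase import (
    CATEGORIES,
    GenotypeMatrix,
    HET,
    HOM_ALT,
    HOM_REF,
    MISSING,
    allele_counts_per_gene,
    classify_regulatory,
    effect_size_compare,
    mapping_bias_check,
    select_informative_snps,
    trio_tests,
)

from conftest import make_count_matrix


def make_genotypes(rows, n_a=4, n_b=4, n_f1=3):
    """GenotypeMatrix from per-SNP genotype-code lists (A..., B..., F1...)."""
    samples = (
        [f"A{i}" for i in range(n_a)]
        + [f"B{i}" for i in range(n_b)]
        + [f"F{i}" for i in range(n_f1)]
    )
    groups = pd.Series(["A"] * n_a + ["B"] * n_b + ["F1"] * n_f1,
                       index=pd.Index(samples))
    snps = pd.DataFrame(
        {"chrom": "chr1", "pos": 100 * (np.arange(len(rows)) + 1),
         "ref": "A", "alt": "T"}
    )
    return GenotypeMatrix(
        snps, pd.DataFrame(np.array(rows), columns=samples), groups
    )


class TestInformativeSnps:
    def test_fixed_different_het_f1_retained(self):
        gm = make_genotypes([[HOM_REF] * 4 + [HOM_ALT] * 4 + [HET] * 3])
        out = select_informative_snps(gm, "A", "B")
        assert len(out) == 1
        assert out.loc[0, "ref_parent"] == "A"
        assert out.loc[0, "alt_parent"] == "B"

    def test_segregating_parent_dropped(self):
        gm = make_genotypes(
            [[HOM_REF, HOM_REF, HET, HOM_REF] + [HOM_ALT] * 4 + [HET] * 3]
        )
        with pytest.warns(UserWarning):
            assert len(select_informative_snps(gm, "A", "B")) == 0

    def test_homozygous_f1_dropped(self):
        gm = make_genotypes(
            [[HOM_REF] * 4 + [HOM_ALT] * 4 + [HET, HET, HOM_ALT]]
        )
        with pytest.warns(UserWarning):
            assert len(select_informative_snps(gm, "A", "B")) == 0

    def test_call_rate_boundary_inclusive(self):
        # 3 of 4 parent-A calls = 0.75 < 0.85 -> dropped; at threshold
        # 0.75 the same SNP is retained (>= comparison)
        row = [[MISSING, HOM_REF, HOM_REF, HOM_REF] + [HOM_ALT] * 4 + [HET] * 3]
        gm = make_genotypes(row)
        with pytest.warns(UserWarning):
            assert len(select_informative_snps(gm, "A", "B", 0.85)) == 0
        assert len(select_informative_snps(gm, "A", "B", 0.75)) == 1

    def test_reversed_phase_recorded(self):
        gm = make_genotypes([[HOM_ALT] * 4 + [HOM_REF] * 4 + [HET] * 3])
        out = select_informative_snps(gm, "A", "B")
        assert out.loc[0, "ref_parent"] == "B"

    def test_recovers_planted_truth(self, small_study):
        inf = select_informative_snps(small_study.genotypes, "NORTH", "SOUTH")
        truth = small_study.informative_truth
        expected = truth[truth["informative"]]
        got = set(zip(inf["chrom"], inf["pos"]))
        assert got == set(zip(expected["chrom"], expected["pos"]))
        merged = inf.merge(expected, on=["chrom", "pos"])
        assert (merged["ref_parent_x"] == merged["ref_parent_y"]).all()


def _phasing(rows):
    return pd.DataFrame(
        rows, columns=["chrom", "pos", "ref", "alt", "ref_parent",
                       "alt_parent"]
    )


ANNOT = pd.DataFrame(
    {"chrom": ["chr1", "chr1"], "start": [0, 1000], "end": [500, 1500],
     "gene_id": ["gX", "gY"], "score": 0, "strand": "+"}
)


class TestAlleleCountsPerGene:
    def test_single_snp_phase_assignment(self):
        inf = _phasing([("chr1", 100, "A", "T", "P1", "P2")])
        snp_counts = pd.DataFrame(
            {"chrom": ["chr1"], "pos": [100], "individual": ["F1_1"],
             "ref_reads": [30], "alt_reads": [10]}
        )
        cm = allele_counts_per_gene(snp_counts, inf, ANNOT)
        assert cm.counts.loc["gX", "F1_1|P1"] == 30
        assert cm.counts.loc["gX", "F1_1|P2"] == 10

    def test_two_snps_additive(self):
        inf = _phasing([
            ("chr1", 100, "A", "T", "P1", "P2"),
            ("chr1", 200, "A", "T", "P2", "P1"),  # opposite phase
        ])
        snp_counts = pd.DataFrame(
            {"chrom": ["chr1", "chr1"], "pos": [100, 200],
             "individual": ["F1_1", "F1_1"],
             "ref_reads": [30, 5], "alt_reads": [10, 20]}
        )
        cm = allele_counts_per_gene(snp_counts, inf, ANNOT)
        assert cm.counts.loc["gX", "F1_1|P1"] == 30 + 20
        assert cm.counts.loc["gX", "F1_1|P2"] == 10 + 5

    def test_gene_without_informative_snps_absent(self):
        inf = _phasing([("chr1", 100, "A", "T", "P1", "P2")])
        snp_counts = pd.DataFrame(
            {"chrom": ["chr1"], "pos": [100], "individual": ["F1_1"],
             "ref_reads": [3], "alt_reads": [4]}
        )
        cm = allele_counts_per_gene(snp_counts, inf, ANNOT)
        assert "gY" not in cm.gene_ids

    def test_aggregation_matches_gene_level_truth(self, small_study):
        inf = select_informative_snps(small_study.genotypes, "NORTH", "SOUTH")
        cm = allele_counts_per_gene(
            small_study.snp_allele_counts, inf, small_study.annotation
        )
        truth = small_study.f1_allele_counts.counts
        shared = cm.gene_ids
        diff = (cm.counts.loc[shared] - truth.loc[shared, cm.counts.columns])
        assert diff.abs().to_numpy().max() == 0


class TestTrioTests:
    @staticmethod
    def _fixture(rng, par_ratio, allele_ratio, n_signal=40, n_bg=120,
                 depth=1000.0):
        """Signal genes with the given parent/allele ratios over an
        equal-expression background that anchors the normalization."""
        n = n_signal + n_bg
        par_mu = np.full((n, 6), depth)
        par_mu[:n_signal, :3] *= par_ratio
        f1_mu = np.full((n, 6), depth / 2)
        f1_mu[:n_signal, ::2] *= allele_ratio
        par = make_count_matrix(
            rng.poisson(par_mu), ["A"] * 3 + ["B"] * 3
        )
        f1 = make_count_matrix(
            rng.poisson(f1_mu), ["A", "B"] * 3, generation="F1",
            allele_of_origin=["A", "B"] * 3,
            individual=[f"I{j // 2}" for j in range(6)],
        )
        return par, f1

    def test_equal_ratios_give_nonsignificant_t(self):
        # parents 2:1 and F1 alleles 2:1 -> cis pattern, no trans effect
        par, f1 = self._fixture(np.random.default_rng(0), 2.0, 2.0)
        trio = trio_tests(par, f1, ("A", "B")).iloc[:40]
        assert (trio["T_pvalue"] > 0.05).mean() > 0.9
        assert trio["P_padj"].lt(0.05).mean() > 0.9
        assert trio["H_padj"].lt(0.05).mean() > 0.9

    def test_pure_trans_pattern(self):
        # parents 4:1, F1 alleles 1:1 at depth ~1000
        par, f1 = self._fixture(np.random.default_rng(1), 4.0, 1.0)
        trio = trio_tests(par, f1, ("A", "B")).iloc[:40]
        assert trio["P_padj"].lt(0.05).mean() > 0.9
        assert trio["T_padj"].lt(0.05).mean() > 0.9
        assert trio["H_padj"].ge(0.05).mean() > 0.8

    def test_all_equal_counts_nonsignificant(self):
        rng = np.random.default_rng(2)
        par = make_count_matrix(
            rng.poisson(500, size=(30, 6)), ["A"] * 3 + ["B"] * 3
        )
        f1 = make_count_matrix(
            rng.poisson(250, size=(30, 6)), ["A", "B"] * 3,
            generation="F1", allele_of_origin=["A", "B"] * 3,
            individual=[f"I{j // 2}" for j in range(6)],
        )
        trio = trio_tests(par, f1, ("A", "B"))
        for fam in ("P", "H", "T"):
            assert (trio[f"{fam}_padj"] < 0.05).mean() < 0.1

    def test_low_count_genes_excluded(self):
        par = make_count_matrix(
            [[2, 3, 1, 2, 4, 1], [100] * 6], ["A"] * 3 + ["B"] * 3
        )
        f1 = make_count_matrix(
            [[1, 2, 0, 1, 2, 3], [50] * 6], ["A", "B"] * 3,
            generation="F1", allele_of_origin=["A", "B"] * 3,
            individual=[f"I{j // 2}" for j in range(6)],
        )
        trio = trio_tests(par, f1, ("A", "B"), min_mean=10)
        assert list(trio.index) == ["g001"]


def _trio_row(p, h, t, dir_p=1.0, dir_h=1.0):
    return pd.DataFrame(
        {
            "P_log2fc": [dir_p], "P_pvalue": [p], "P_padj": [p],
            "H_log2fc": [dir_h], "H_pvalue": [h], "H_padj": [h],
            "T_stat": [1.0], "T_pvalue": [t], "T_padj": [t],
        },
        index=["g"],
    )


class TestClassification:
    @pytest.mark.parametrize(
        "sig, same_dir, expected",
        [
            ((True, True, False), True, "cis_only"),
            ((True, False, True), True, "trans_only"),
            ((True, True, True), True, "cis_plus_trans"),
            ((True, True, True), False, "cis_times_trans"),
            ((False, True, True), True, "compensatory"),
            ((False, False, False), True, "conserved"),
            ((False, False, True), True, "ambiguous"),
            ((True, False, False), True, "ambiguous"),
            ((False, True, False), True, "ambiguous"),
        ],
    )
    def test_decision_table(self, sig, same_dir, expected):
        p, h, t = (0.01 if s else 0.5 for s in sig)
        trio = _trio_row(p, h, t, dir_p=1.0, dir_h=1.0 if same_dir else -1.0)
        assert classify_regulatory(trio).iloc[0] == expected

    def test_all_patterns_map_to_exactly_one_category(self):
        # exhaustiveness: 8 significance patterns x 2 direction states
        for sp, sh, st_, same in itertools.product(
            [True, False], repeat=4
        ):
            trio = _trio_row(
                0.01 if sp else 0.5, 0.01 if sh else 0.5,
                0.01 if st_ else 0.5, 1.0, 1.0 if same else -1.0,
            )
            cat = classify_regulatory(trio).iloc[0]
            assert cat in CATEGORIES

    def test_missing_tests_are_ambiguous(self):
        trio = _trio_row(0.01, np.nan, 0.01)
        assert classify_regulatory(trio).iloc[0] == "ambiguous"

    def test_zero_direction_ties_go_to_cis_plus_trans(self):
        trio = _trio_row(0.01, 0.01, 0.01, dir_p=0.0, dir_h=1.0)
        assert classify_regulatory(trio).iloc[0] == "cis_plus_trans"

    def test_parent_label_reversal_keeps_categories(self, small_study):
        inf = select_informative_snps(small_study.genotypes, "NORTH", "SOUTH")
        cm = allele_counts_per_gene(
            small_study.snp_allele_counts, inf, small_study.annotation
        )
        fwd = trio_tests(small_study.parental_counts, cm, ("NORTH", "SOUTH"))
        rev = trio_tests(small_study.parental_counts, cm, ("SOUTH", "NORTH"))
        c_fwd = classify_regulatory(fwd)
        c_rev = classify_regulatory(rev)
        assert (c_fwd == c_rev).mean() > 0.97

    def test_conserved_null_misclassification_bounded(self, null_study):
        inf = select_informative_snps(null_study.genotypes, "NORTH", "SOUTH")
        cm = allele_counts_per_gene(
            null_study.snp_allele_counts, inf, null_study.annotation
        )
        trio = trio_tests(null_study.parental_counts, cm, ("NORTH", "SOUTH"))
        calls = classify_regulatory(trio, fdr=0.05)
        assert (calls != "conserved").mean() <= 2 * 0.05


class TestDiagnostics:
    def test_balanced_counts_give_half_ratio(self):
        f1 = make_count_matrix(
            [[100, 100, 80, 80], [50, 50, 20, 20]],
            ["A", "B", "A", "B"], generation="F1",
            allele_of_origin=["A", "B", "A", "B"],
            individual=["I1", "I1", "I2", "I2"],
        )
        ratio, res = mapping_bias_check(f1, "A")
        assert (ratio == 0.5).all()
        assert res.p_value == 1.0

    def test_strong_bias_detected_at_depth(self):
        rng = np.random.default_rng(3)
        counts = np.empty((20, 12), dtype=int)
        for j in range(6):
            counts[:, 2 * j] = rng.poisson(6000, 20)      # 60%
            counts[:, 2 * j + 1] = rng.poisson(4000, 20)  # 40%
        f1 = make_count_matrix(
            counts, ["A", "B"] * 6, generation="F1",
            allele_of_origin=["A", "B"] * 6,
            individual=[f"I{j // 2}" for j in range(12)],
        )
        _, res = mapping_bias_check(f1, "A")
        assert res.p_value < 1e-4

    def test_empty_gene_rows_ignored(self):
        f1 = make_count_matrix(
            [[0, 0, 0, 0], [30, 30, 30, 10]],
            ["A", "B", "A", "B"], generation="F1",
            allele_of_origin=["A", "B", "A", "B"],
            individual=["I1", "I1", "I2", "I2"],
        )
        ratio, _ = mapping_bias_check(f1, "A")
        assert ratio["I1"] == pytest.approx(0.5)
        assert ratio["I2"] == pytest.approx(0.75)

    def test_cis_effects_larger_than_trans(self):
        sc = simulate.RegulatoryScenario(
            400,
            mode_fractions={"cis_only": 0.3, "trans_only": 0.3,
                            "conserved": 0.4},
            cis_effect_log2=3.0, trans_effect_log2=1.5, seed=61,
        )
        study = simulate.simulate_expression_study(sc)
        from parevol.diffexpr import nb_wald

        de = nb_wald(study.parental_counts, ("NORTH", "SOUTH"))
        res = effect_size_compare(
            study.true_modes, de, "cis_only", "trans_only"
        )
        assert res.statistic > 3
        assert res.p_value < 1e-3
        assert res.df != int(res.df)  # Welch df is fractional

    def test_small_category_rejected(self, small_study):
        calls = pd.Series(["cis_only"] + ["conserved"] * 9,
                          index=[f"g{i:06d}" for i in range(10)])
        de = pd.DataFrame({"log2FoldChange": np.ones(10)}, index=calls.index)
        with pytest.raises(ValueError):
            effect_size_compare(calls, de, "cis_only", "conserved")
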