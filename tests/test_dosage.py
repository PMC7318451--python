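"""Gene CN annotation, population matrix, V_ST, and dosage correlation."""

import numpy as np
import pandas as pd
import pytest
from statsmodels.stats.multitest import multipletests

import copyvar as cv
from copyvar.calling import CNVCall
from copyvar.depth import BinDepthTrack, compute_cn_index
from copyvar.dosage import (
    GeneModel,
    annotate_gene_copy_numbers,
    build_population_matrix,
    correlate_dosage,
    expression_increase_rates,
    read_gene_models,
    select_genes_for_correlation,
    tandem_flags,
    vst,
)
from oracles import bh_adjust_oracle


def dup_call(start, end, cn=3):
    return CNVCall("chr1", start, end, "DUP", cn, float(cn), (end - start) // 250)


def del_call(start, end):
    return CNVCall("chr1", start, end, "DEL", 0, 0.05, (end - start) // 250)


class TestAnnotation:
    def test_gene_sixty_percent_covered_takes_call_cn(self):
        gene = GeneModel("g1", "chr1", 1000, 2000)
        cn = annotate_gene_copy_numbers([dup_call(900, 1600)], [gene])
        assert cn["g1"] == 3

    def test_gene_forty_percent_covered_stays_normal(self):
        gene = GeneModel("g1", "chr1", 1000, 2000)
        cn = annotate_gene_copy_numbers([del_call(1000, 1400)], [gene])
        assert cn["g1"] == 1

    def test_overlapping_same_type_calls_sum_coverage(self):
        gene = GeneModel("g1", "chr1", 1000, 2000)
        calls = [dup_call(1000, 1300, cn=2), dup_call(1600, 1900, cn=3)]
        cn = annotate_gene_copy_numbers(calls, [gene])
        assert cn["g1"] in (2, 3)  # covered 60% in total; highest overlap wins

    def test_cn_zero_rescued_when_depth_disagrees(self):
        gene = GeneModel("g1", "chr1", 0, 1000)
        track = compute_cn_index(
            BinDepthTrack("chr1", 250, np.array([30.0, 35.0, 30.0, 25.0, 30.0, 30.0]))
        )
        cn = annotate_gene_copy_numbers(
            [del_call(0, 1000)], [gene], track_by_chrom={"chr1": track}
        )
        assert cn["g1"] == 1

    def test_transposon_genes_excluded(self):
        gene = GeneModel("te1", "chr1", 1000, 2000, is_transposon=True)
        assert annotate_gene_copy_numbers([dup_call(900, 2100)], [gene]) == {}

    def test_gff3_reader_flags_transposons(self, tmp_path):
        gff = tmp_path / "genes.gff3"
        gff.write_text(
            "##gff-version 3\n"
            "chr1\ttest\tgene\t1001\t2000\t.\t+\t.\tID=g1;Note=protein coding\n"
            "chr1\ttest\tgene\t3001\t4000\t.\t-\t.\tID=te1;Note=transposon protein\n"
        )
        genes = read_gene_models(gff)
        assert [(g.gene_id, g.start, g.end, g.is_transposon) for g in genes] == [
            ("g1", 1000, 2000, False),
            ("te1", 3000, 4000, True),
        ]


class TestPopulationMatrix:
    def test_single_accession_matrix_equals_vector(self):
        m = build_population_matrix({"acc1": {"g1": 3, "g2": 0}})
        assert m.cn.loc["g1", "acc1"] == 3 and m.cn.loc["g2", "acc1"] == 0

    def test_genotype_encodings(self):
        m = build_population_matrix(
            {"a1": {"g1": 3, "g2": 0}, "a2": {"g1": 1, "g2": 1}}
        )
        assert m.duplication_genotypes().loc["g1"].tolist() == [1, 0]
        assert m.deletion_genotypes().loc["g2"].tolist() == [1, 0]

    def test_missing_entries_default_to_one(self):
        m = build_population_matrix(
            {"a1": {"g1": 2}, "a2": {}}, gene_universe=["g1", "g2"]
        )
        assert m.cn.loc["g2", "a1"] == 1 and m.cn.loc["g1", "a2"] == 1

    def test_no_cnvs_gives_all_ones_all_zero_genotypes(self):
        m = build_population_matrix({"a1": {}}, gene_universe=["g1", "g2"])
        assert (m.cn == 1).all().all()
        assert (m.duplication_genotypes() == 0).all().all()

    def test_fold_over_positive_values_only(self):
        m = build_population_matrix(
            {"a1": {"g1": 0, "g2": 2}, "a2": {"g1": 1, "g2": 1}}
        )
        folds = m.change_fold()
        assert folds["g1"] == 1.0  # 0/1 gene: fold over positive CNs only
        assert folds["g2"] == 2.0


class TestVst:
    def test_identical_populations_give_zero(self, rng):
        values = np.concatenate([rng.normal(2, 1, 50), rng.normal(2, 1, 50)])
        labels = np.array(["p1"] * 50 + ["p2"] * 50)
        assert vst(values, labels) < 0.05

    def test_disjoint_constant_populations_give_one(self):
        values = np.array([1, 1, 1, 3, 3, 3], dtype=float)
        labels = np.array(["p1"] * 3 + ["p2"] * 3)
        assert vst(values, labels) == 1.0

    def test_hand_computed_value(self):
        # pop1 = {1,1,2}, pop2 = {2,3,3}: V_T = 0.8, V_S = 1/3 -> 0.58333
        values = np.array([1, 1, 2, 2, 3, 3], dtype=float)
        labels = np.array(["p1"] * 3 + ["p2"] * 3)
        assert vst(values, labels) == pytest.approx((0.8 - 1 / 3) / 0.8)

    def test_bounds_and_affine_invariance(self, rng):
        for _ in range(20):
            values = rng.normal(0, 1, 40)
            labels = rng.choice(["p1", "p2"], size=40)
            if min((labels == p).sum() for p in ("p1", "p2")) < 2:
                continue
            v = vst(values, labels)
            assert 0.0 <= v <= 1.0
            assert vst(3.0 * values - 7.0, labels) == pytest.approx(v)

    def test_zero_total_variance_defined_as_zero(self):
        assert vst(np.ones(6), np.array(["a"] * 3 + ["b"] * 3)) == 0.0

    def test_single_population_rejected(self):
        with pytest.raises(ValueError):
            vst(np.arange(4.0), np.array(["a"] * 4))


def _matrix_and_tpm(cn_rows, tpm_rows, genes=None, accs=None):
    genes = genes or [f"g{i}" for i in range(len(cn_rows))]
    accs = accs or [f"a{i}" for i in range(len(cn_rows[0]))]
    from copyvar.dosage import GeneCopyNumberMatrix

    cn = pd.DataFrame(cn_rows, index=genes, columns=accs, dtype=int)
    tpm = pd.DataFrame(tpm_rows, index=genes, columns=accs, dtype=float)
    return GeneCopyNumberMatrix(cn), tpm


class TestSelection:
    def test_low_fold_gene_excluded(self):
        # all CNs equal -> fold 1.0 < 1.1
        m, tpm = _matrix_and_tpm([[2] * 8], [[5.0] * 8])
        assert select_genes_for_correlation(m, tpm) == {}

    def test_small_cn_group_dropped_and_gene_excluded(self):
        cn = [[1] * 10 + [2] * 2]
        m, tpm = _matrix_and_tpm(cn, [list(range(12))])
        assert select_genes_for_correlation(m, tpm) == {}

    def test_two_types_with_smaller_zero_discarded(self):
        cn = [[0] * 5 + [1] * 5]
        m, tpm = _matrix_and_tpm(cn, [list(range(10))])
        assert select_genes_for_correlation(m, tpm) == {}

    def test_outlier_tpm_pairs_dropped(self):
        cn = [[1] * 10 + [2] * 10]
        tpm_vals = [10.0] * 10 + [20.0] * 9 + [500.0]
        m, tpm = _matrix_and_tpm(cn, [tpm_vals])
        grouped = select_genes_for_correlation(m, tpm)
        assert len(grouped["g0"]) == 19  # the 500 TPM outlier is gone

    def test_vst_filter_removes_structured_genes(self):
        cn = [[1] * 10 + [3] * 10, [1, 3] * 10]
        tpm_rows = [list(range(20)), list(range(20))]
        m, tpm = _matrix_and_tpm(cn, tpm_rows)
        labels = {f"a{i}": ("p1" if i < 10 else "p2") for i in range(20)}
        grouped = select_genes_for_correlation(m, tpm, population_labels=labels)
        assert "g0" not in grouped  # CN perfectly splits with population
        assert "g1" in grouped

    def test_selection_is_idempotent(self):
        cn = [[1] * 6 + [2] * 6 + [3] * 6]
        tpm_vals = [[float(10 + i) for i in range(18)]]
        m, tpm = _matrix_and_tpm(cn, tpm_vals)
        g1 = select_genes_for_correlation(m, tpm)
        # re-feed the surviving pairs as a fresh matrix/tpm
        df = g1["g0"]
        m2, tpm2 = _matrix_and_tpm(
            [df["cn"].tolist()], [df["tpm"].tolist()],
            genes=["g0"], accs=df["accession"].tolist(),
        )
        g2 = select_genes_for_correlation(m2, tpm2)
        assert g2["g0"]["cn"].tolist() == df["cn"].tolist()


class TestCorrelation:
    def test_exact_dosage_classified_positive(self):
        cn = [[1] * 5 + [2] * 5 + [3] * 5]
        tpm = [[2.0 * c for c in cn[0]]]
        m, t = _matrix_and_tpm(cn, tpm)
        grouped = select_genes_for_correlation(m, t)
        res = correlate_dosage(grouped)
        assert res.table.loc["g0", "class"] == "positive"

    def test_constant_tpm_skipped_or_nonsignificant(self):
        grouped = {
            "g0": pd.DataFrame(
                {"accession": list("abcdef"), "cn": [1, 1, 1, 2, 2, 2], "tpm": [5.0] * 6}
            )
        }
        res = correlate_dosage(grouped)
        assert len(res.table) == 0  # zero TPM variance -> skipped

    def test_bh_adjustment_matches_stepup_oracle(self, rng):
        pvals = rng.uniform(0, 1, size=100)
        ours = multipletests(pvals, method="fdr_bh")[1]
        assert np.allclose(ours, bh_adjust_oracle(pvals))

    def test_negative_slope_recovered(self):
        rng = np.random.default_rng(5)
        cn_row = [1] * 15 + [2] * 15
        cn = pd.DataFrame([cn_row], index=["g0"], columns=[f"a{i}" for i in range(30)])
        tpm = cv.simulate_dosage_expression(cn, {"g0": (-10.0, 2.0, 50.0)}, seed=5)
        from copyvar.dosage import GeneCopyNumberMatrix

        grouped = select_genes_for_correlation(GeneCopyNumberMatrix(cn), tpm)
        res = correlate_dosage(grouped)
        assert res.table.loc["g0", "class"] == "negative"


class TestIncreaseRates:
    def test_dupcn1_arithmetic(self):
        df = pd.DataFrame({"cn": [1] * 3 + [2] * 3, "tpm": [10.0] * 3 + [15.0] * 3})
        rates = expression_increase_rates(df)
        assert rates.loc[rates.cn == 2, "dup_cn1_pct"].item() == pytest.approx(50.0)

    def test_addcn1_uses_cn1_denominator(self):
        df = pd.DataFrame(
            {"cn": [1] * 3 + [2] * 3 + [3] * 3, "tpm": [10.0] * 3 + [15.0] * 3 + [18.0] * 3}
        )
        rates = expression_increase_rates(df)
        assert rates.loc[rates.cn == 3, "add_cn1_pct"].item() == pytest.approx(30.0)

    def test_flat_means_give_zero_rates(self):
        df = pd.DataFrame({"cn": [1] * 3 + [2] * 3, "tpm": [10.0] * 6})
        rates = expression_increase_rates(df)
        assert rates["dup_cn1_pct"].item() == 0.0

    def test_zero_cn1_mean_flagged(self):
        df = pd.DataFrame({"cn": [1, 1, 2, 2], "tpm": [0.0, 0.0, 5.0, 5.0]})
        with pytest.raises(ValueError, match="undefined"):
            expression_increase_rates(df)

    def test_tandem_labels(self):
        flags = tandem_flags(
            {
                "g1": [("chr1", 1000), ("chr1", 20_000)],
                "g2": [("chr1", 1000), ("chr2", 1000)],
                "g3": [("chr1", 1000), ("chr1", 90_000)],
            }
        )
        assert flags == {"g1": True, "g2": False, "g3": False}
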