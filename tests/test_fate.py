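"""Ka/Ks, age staging, fate classification, and copy expression."""

from collections import Counter

import numpy as np
import pytest

from copyvar.fate import (
    DuplicatePair,
    FateConfig,
    STAGES,
    assign_parent_offspring,
    build_fate_table,
    classify_gene_fate,
    divergence_time_and_stage,
    fate_table_from_counts,
    find_csvs_and_split_expression,
    jukes_cantor,
    nei_gojobori_kaks,
)
from copyvar.simulate import mutate_cds_pair, random_cds
from oracles import nei_gojobori_oracle


BASE_CDS = (
    "ATGGCTGACTTTAAACCCGGGTTGACGGAACAGCATATCGATCGTAGCTGGCTGAGCTTC"
    "AAAGTTGGCCGCGATATGGAGCTGGATCGTACGGCATTCGAACTGATGAAGCTGGTTCAG"
    "GACCCGATTGCTGAAGGTCGTGAACTGGCATCTCGTATGGGTATCGAACTGGCTGAAGCT"
)


class TestNeiGojobori:
    def test_identical_sequences(self):
        ka, ks, ratio = nei_gojobori_kaks(BASE_CDS, BASE_CDS)
        assert ka == 0.0 and ks == 0.0 and ratio is None

    def test_pure_synonymous_pair_has_zero_ka(self):
        a, b = mutate_cds_pair(BASE_CDS, 2, 0, seed=1)
        ka, ks, _ = nei_gojobori_kaks(a, b)
        assert ka == 0.0 and ks > 0.0

    def test_pure_nonsynonymous_pair_has_zero_ks(self):
        a, b = mutate_cds_pair(BASE_CDS, 0, 3, seed=2)
        ka, ks, ratio = nei_gojobori_kaks(a, b)
        assert ks == 0.0 and ka > 0.0 and ratio is None

    def test_matches_enumeration_oracle_on_fixture(self):
        a, b = mutate_cds_pair(BASE_CDS, 2, 1, seed=3)
        ka, ks, _ = nei_gojobori_kaks(a, b)
        oka, oks = nei_gojobori_oracle(a, b)
        assert ka == pytest.approx(oka, abs=1e-9)
        assert ks == pytest.approx(oks, abs=1e-9)

    def test_matches_oracle_with_multi_hit_codons(self):
        # force two substitutions inside one codon -> pathway averaging
        a = "ATG" + "TTA" + "GGG" * 48
        b = "ATG" + "CTG" + "GGG" * 48  # TTA->CTG: 2 changes, both Leu
        ka, ks, _ = nei_gojobori_kaks(a, b)
        oka, oks = nei_gojobori_oracle(a, b)
        assert ka == pytest.approx(oka, abs=1e-9)
        assert ks == pytest.approx(oks, abs=1e-9)

    def test_symmetric_in_arguments(self):
        a, b = mutate_cds_pair(BASE_CDS, 3, 2, seed=4)
        assert nei_gojobori_kaks(a, b)[:2] == nei_gojobori_kaks(b, a)[:2]

    def test_invariant_under_codon_permutation(self):
        a, b = mutate_cds_pair(BASE_CDS, 2, 2, seed=5)
        rng = np.random.default_rng(0)
        perm = rng.permutation(len(a) // 3)
        pa = "".join(a[3 * i : 3 * i + 3] for i in perm)
        pb = "".join(b[3 * i : 3 * i + 3] for i in perm)
        assert nei_gojobori_kaks(a, b)[:2] == pytest.approx(nei_gojobori_kaks(pa, pb)[:2])

    def test_site_counts_sum_to_sequence_length(self):
        from copyvar.fate import _codon_sites

        for codon in ("ATG", "TTT", "CTG", "TGG", "GGG"):
            s, n = _codon_sites(codon)
            assert s + n == pytest.approx(3.0)

    def test_stop_codon_raises_with_position(self):
        bad = BASE_CDS[:30] + "TAA" + BASE_CDS[33:]
        with pytest.raises(ValueError, match="stop codon"):
            nei_gojobori_kaks(bad, BASE_CDS)

    def test_short_cds_rejected(self):
        with pytest.raises(ValueError, match="shorter"):
            nei_gojobori_kaks("ATGGCTAAA", "ATGGCTAAA")

    def test_saturation_raises(self):
        with pytest.raises(ValueError, match="saturated"):
            jukes_cantor(0.8)

    def test_parameter_recovery_across_ks_range(self):
        """Estimated Ks tracks the enumeration oracle over many fixtures."""
        rng = np.random.default_rng(11)
        max_err = 0.0
        for i in range(50):
            cds = random_cds(rng, 80)
            n_syn = int(rng.integers(0, 10))
            n_non = int(rng.integers(0, 10))
            try:
                a, b = mutate_cds_pair(cds, n_syn, n_non, seed=i)
            except ValueError:
                continue
            ka, ks, _ = nei_gojobori_kaks(a, b)
            oka, oks = nei_gojobori_oracle(a, b)
            max_err = max(max_err, abs(ka - oka), abs(ks - oks))
        assert max_err < 1e-9


class TestStaging:
    @pytest.mark.parametrize(
        "ks,expected_stage,expected_mya",
        [
            (0.0, "I", 0.0),
            (0.0072, "II", 0.55),
            (0.0313, "III", 2.41),
            (0.0879, "IV", 6.76),
            (0.195, "V", 15.0),
            (0.30, "VI", 23.08),
        ],
    )
    def test_stage_boundaries_and_times(self, ks, expected_stage, expected_mya):
        t, stage = divergence_time_and_stage(ks)
        assert stage == expected_stage
        assert t / 1e6 == pytest.approx(expected_mya, abs=0.01)

    def test_linear_in_ks_and_mu(self):
        t1, _ = divergence_time_and_stage(0.1)
        t2, _ = divergence_time_and_stage(0.2)
        assert t2 == pytest.approx(2 * t1)
        double_mu = FateConfig(mu=2 * 6.5e-9)
        t3, _ = divergence_time_and_stage(0.1, double_mu)
        assert t3 == pytest.approx(t1 / 2)

    def test_negative_ks_rejected(self):
        with pytest.raises(ValueError):
            divergence_time_and_stage(-0.1)


def make_pair(**kw):
    defaults = dict(pair_id="p1", cds_a=BASE_CDS, cds_b=BASE_CDS)
    defaults.update(kw)
    return DuplicatePair(**defaults)


class TestFateClassification:
    def test_fewer_domains_than_reference_is_sub(self):
        pair = make_pair(
            domains_a=Counter({"A": 1}),
            domains_b=Counter({"A": 1, "B": 1}),
            domains_ref=Counter({"A": 1, "B": 1}),
        )
        assert classify_gene_fate(pair) == "Sub"

    def test_new_domain_is_neo(self):
        pair = make_pair(
            domains_a=Counter({"A": 1, "B": 1, "C": 1}),
            domains_b=Counter({"A": 1, "B": 1}),
            domains_ref=Counter({"A": 1, "B": 1}),
        )
        assert classify_gene_fate(pair) == "Neo"

    def test_extra_copy_of_existing_domain_is_neo(self):
        pair = make_pair(
            domains_a=Counter({"A": 2, "B": 1}),
            domains_b=Counter({"A": 1, "B": 1}),
            domains_ref=Counter({"A": 1, "B": 1}),
        )
        assert classify_gene_fate(pair) == "Neo"

    def test_identical_domains_are_non(self):
        pair = make_pair(
            domains_a=Counter({"A": 1, "B": 1}),
            domains_b=Counter({"A": 1, "B": 1}),
            domains_ref=Counter({"A": 1, "B": 1}),
        )
        assert classify_gene_fate(pair) == "Non"

    def test_pseudogene_flags_short_circuit(self):
        assert classify_gene_fate(make_pair(pseudo_a=True)) == "Gene-Psi"
        assert classify_gene_fate(make_pair(pseudo_a=True, pseudo_b=True)) == "Psi-Psi"

    def test_missing_reference_is_indeterminate(self):
        assert classify_gene_fate(make_pair(domains_a=Counter({"A": 1}))) == "indeterminate"

    def test_mixed_neo_sub_defaults_to_neo(self):
        pair = make_pair(
            domains_a=Counter({"A": 1, "B": 1, "C": 1}),
            domains_b=Counter({"A": 1}),
            domains_ref=Counter({"A": 1, "B": 1}),
        )
        assert classify_gene_fate(pair) == "Neo"
        assert pair.copy_fates == {"A": "Neo", "B": "Sub"}


class TestParentOffspring:
    def test_one_supported_copy_becomes_parent(self):
        support = {"A": {f"acc{i}": 2 for i in range(12)}, "B": {}}
        assert assign_parent_offspring(make_pair(), support) == "A-parent"

    def test_tandem_pair_indistinguishable(self):
        support = {"A": {f"acc{i}": 2 for i in range(12)}, "B": {}}
        pair = make_pair(tandem=True)
        assert assign_parent_offspring(pair, support) == "indistinguishable"

    def test_symmetric_support_indistinguishable(self):
        support = {
            "A": {f"acc{i}": 2 for i in range(12)},
            "B": {f"acc{i}": 3 for i in range(12)},
        }
        assert assign_parent_offspring(make_pair(), support) == "indistinguishable"

    def test_support_below_accession_cutoff_ignored(self):
        support = {"A": {f"acc{i}": 2 for i in range(10)}, "B": {}}  # 10 is not > 10
        assert assign_parent_offspring(make_pair(), support) == "indistinguishable"

    def test_single_flanking_gene_not_enough(self):
        support = {"A": {f"acc{i}": 1 for i in range(12)}, "B": {}}
        assert assign_parent_offspring(make_pair(), support) == "indistinguishable"


class TestCopyExpression:
    def test_identical_pair_excluded(self):
        with pytest.raises(ValueError, match="no CSVs"):
            find_csvs_and_split_expression(make_pair(), reads=[])

    def test_major_and_dominance(self):
        a, b = mutate_cds_pair(BASE_CDS, 2, 1, seed=7)
        pair = make_pair(cds_a=a, cds_b=b)
        expr = find_csvs_and_split_expression(pair, counts=(30, 10))
        assert expr.major == "A" and expr.dominance  # 30 > 2 x 10

    def test_tie_has_no_major(self):
        a, b = mutate_cds_pair(BASE_CDS, 2, 1, seed=7)
        expr = find_csvs_and_split_expression(make_pair(cds_a=a, cds_b=b), counts=(10, 10))
        assert expr.major is None and not expr.dominance

    def test_reads_assigned_by_exact_allele_match(self):
        a, b = mutate_cds_pair(BASE_CDS, 2, 1, seed=8)
        diffs = [i for i, (x, y) in enumerate(zip(a, b)) if x != y]
        csv_pos = diffs[0]
        lo, hi = max(0, csv_pos - 10), csv_pos + 11
        # a window identical in both copies -> read carries no CSV
        shared_lo = next(
            s for s in range(len(a) - 20) if all(not s <= d < s + 20 for d in diffs)
        )
        reads = [a[lo:hi], a[lo:hi], b[lo:hi], a[shared_lo : shared_lo + 20]]
        expr = find_csvs_and_split_expression(make_pair(cds_a=a, cds_b=b), reads=reads)
        assert (expr.count_a, expr.count_b) == (2, 1)

    def test_two_to_one_is_not_dominance(self):
        a, b = mutate_cds_pair(BASE_CDS, 2, 1, seed=7)
        expr = find_csvs_and_split_expression(make_pair(cds_a=a, cds_b=b), counts=(20, 10))
        assert expr.major == "A" and not expr.dominance  # needs strictly > 2x


class TestFateTable:
    def test_rates_from_classified_pairs(self):
        pairs = []
        for fate, n in (("Non", 8), ("Neo", 1), ("Sub", 1)):
            for i in range(n):
                p = make_pair(pair_id=f"{fate}{i}")
                p.stage, p.fate = "III", fate
                pairs.append(p)
        table = build_fate_table(pairs)
        assert table.loc["III", "differentiated_rate_pct"] == 20.0
        assert table.loc["III", "neo_rate_pct"] == 50.0

    def test_all_non_gives_zero_rates(self):
        counts = {s: (5, 0, 0) for s in STAGES}
        table = fate_table_from_counts(counts)
        assert (table["differentiated_rate_pct"] == 0.0).all()

    def test_row_sums_consistent(self):
        counts = {s: (10 + i, i, 2 * i) for i, s in enumerate(STAGES)}
        table = fate_table_from_counts(counts)
        for stage in STAGES:
            row = table.loc[stage]
            assert row["non_differentiated"] + row["differentiated"] == row["pairs"]
            assert row["neo"] + row["sub"] == row["differentiated"]
        assert table.loc["Total", "pairs"] == table.loc[list(STAGES), "pairs"].sum()

    def test_pseudogenic_pairs_rejected(self):
        p = make_pair(pseudo_a=True)
        p.stage = "I"
        classify_gene_fate(p)
        with pytest.raises(ValueError, match="excluded"):
            build_fate_table([p])
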