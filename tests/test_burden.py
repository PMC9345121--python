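"""Variant table parsing, rare filtering, allele aggregation, burden test."""

import numpy as np
import pytest

from cav3ephys.burden import (
    BurdenCounts,
    aggregate_counts,
    bundled_variant_table,
    burden_test,
    filter_rare,
    read_variant_table,
)


@pytest.fixture(scope="module")
def records():
    return read_variant_table(bundled_variant_table())


class TestReadVariantTable:
    def test_bundled_table_has_ten_variants(self, records):
        assert len(records) == 10
        assert {r.protein_change for r in records} >= {"p.R111G", "p.Q1158H"}

    def test_q1158h_carriers_and_maf(self, records):
        q = next(r for r in records if r.protein_change == "p.Q1158H")
        assert len(q.sample_ids) == 4  # four heterozygous probands
        assert q.case_maf == pytest.approx(4 / (2 * 187), abs=1e-7)

    def test_predictor_annotations_passed_through(self, records):
        r111g = next(r for r in records if r.protein_change == "p.R111G")
        assert r111g.predictor_annotations["sift"] == "D"
        assert r111g.predictor_annotations["cadd"] == "34"

    def test_empty_file_with_header(self, tmp_path):
        p = tmp_path / "empty.tsv"
        p.write_text("locus\taa_change\tcase_maf\tgnomad_nfe_maf\n")
        assert read_variant_table(p) == []

    def test_malformed_maf_names_the_row(self, tmp_path):
        p = tmp_path / "bad.tsv"
        p.write_text(
            "locus\taa_change\tcase_maf\tgnomad_nfe_maf\n"
            "chr22:1\tp.A1B\t0.001\t0.0001\n"
            "chr22:2\tp.C2D\tabc\t0.0001\n"
        )
        with pytest.raises(ValueError, match="line 3"):
            read_variant_table(p)

    def test_missing_required_column(self, tmp_path):
        p = tmp_path / "nocol.tsv"
        p.write_text("locus\tcase_maf\tgnomad_nfe_maf\nchr22:1\t0.001\t0.0001\n")
        with pytest.raises(ValueError, match="aa_change"):
            read_variant_table(p)


class TestFilterRare:
    def test_all_ten_pass_default_threshold(self, records):
        # the largest control MAF in the table is 0.0073 (R307H, gnomAD)
        assert len(filter_rare(records, 0.01)) == 10

    def test_strict_gnomad_threshold(self, records):
        kept = filter_rare(records, 0.001, columns=["gnomad_nfe_maf"])
        names = {r.protein_change for r in kept}
        assert names == {"p.R111G", "p.M128L", "p.G859C", "p.P905L", "p.R924K"}

    def test_common_variant_removed(self, records):
        assert len(filter_rare(records, 0.005, columns=["gnomad_nfe_maf"])) == 8

    def test_unknown_column_rejected(self, records):
        with pytest.raises(KeyError):
            filter_rare(records, 0.01, columns=["esp6500_maf"])

    def test_invalid_threshold(self, records):
        with pytest.raises(ValueError):
            filter_rare(records, 0.0)


class TestAggregateCounts:
    def test_case_count_is_seventeen_carriers(self, records):
        counts = aggregate_counts(records, 187, "ukbiobank_maf", 43_000)
        assert counts.case_alt == 17
        assert counts.case_total == 2 * 187 * 10

    def test_single_variant_half_frequency(self):
        from cav3ephys.burden import VariantRecord

        rec = VariantRecord(
            sample_ids=(), locus="chr1:1", protein_change="p.X", coding_change="",
            predictor_annotations={}, case_maf=0.5, control_mafs={"c_maf": 0.5}, rsid="",
        )
        counts = aggregate_counts([rec], 10, "c_maf", 10)
        assert (counts.case_alt, counts.case_total) == (10, 20)

    def test_empty_records_rejected(self):
        with pytest.raises(ValueError):
            aggregate_counts([], 187, "ukbiobank_maf", 43_000)

    def test_aggregated_freq_close_to_mean_maf(self, records):
        # algebraic identity up to per-variant rounding of estimated counts
        counts = aggregate_counts(records, 187, "ukbiobank_maf", 43_000)
        mean_maf = np.mean([r.control_mafs["ukbiobank_maf"] for r in records])
        assert counts.ctrl_alt / counts.ctrl_total == pytest.approx(mean_maf, abs=1e-5)


class TestBurdenTest:
    def test_equal_frequencies_null(self):
        counts = BurdenCounts(10, 1000, 100, 10000, 5)
        res = burden_test(counts)
        assert res.odds_ratio == pytest.approx(1.0)
        assert res.chi2 == pytest.approx(0.0, abs=1e-9)

    def test_ukbiobank_reproduction(self, records):
        counts = aggregate_counts(records, 187, "ukbiobank_maf", 43_000)
        res = burden_test(counts, "ukbiobank")
        assert round(res.case_freq, 4) == 0.0045
        assert round(res.ctrl_freq, 4) == 0.0020
        assert round(res.odds_ratio, 2) == 2.32
        assert res.p_value == pytest.approx(4e-4, abs=1e-4)

    def test_chi2_matches_four_cell_oracle(self):
        # independent expected-count computation on a reference 2x2 table
        table = np.array([[17, 3723], [1686, 858314]], dtype=float)
        expected = np.outer(table.sum(1), table.sum(0)) / table.sum()
        chi2_oracle = float(((table - expected) ** 2 / expected).sum())
        counts = BurdenCounts(17, 3740, 1686, 860_000, 10)
        assert burden_test(counts).chi2 == pytest.approx(chi2_oracle, abs=1e-9)

    def test_or_invariance_and_chi2_scaling(self):
        base = BurdenCounts(20, 1000, 50, 5000, 4)
        scaled = BurdenCounts(200, 10000, 500, 50000, 4)
        rb, rs = burden_test(base), burden_test(scaled)
        assert rs.odds_ratio == pytest.approx(rb.odds_ratio, rel=1e-12)
        assert rs.chi2 == pytest.approx(10 * rb.chi2, rel=1e-9)

    def test_case_control_swap_symmetry(self):
        a = BurdenCounts(17, 3740, 1687, 860_000, 10)
        b = BurdenCounts(1687, 860_000, 17, 3740, 10)
        ra, rb = burden_test(a), burden_test(b)
        assert rb.odds_ratio == pytest.approx(1 / ra.odds_ratio, rel=1e-12)
        assert rb.chi2 == pytest.approx(ra.chi2, rel=1e-12)

    def test_fisher_option(self):
        counts = BurdenCounts(8, 100, 10, 1000, 2)
        res = burden_test(counts, method="fisher")
        assert 0 < res.p_value < 1
        assert np.isnan(res.chi2)
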