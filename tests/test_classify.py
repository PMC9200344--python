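"""Classification rules, hierarchy, tie-breaking and count tables."""

import numpy as np
import pandas as pd
import pytest

from nemasrna.align import AlignedRead
from nemasrna.annotation import FeatureRecord, GenomeAnnotation
from nemasrna.classify import (
    assign_class,
    class_counts,
    classify_reads,
    count_matrix,
    relative_strand,
)
from nemasrna.config import PipelineConfig

from conftest import brute_force_classify

CFG = PipelineConfig()


def _read(seq, start, strand, chrom="chrI"):
    return AlignedRead("r", seq, chrom, start, strand, 0)


@pytest.fixture(scope="module")
def mini_annotation():
    return GenomeAnnotation(
        [
            FeatureRecord("piRNA_21ur_0001", "chrI", "+", [(100, 121)], "piRNA_21ur"),
            FeatureRecord("protein_coding_0001", "chrI", "+", [(300, 900)], "protein_coding"),
            FeatureRecord("rRNA_0001", "chrI", "+", [(1000, 1120)], "rRNA"),
            FeatureRecord("miRNA_mature_0001", "chrI", "-", [(1300, 1322)], "miRNA_mature"),
            FeatureRecord("transposon_0001", "chrI", "-", [(1500, 2200)], "transposon",
                          family="TcToy1"),
            FeatureRecord("lincRNA_0001", "chrI", "+", [(2400, 2900)], "lincRNA"),
        ]
    )


class TestRelativeStrand:
    def test_matching_strands_are_sense(self, mini_annotation):
        f = mini_annotation.by_id["protein_coding_0001"]
        assert relative_strand(_read("G" * 22, 400, "+"), f) == "sense"

    def test_opposite_strands_are_antisense(self, mini_annotation):
        f = mini_annotation.by_id["protein_coding_0001"]
        assert relative_strand(_read("G" * 22, 400, "-"), f) == "antisense"


class TestAssignClass:
    def test_21nt_t_start_sense_over_pirna_locus_is_21u(self, mini_annotation):
        c = assign_class(_read("T" + "A" * 20, 100, "+"), mini_annotation, CFG)
        assert (c.sclass, c.feature_id) == ("21U", "piRNA_21ur_0001")

    def test_22nt_g_start_antisense_over_coding_exon_is_22g(self, mini_annotation):
        c = assign_class(_read("G" + "A" * 21, 400, "-"), mini_annotation, CFG)
        assert (c.sclass, c.feature_id) == ("22G", "protein_coding_0001")

    def test_26nt_g_start_antisense_over_coding_exon_is_26g(self, mini_annotation):
        c = assign_class(_read("G" + "A" * 25, 400, "-"), mini_annotation, CFG)
        assert (c.sclass, c.feature_id) == ("26G", "protein_coding_0001")

    def test_22nt_g_start_sense_over_rrna_is_structural(self, mini_annotation):
        c = assign_class(_read("G" + "A" * 21, 1010, "+"), mini_annotation, CFG)
        assert (c.sclass, c.feature_id) == ("structural", "rRNA_0001")

    def test_23nt_any_start_sense_over_mirna_is_mirna(self, mini_annotation):
        c = assign_class(_read("A" * 23, 1299, "-"), mini_annotation, CFG)
        assert (c.sclass, c.feature_id) == ("miRNA", "miRNA_mature_0001")

    def test_20nt_g_start_antisense_over_coding_exon_is_unclassified(
        self, mini_annotation
    ):
        c = assign_class(_read("G" + "A" * 19, 400, "-"), mini_annotation, CFG)
        assert c.sclass == "unclassified" and c.feature_id is None

    def test_22nt_sense_to_transposon_means_antisense_read_strand_plus(
        self, mini_annotation
    ):
        # transposon is on '-', so a '+' read is antisense to it
        c = assign_class(_read("G" + "A" * 21, 1600, "+"), mini_annotation, CFG)
        assert (c.sclass, c.feature_id) == ("22G", "transposon_0001")

    def test_26g_transposon_admission_is_configurable(self, mini_annotation):
        read = _read("G" + "A" * 25, 1600, "+")
        assert assign_class(read, mini_annotation, CFG).sclass == "26G"
        strict = PipelineConfig(allow_26g_transposons=False)
        assert assign_class(read, mini_annotation, strict).sclass == "unclassified"

    def test_largest_overlap_wins_then_feature_id(self):
        ann = GenomeAnnotation(
            [
                FeatureRecord("gene_a", "chrI", "+", [(100, 200)], "protein_coding"),
                FeatureRecord("gene_b", "chrI", "+", [(190, 300)], "protein_coding"),
            ]
        )
        # read 188-210: 12 bases on gene_a, 20 on gene_b
        c = assign_class(_read("G" + "A" * 21, 188, "-"), ann, CFG)
        assert c.feature_id == "gene_b"
        # read 180-202: 20 on gene_a, 12 on gene_b
        c = assign_class(_read("G" + "A" * 21, 180, "-"), ann, CFG)
        assert c.feature_id == "gene_a"
        # symmetric overlap: lexicographic id
        ann2 = GenomeAnnotation(
            [
                FeatureRecord("gene_b", "chrI", "+", [(100, 300)], "protein_coding"),
                FeatureRecord("gene_a", "chrI", "+", [(100, 300)], "protein_coding"),
            ]
        )
        c = assign_class(_read("G" + "A" * 21, 150, "-"), ann2, CFG)
        assert c.feature_id == "gene_a"

    def test_structural_beats_target_rule_in_planted_overlap(self):
        # transposon inside an rRNA span: a sense structural read over both
        ann = GenomeAnnotation(
            [
                FeatureRecord("rRNA_0001", "chrI", "+", [(100, 400)], "rRNA"),
                FeatureRecord("transposon_0001", "chrI", "-", [(150, 350)], "transposon"),
            ]
        )
        read = _read("G" + "A" * 21, 200, "+")  # antisense to transposon, sense to rRNA
        assert assign_class(read, ann, CFG).sclass == "structural"

    def test_label_frequencies_invariant_to_input_order(self, mini_annotation):
        rng = np.random.default_rng(3)
        reads = []
        for i in range(200):
            start = int(rng.integers(0, 3000))
            L = int(rng.integers(18, 31))
            strand = "+" if rng.random() < 0.5 else "-"
            first = "TGAC"[i % 4]
            reads.append(AlignedRead(f"r{i}", first + "A" * (L - 1), "chrI",
                                     start, strand, 0))
        fwd = [assign_class(r, mini_annotation, CFG).sclass for r in reads]
        rev = [assign_class(r, mini_annotation, CFG).sclass for r in reads[::-1]]
        assert sorted(fwd) == sorted(rev)


def test_agrees_with_first_principles_oracle_on_simulated_reads(
    toy_genome, toy_annotation
):
    from nemasrna.annotation import plant_overlap_fixture
    from nemasrna.simulate import make_truth, simulate_reads

    host = next(
        f for f in toy_annotation.features
        if f.biotype == "protein_coding" and f.exonic_length > 900
    )
    ann = plant_overlap_fixture(toy_annotation, host.feature_id, seed=41)
    truth = make_truth(
        ann, {"22G": 0.5, "26G": 0.1, "21U": 0.2, "miRNA": 0.1, "structural": 0.1},
        2_000, n_replicates=1, frac_26g=0.15, seed=43,
    )
    _, table = simulate_reads(toy_genome, ann, truth, "insert")
    mismatched = 0
    for _, row in table.iterrows():
        read = AlignedRead(row["read_id"], row["insert"], row["chrom"],
                           int(row["start"]), row["strand"], int(row["mismatches"]))
        got = assign_class(read, ann, CFG)
        want_label, want_fid = brute_force_classify(read, ann)
        if (got.sclass, got.feature_id) != (want_label, want_fid):
            mismatched += 1
    assert mismatched == 0


class TestCountMatrix:
    def test_three_reads_one_gene_one_cell(self, mini_annotation):
        reads = [_read("G" + "A" * 21, 400 + i, "-") for i in range(3)]
        classified = classify_reads(reads, mini_annotation, CFG)
        counts, unclassified = count_matrix({"s1": classified})
        assert counts.loc[("protein_coding_0001", "22G"), "s1"] == 3
        assert unclassified["s1"] == 0

    def test_matrix_plus_unclassified_conserves_input(self, mini_annotation):
        rng = np.random.default_rng(5)
        reads = [
            AlignedRead(f"r{i}", "G" + "A" * 21, "chrI", int(rng.integers(0, 3000)),
                        "+" if rng.random() < 0.5 else "-", 0)
            for i in range(300)
        ]
        classified = classify_reads(reads, mini_annotation, CFG)
        counts, unclassified = count_matrix({"s1": classified})
        assert counts["s1"].sum() + unclassified["s1"] == 300

    def test_family_aggregation_sums_transposon_copies(self):
        ann = GenomeAnnotation(
            [
                FeatureRecord("transposon_0001", "chrI", "+", [(100, 700)],
                              "transposon", family="TcToy1"),
                FeatureRecord("transposon_0002", "chrI", "+", [(1000, 1600)],
                              "transposon", family="TcToy1"),
            ]
        )
        reads = [_read("G" + "A" * 21, 200, "-"), _read("G" + "A" * 21, 1100, "-")]
        classified = classify_reads(reads, ann, CFG)
        counts, _ = count_matrix({"s1": classified}, annotation=ann,
                                 aggregate_families=True)
        assert counts.loc[("TcToy1", "22G"), "s1"] == 2

    def test_class_slice_returns_single_class_table(self, mini_annotation):
        reads = [_read("G" + "A" * 21, 400, "-"), _read("T" + "A" * 20, 100, "+")]
        classified = classify_reads(reads, mini_annotation, CFG)
        counts, _ = count_matrix({"s1": classified})
        sub = class_counts(counts, "22G")
        assert list(sub.index) == ["protein_coding_0001"]
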