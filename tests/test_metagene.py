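"""Metagene binning, relative/total profiles and the centroid shift."""

import numpy as np
import pandas as pd
import pytest

from nemasrna.align import AlignedRead
from nemasrna.annotation import FeatureRecord, GenomeAnnotation
from nemasrna.config import PipelineConfig
from nemasrna.metagene import (
    EmptyProfileError,
    bin_coverage,
    bin_vector,
    centroid_shift,
    coverage_centroid,
    metagene_matrix,
    profile_by_geneset,
    relative_profile,
    total_profile,
    transcript_coverage,
    unaffected_set,
)

from conftest import brute_force_bins

CFG = PipelineConfig()


def _gene(length=1000, strand="+", start=0, fid="gene_a", chrom="chrI"):
    return FeatureRecord(fid, chrom, strand, [(start, start + length)],
                         "protein_coding")


def _reads(spans, chrom="chrI", strand="-"):
    return [
        AlignedRead(f"r{i}", "G" * (e - s), chrom, s, strand, 0)
        for i, (s, e) in enumerate(spans)
    ]


class TestBinCoverage:
    def test_uniform_coverage_gives_constant_bins(self):
        gene = _gene(1000)
        reads = _reads([(i, i + 100) for i in range(0, 1000, 100)] * 3)
        bins = bin_coverage(gene, reads, CFG)
        assert np.allclose(bins, 3.0)

    def test_single_5prime_read_fills_only_bin_one(self):
        gene = _gene(2200)
        bins = bin_coverage(gene, _reads([(0, 22)]), CFG)
        assert bins[0] == 1.0
        assert np.allclose(bins[1:], 0.0)

    def test_minus_strand_gene_right_end_maps_to_bin_one(self):
        gene = _gene(2200, strand="-")
        bins = bin_coverage(gene, _reads([(2178, 2200)], strand="+"), CFG)
        assert bins[0] == 1.0
        assert np.allclose(bins[1:], 0.0)

    def test_gene_shorter_than_bin_count_gets_zero_padded_bins(self):
        cov = np.ones(60)
        bins = bin_vector(cov, 100)
        assert (bins[np.nonzero(bins)] == 1.0).all()
        assert (bins == 0.0).sum() == 40

    def test_intronic_read_bases_do_not_count(self):
        gene = FeatureRecord("g", "chrI", "+", [(0, 100), (200, 300)],
                             "protein_coding")
        # read spans the 3' end of exon 1 and intron
        bins = bin_vector(transcript_coverage(gene, _reads([(90, 112)])), 10)
        assert bins[4] == 0.5  # transcript bases 80-99: half covered
        assert np.allclose(bins[5:], 0.0)

    def test_matches_per_base_brute_force_on_random_genes(self, toy_genome):
        rng = np.random.default_rng(47)
        chrom = toy_genome.chrom_names[0]
        for trial in range(50):
            start = int(rng.integers(0, 40_000))
            length = int(rng.integers(150, 2_000))
            strand = "+" if rng.random() < 0.5 else "-"
            gene = _gene(length, strand, start, f"g{trial}", chrom)
            spans = []
            for _ in range(int(rng.integers(1, 40))):
                s = int(rng.integers(max(0, start - 30), start + length + 10))
                spans.append((s, s + 22))
            reads = _reads(spans, chrom)
            got = bin_coverage(gene, reads, CFG)
            want = brute_force_bins(gene, reads, 100)
            assert np.allclose(got, want), trial

    def test_strand_mirroring_invariance(self):
        """Flipping the gene strand and mirroring its reads leaves the
        bin vector unchanged."""
        L = 1500
        fwd_gene = _gene(L, "+")
        rev_gene = _gene(L, "-")
        spans = [(37, 59), (400, 422), (1210, 1232), (0, 22)]
        mirrored = [(L - e, L - s) for s, e in spans]
        fwd = bin_coverage(fwd_gene, _reads(spans), CFG)
        rev = bin_coverage(rev_gene, _reads(mirrored, strand="+"), CFG)
        assert np.allclose(fwd, rev)


class TestProfiles:
    def _matrix(self, rows, ids=None):
        return pd.DataFrame(
            np.asarray(rows, dtype=float),
            index=ids or [f"g{i}" for i in range(len(rows))],
            columns=[f"bin{b}" for b in range(1, 101)],
        )

    def test_single_uniform_gene_profile_sums_to_one(self):
        M = self._matrix([np.full(100, 5.0)])
        prof = relative_profile(M, CFG)
        assert np.allclose(prof.values, 0.01)
        assert prof.genes_used == 1

    def test_rowsum_filter_is_strictly_greater_than_ten(self):
        low = np.zeros(100); low[0] = 10.0        # rowSum exactly 10: dropped
        high = np.zeros(100); high[0] = 10.5      # rowSum 10.5: kept
        prof = relative_profile(self._matrix([low, high]), CFG)
        assert prof.genes_used == 1
        assert prof.values[0] == pytest.approx(1.0)

    def test_row_scaling_does_not_change_relative_weight(self):
        row = np.linspace(1, 3, 100)
        single = relative_profile(self._matrix([row]), CFG)
        doubled = relative_profile(self._matrix([row, row * 10]), CFG)
        assert np.allclose(doubled.values, 2 * single.values)

    def test_kept_rows_sum_to_one_and_profile_to_genes_used(self):
        rng = np.random.default_rng(53)
        M = self._matrix(rng.gamma(2.0, 1.0, size=(40, 100)))
        prof = relative_profile(M, CFG)
        assert prof.values.sum() == pytest.approx(prof.genes_used, abs=1e-6)

    def test_no_gene_passes_filter_raises(self):
        with pytest.raises(EmptyProfileError):
            relative_profile(self._matrix([np.full(100, 0.05)]), CFG)

    def test_total_profile_scales_with_size_factor_and_skips_filtering(self):
        weak = np.full(100, 0.01)  # rowSum 1: would be dropped in relative mode
        strong = np.full(100, 50.0)
        M = self._matrix([weak, strong])
        prof = total_profile(M, size_factor=2.0)
        assert prof.genes_used == 2
        assert np.allclose(prof.values, (0.01 + 50.0) / 2.0)

    def test_total_profile_dominated_by_strong_gene(self):
        shape = np.linspace(2, 0, 100)
        M = self._matrix([shape * 100, np.ones(100)])
        prof = total_profile(M, 1.0)
        corr = np.corrcoef(prof.values, shape)[0, 1]
        assert corr > 0.999

    def test_all_zero_matrix_total_profile_is_zero(self):
        prof = total_profile(self._matrix([np.zeros(100)]), 1.0)
        assert np.allclose(prof.values, 0.0)


class TestCentroid:
    def test_uniform_vector_centroid_is_middle(self):
        assert coverage_centroid(np.ones(100)) == pytest.approx(50.5)

    def test_all_mass_in_bin_one(self):
        v = np.zeros(100); v[0] = 7.0
        assert coverage_centroid(v) == 1.0

    def test_zero_sum_vector_is_undefined(self):
        with pytest.raises(EmptyProfileError):
            coverage_centroid(np.zeros(100))

    def test_beta_positional_bias_shifts_centroid_negative(self, toy_genome):
        """Genes simulated with a 5'-skewed mutant Beta law must show a
        negative per-gene centroid shift nearly everywhere, with set-level
        centroids near 100*a/(a+b) + 0.5."""
        from nemasrna.annotation import generate_annotation
        from nemasrna.simulate import make_truth, simulate_reads

        genome = toy_genome
        ann = generate_annotation(
            genome, {"protein_coding": 20}, min_gap=60, seed=61
        )
        truth = make_truth(
            ann, {"22G": 1.0}, 2_000, n_replicates=1, dispersion=0.0,
            beta_wt=(2.0, 2.0), beta_mut=(1.2, 2.8), seed=67,
        )
        _, table = simulate_reads(genome, ann, truth, "insert")
        shifts = []
        cents = {"wt": [], "mutant": []}
        for cond in ("wt", "mutant"):
            sub = table[table["condition"] == cond]
            for fid, grp in sub.groupby("feature_id"):
                reads = _reads(
                    [(s, s + 22) for s in grp["start"]],
                    chrom=ann.by_id[fid].chrom,
                )
                bins = bin_coverage(ann.by_id[fid], reads, CFG)
                cents[cond].append((fid, coverage_centroid(bins)))
        wt = dict(cents["wt"]); mut = dict(cents["mutant"])
        common = sorted(set(wt) & set(mut))
        assert len(common) >= 15
        shifts = np.array([mut[g] - wt[g] for g in common])
        assert (shifts < 0).mean() >= 0.95
        assert np.mean(list(wt.values())) == pytest.approx(50.5, abs=2.0)
        assert np.mean(list(mut.values())) == pytest.approx(30.5, abs=2.0)


class TestGenesetProfiles:
    def _matrix(self):
        rng = np.random.default_rng(71)
        return pd.DataFrame(
            rng.gamma(2.0, 1.0, size=(30, 100)),
            index=[f"g{i}" for i in range(30)],
            columns=[f"bin{b}" for b in range(1, 101)],
        )

    def test_full_gene_list_equals_relative_profile(self):
        M = self._matrix()
        a = profile_by_geneset(M, list(M.index), "relative", CFG)
        b = relative_profile(M, CFG)
        assert np.allclose(a.values, b.values)

    def test_disjoint_gene_list_raises(self):
        with pytest.raises(EmptyProfileError):
            profile_by_geneset(self._matrix(), ["nope"], "relative", CFG)

    def test_unaffected_set_uses_p_equal_one_and_base_mean(self):
        ma = pd.DataFrame(
            {
                "baseMean": [50.0, 5.0, 80.0],
                "log2FoldChange": [0.0, 0.0, 2.0],
                "pvalue": [1.0, 1.0, 0.001],
                "padj": [1.0, 1.0, 0.01],
            },
            index=["g0", "g1", "g2"],
        )
        assert unaffected_set(ma) == {"g0"}


def test_metagene_matrix_rows_follow_gene_id_order(toy_annotation):
    genes = [f for f in toy_annotation.features if f.biotype == "protein_coding"][:3]
    ids = [g.feature_id for g in genes]

    class C:
        def __init__(self, read, sclass, feature_id):
            self.read, self.sclass, self.feature_id = read, sclass, feature_id

    classified = [
        C(AlignedRead("r0", "G" * 22, genes[0].chrom, genes[0].start, "-", 0),
          "22G", ids[0])
    ]
    M = metagene_matrix(GenomeAnnotation(genes), classified,
                        CFG, "22G", gene_ids=ids)
    assert list(M.index) == ids
    assert M.loc[ids[0]].sum() > 0
    assert M.loc[ids[1]].sum() == 0
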