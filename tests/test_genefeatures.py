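import numpy as np
import pytest

from quadmap import genefeatures
from quadmap.genomeio import Genome, GeneModel, Interval, SignalTrack


@pytest.fixture
def simple_genes():
    # + strand gene with two exons and a - strand gene far away
    return [
        GeneModel("gA", "chr1", 10_000, 16_000, "+",
                  ((10_000, 11_000), (14_000, 15_000))),
        GeneModel("gB", "chr1", 40_000, 44_000, "-",
                  ((40_000, 41_000), (43_000, 44_000))),
    ]


@pytest.fixture
def wide_genome():
    return Genome({"chr1": "A" * 100_000})


class TestAnnotate:
    def test_promoter_upstream_of_plus_tss(self, simple_genes):
        peak = Interval("chr1", 9_450, 9_550)  # midpoint 9500, 500 bp upstream
        (rec,) = genefeatures.annotate_peaks([peak], simple_genes)
        assert rec.category == "Promoter"
        assert rec.distance_to_tss == -500
        assert rec.gene_id == "gA"

    def test_promoter_strand_awareness_on_minus_gene(self, simple_genes):
        # 500 bp upstream of gB's TSS (43999) is at larger coordinates
        peak = Interval("chr1", 44_449, 44_549)  # midpoint 44499
        (rec,) = genefeatures.annotate_peaks([peak], simple_genes)
        assert rec.category == "Promoter"
        assert rec.distance_to_tss == -500
        assert rec.gene_id == "gB"

    def test_exon_beats_intron_beyond_promoter_window(self, simple_genes):
        peak = Interval("chr1", 14_400, 14_600)  # inside exon 2, 4.5 kb from TSS
        (rec,) = genefeatures.annotate_peaks([peak], simple_genes)
        assert rec.category == "Exon"

    def test_intron_between_exons(self, simple_genes):
        peak = Interval("chr1", 12_400, 12_600)
        (rec,) = genefeatures.annotate_peaks([peak], simple_genes)
        assert rec.category == "Intron"

    def test_downstream_past_three_prime_end(self, simple_genes):
        peak = Interval("chr1", 17_400, 17_600)  # 1.5 kb past gA's end
        (rec,) = genefeatures.annotate_peaks([peak], simple_genes)
        assert rec.category == "Downstream"

    def test_distal_fall_through(self, simple_genes):
        peak = Interval("chr1", 70_000, 70_100)
        (rec,) = genefeatures.annotate_peaks([peak], simple_genes)
        assert rec.category == "Distal intergenic"

    def test_empty_gene_set_flagged(self):
        (rec,) = genefeatures.annotate_peaks([Interval("chr1", 0, 100)], [])
        assert rec.category == "Distal intergenic"
        assert rec.distance_to_tss is None and rec.gene_id is None

    def test_every_peak_gets_exactly_one_category(self, simple_genes):
        rng = np.random.default_rng(4)
        peaks = [
            Interval("chr1", int(s), int(s) + 200)
            for s in rng.integers(0, 99_800, size=300)
        ]
        records = genefeatures.annotate_peaks(peaks, simple_genes)
        assert len(records) == len(peaks)
        counts = {c: 0 for c in genefeatures.CATEGORIES}
        for r in records:
            counts[r.category] += 1
        assert sum(counts.values()) == len(peaks)


class TestNormalizedDistribution:
    def test_two_category_arithmetic(self):
        """Promoter 10% of genome with half the peaks -> 90% normalized."""
        genome = Genome({"chr1": "A" * 10_000})
        # tiny gene fully inside its own promoter paint; downstream window 1 bp
        genes = [GeneModel("g", "chr1", 5_000, 5_010, "+", ((5_000, 5_010),))]
        window = (-500, 499)  # promoter footprint = exactly 1000 bases
        peaks = (
            [Interval("chr1", 4_990, 5_010)] * 10      # promoter midpoints
            + [Interval("chr1", 800, 900)] * 10          # distal midpoints
        )
        ann = genefeatures.annotate_peaks(
            peaks, genes, promoter_window=window, downstream_window=1
        )
        norm = genefeatures.normalized_feature_distribution(
            ann, genome, genes, promoter_window=window, downstream_window=1
        )
        assert norm["Promoter"] == pytest.approx(90.0)
        assert norm["Distal intergenic"] == pytest.approx(10.0)

    def test_uniform_peaks_give_flat_normalized_shares(
        self, simple_genes, wide_genome
    ):
        for seed in range(5):
            rng = np.random.default_rng(seed)
            peaks = [
                Interval("chr1", int(s), int(s) + 10)
                for s in rng.integers(0, 99_900, size=4000)
            ]
            ann = genefeatures.annotate_peaks(peaks, simple_genes)
            norm = genefeatures.normalized_feature_distribution(
                ann, wide_genome, simple_genes
            )
            for value in norm.values():
                assert abs(value - 100 / len(norm)) < 8.0

    def test_all_promoter_peaks_degenerate(self, simple_genes, wide_genome):
        peaks = [Interval("chr1", 9_400 + i, 9_500 + i) for i in range(20)]
        ann = genefeatures.annotate_peaks(peaks, simple_genes)
        norm = genefeatures.normalized_feature_distribution(
            ann, wide_genome, simple_genes
        )
        assert norm["Promoter"] == pytest.approx(100.0)


class TestTssMatrix:
    def test_constant_track_and_zscore_rule(self, simple_genes, wide_genome):
        dense = np.full(100_000, 3.0)
        track = SignalTrack.from_dense({"chr1": dense})
        matrix, profile, ids = genefeatures.tss_matrix(
            track, simple_genes, wide_genome, flank=1000, bin_size=25
        )
        assert matrix.shape == (2, 80)
        assert np.allclose(matrix, 3.0)
        z, _, _ = genefeatures.tss_matrix(
            track, simple_genes, wide_genome, flank=1000, bin_size=25,
            scale="zscore",
        )
        assert np.allclose(z, 0.0)

    def test_minus_strand_rows_flipped_downstream(self, wide_genome):
        gene = GeneModel("g", "chr1", 40_000, 44_000, "-")
        tss = gene.tss  # 43999
        dense = np.zeros(100_000)
        dense[tss - 1000 : tss] = 10.0  # genomic left of TSS = downstream for '-'
        track = SignalTrack.from_dense({"chr1": dense})
        matrix, _, _ = genefeatures.tss_matrix(
            track, [gene], wide_genome, flank=1000, bin_size=25
        )
        # downstream columns are the second half after orientation flip
        assert matrix[0, 40:].mean() > 9.0
        assert matrix[0, :40].mean() < 1.0

    def test_clipped_bins_are_missing(self, wide_genome):
        gene = GeneModel("g", "chr1", 100, 2000, "+")  # TSS at 100, flank 1000
        track = SignalTrack.from_dense({"chr1": np.ones(100_000)})
        matrix, profile, _ = genefeatures.tss_matrix(
            track, [gene], wide_genome, flank=1000, bin_size=25
        )
        assert np.isnan(matrix[0, :36]).all()  # bins before base 0
        assert np.isfinite(matrix[0, 36:]).all()

    def test_flank_must_divide_by_bin(self, simple_genes, wide_genome):
        track = SignalTrack.from_dense({"chr1": np.ones(100_000)})
        with pytest.raises(ValueError, match="divisible"):
            genefeatures.tss_matrix(
                track, simple_genes, wide_genome, flank=1000, bin_size=30
            )
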