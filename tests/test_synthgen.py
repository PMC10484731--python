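import numpy as np
import pytest

from quadmap import quadmotif, synthgen
from quadmap.genomeio import Interval
from quadmap.quadmotif import MotifSpec, all_specs


def gc_fraction(seq: str) -> float:
    return (seq.count("G") + seq.count("C")) / len(seq)


class TestSimulateGenome:
    def test_degenerate_gc_one_gives_only_gc(self):
        cfg = synthgen.SimConfig(
            chromosome_lengths={"c": 100}, gc_fraction=1.0, seed=0
        )
        seq = synthgen.simulate_genome(cfg).sequence("c")
        assert set(seq) <= {"G", "C"}

    def test_observed_gc_within_three_binomial_sd(self):
        n = 1_000_000
        cfg = synthgen.SimConfig(
            chromosome_lengths={"c": n}, gc_fraction=0.5, seed=1
        )
        seq = synthgen.simulate_genome(cfg).sequence("c")
        sd = np.sqrt(0.25 / n)
        assert abs(gc_fraction(seq) - 0.5) < 3 * sd

    def test_seed_determinism_end_to_end(self):
        lengths = {"c1": 50_000, "c2": 50_000}
        regions = synthgen.default_peak_regions(lengths, 4, 500)
        cfg = synthgen.SimConfig(
            chromosome_lengths=lengths,
            peak_regions=regions,
            fragments_per_replicate=500,
            seed=7,
        )
        out = []
        for _ in range(2):
            g = synthgen.simulate_genome(cfg)
            reps = synthgen.simulate_fragments(cfg, g)
            genes, tpm = synthgen.simulate_genes_and_expression(
                cfg, g, ["none", "iM", "G4", "both"] * 5
            )
            out.append((dict(g), reps, genes, tpm.to_dict()))
        assert out[0] == out[1]

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            synthgen.SimConfig(chromosome_lengths={"c": 0})
        with pytest.raises(ValueError):
            synthgen.SimConfig(chromosome_lengths={"c": 10}, gc_fraction=1.5)
        with pytest.raises(ValueError):
            synthgen.SimConfig(chromosome_lengths={"c": 10}, enrichment_ratio=0.5)


class TestPlantMotifs:
    def test_planted_substring_matches_canonical_instance(self):
        cfg = synthgen.SimConfig(chromosome_lengths={"c": 10_000}, seed=3)
        genome = synthgen.simulate_genome(cfg)
        spec = MotifSpec.from_labels("C", "low", 7)
        planted, truth = synthgen.plant_motifs(genome, [(spec, None, 5)], seed=3)
        assert len(truth) == 5
        for t in truth:
            assert planted.fetch(t.chrom, t.start, t.end) == spec.canonical_instance()
        assert spec.canonical_instance() == "CCACCACCACC"

    def test_plants_confined_to_regions(self):
        lengths = {"c": 100_000}
        regions = synthgen.default_peak_regions(lengths, 5, 2000)
        genome = synthgen.simulate_genome(
            synthgen.SimConfig(chromosome_lengths=lengths, seed=4)
        )
        spec = MotifSpec.from_labels("G", "high", 12)
        _, truth = synthgen.plant_motifs(genome, [(spec, regions, 50)], seed=4)
        for t in truth:
            assert any(
                r.start <= t.start and t.end <= r.end for r in regions
            )

    def test_insufficient_space_raises(self):
        genome = synthgen.simulate_genome(
            synthgen.SimConfig(chromosome_lengths={"c": 2000}, seed=5)
        )
        region = (Interval("c", 100, 200),)
        spec = MotifSpec.from_labels("C", "low", 7)
        with pytest.raises(ValueError, match="insufficient space"):
            synthgen.plant_motifs(genome, [(spec, region, 50)], seed=5)

    def test_scanner_recovers_every_plant_at_recorded_coordinates(self):
        """Truth-set fidelity: recall = 1 at exact coordinates, per class."""
        cfg = synthgen.SimConfig(chromosome_lengths={"c": 300_000}, seed=6)
        genome = synthgen.simulate_genome(cfg)
        specs = all_specs()
        planted, truth = synthgen.plant_motifs(
            genome, [(s, None, 4) for s in specs], seed=6
        )
        for spec in specs:
            found = {
                (h.chrom, h.start, h.end)
                for h in quadmotif.scan_genome(planted, [spec], strands="+")
            }
            for t in truth:
                if t.spec == spec:
                    assert (t.chrom, t.start, t.end) in found


class TestSimulateFragments:
    def test_in_region_fraction_matches_mixture_expectation(self):
        lengths = {"c": 1_000_000}
        regions = (Interval("c", 100_000, 110_000),)  # 1% of genome
        cfg = synthgen.SimConfig(
            chromosome_lengths=lengths,
            peak_regions=regions,
            fragments_per_replicate=20_000,
            enrichment_ratio=10.0,
            n_replicates=1,
            seed=8,
        )
        genome = synthgen.simulate_genome(cfg)
        (frags,) = synthgen.simulate_fragments(cfg, genome)
        expected = (10 * 0.01) / (10 * 0.01 + 0.99)
        mids_in = sum(
            1
            for f in frags
            if regions[0].start <= f.midpoint < regions[0].end
        )
        observed = mids_in / len(frags)
        sd = np.sqrt(expected * (1 - expected) / len(frags))
        assert abs(observed - expected) < 3 * sd

    def test_ratio_one_is_uniform(self):
        lengths = {"c": 500_000}
        regions = (Interval("c", 0, 50_000),)  # 10% share
        cfg = synthgen.SimConfig(
            chromosome_lengths=lengths,
            peak_regions=regions,
            fragments_per_replicate=20_000,
            enrichment_ratio=1.0,
            n_replicates=1,
            seed=9,
        )
        genome = synthgen.simulate_genome(cfg)
        (frags,) = synthgen.simulate_fragments(cfg, genome)
        frac = sum(1 for f in frags if f.midpoint < 50_000) / len(frags)
        assert abs(frac - 0.1) < 3 * np.sqrt(0.1 * 0.9 / len(frags))

    def test_full_duplication_collapses_to_one_template(self):
        cfg = synthgen.SimConfig(
            chromosome_lengths={"c": 10_000},
            fragments_per_replicate=100,
            duplicate_fraction=1.0,
            n_replicates=1,
            seed=10,
        )
        genome = synthgen.simulate_genome(cfg)
        (frags,) = synthgen.simulate_fragments(cfg, genome)
        assert len(frags) == 100
        assert len({(f.chrom, f.start, f.end) for f in frags}) == 1


class TestGenesAndExpression:
    def test_all_zero_fraction_gives_zero_tpm(self):
        cfg = synthgen.SimConfig(chromosome_lengths={"c": 100_000}, seed=12)
        genome = synthgen.simulate_genome(cfg)
        _, tpm = synthgen.simulate_genes_and_expression(
            cfg, genome, ["none"] * 10, zero_fraction=1.0
        )
        assert (tpm == 0).all()

    def test_label_median_ordering_recovered(self):
        cfg = synthgen.SimConfig(
            chromosome_lengths={"c1": 3_000_000, "c2": 3_000_000}, seed=13
        )
        genome = synthgen.simulate_genome(cfg)
        labels = (["none"] * 700 + ["iM"] * 700 + ["G4"] * 600)
        genes, tpm = synthgen.simulate_genes_and_expression(
            cfg,
            genome,
            labels,
            label_medians={"none": 1.0, "iM": 2.0, "G4": 8.0, "both": 10.0},
            zero_fraction=0.0,
        )
        med = {
            lab: np.median(
                [tpm[g.gene_id] for g, l in zip(genes, labels) if l == lab]
            )
            for lab in ("none", "iM", "G4")
        }
        assert med["none"] < med["iM"] < med["G4"]

    def test_genes_non_overlapping_and_strand_tss(self):
        cfg = synthgen.SimConfig(chromosome_lengths={"c": 200_000}, seed=14)
        genome = synthgen.simulate_genome(cfg)
        genes, _ = synthgen.simulate_genes_and_expression(
            cfg, genome, ["none"] * 20
        )
        spans = sorted((g.start, g.end) for g in genes)
        assert all(a[1] <= b[0] for a, b in zip(spans, spans[1:]))
        for g in genes:
            assert g.tss == (g.start if g.strand == "+" else g.end - 1)

    def test_too_many_genes_rejected(self):
        cfg = synthgen.SimConfig(chromosome_lengths={"c": 10_000}, seed=15)
        genome = synthgen.simulate_genome(cfg)
        with pytest.raises(ValueError, match="non-overlapping"):
            synthgen.simulate_genes_and_expression(cfg, genome, ["none"] * 50)


class TestConfigFile:
    def test_yaml_round_trip_and_unknown_key_rejection(self, tmp_path):
        path = tmp_path / "sim.yaml"
        path.write_text(
            "chromosome_lengths: {chr1: 1000}\n"
            "gc_fraction: 0.4\n"
            "peak_regions: ['chr1:100-200']\n"
            "motif_plants:\n"
            "  - {base: C, stringency: low, max_loop: 7, inside: 2}\n"
        )
        cfg = synthgen.load_config(path)
        assert cfg.gc_fraction == 0.4
        assert cfg.peak_regions[0] == Interval("chr1", 100, 200)
        assert cfg.motif_plants[0][0].label == "iM_low_short"
        path.write_text("chromosome_lengths: {chr1: 1000}\nbogus: 1\n")
        with pytest.raises(ValueError, match="bogus"):
            synthgen.load_config(path)
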