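"""Synthetic genomes, planted motifs, fragments, genes and expression.

The generator emulates the statistical structure a CUT&Tag downstream
analysis assumes: a small multi-chromosome genome with controllable GC
content, quadruplex motif instances planted at controlled densities inside
versus outside designated peak regions, paired-end-derived fragment sets
concentrated at peak regions with a stated enrichment ratio and independent
replicate noise, non-overlapping gene models with TSSs, and TPM values
whose distribution differs by structure label.

All randomness flows from one root seed through named sub-streams
(``_substream``), so identical configurations give byte-identical outputs.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml

from .genomeio import (
    Genome,
    GeneModel,
    Interval,
    write_bed,
    write_expression_table,
    write_fasta,
    write_gene_table,
)
from .quadmotif import MotifMatch, MotifSpec

__all__ = [
    "SimConfig",
    "load_config",
    "simulate_genome",
    "plant_motifs",
    "simulate_fragments",
    "simulate_genes_and_expression",
    "write_outputs",
]

_KNOWN_KEYS = {
    "chromosome_lengths",
    "gc_fraction",
    "peak_regions",
    "fragments_per_replicate",
    "fragment_length_mean",
    "fragment_length_sd",
    "fragment_length_min",
    "enrichment_ratio",
    "duplicate_fraction",
    "n_replicates",
    "motif_plants",
    "seed",
}


@dataclass(frozen=True)
class SimConfig:
    """Everything the generator needs; defaults are the package's standard
    study conditions (see docs/methods.md for the rationale)."""

    chromosome_lengths: Mapping[str, int] = field(
        default_factory=lambda: {"chr1": 1_000_000, "chr2": 1_000_000}
    )
    gc_fraction: float = 0.45
    peak_regions: tuple[Interval, ...] = ()
    fragments_per_replicate: int = 8000
    fragment_length_mean: float = 150.0
    fragment_length_sd: float = 25.0
    fragment_length_min: int = 50
    enrichment_ratio: float = 10.0
    duplicate_fraction: float = 0.0
    n_replicates: int = 3
    # (spec, inside_count, outside_count) triples
    motif_plants: tuple[tuple[MotifSpec, int, int], ...] = ()
    seed: int = 0

    def __post_init__(self):
        if not self.chromosome_lengths:
            raise ValueError("at least one chromosome required")
        for name, length in self.chromosome_lengths.items():
            if length <= 0:
                raise ValueError(f"non-positive length for {name}")
        if not (0.0 <= self.gc_fraction <= 1.0):
            raise ValueError("gc_fraction must be in [0, 1]")
        if self.enrichment_ratio < 1:
            raise ValueError("enrichment_ratio must be >= 1")
        if self.fragment_length_mean < self.fragment_length_min:
            raise ValueError("fragment_length_mean must be >= fragment_length_min")
        if not (0.0 <= self.duplicate_fraction <= 1.0):
            raise ValueError("duplicate_fraction must be in [0, 1]")


def _substream(seed: int, name: str) -> np.random.Generator:
    """A named child stream of the root seed (stable across processes)."""
    tag = zlib.crc32(name.encode()) & 0x7FFFFFFF
    return np.random.default_rng(np.random.SeedSequence((seed, tag)))


def default_peak_regions(
    config_lengths: Mapping[str, int],
    n_regions: int = 20,
    width: int = 1000,
    seed: int = 0,
) -> tuple[Interval, ...]:
    """Evenly spaced non-overlapping regions, round-robin over chromosomes."""
    names = list(config_lengths)
    per_chrom = {n: [] for n in names}
    for i in range(n_regions):
        per_chrom[names[i % len(names)]].append(i)
    regions = []
    for name in names:
        k = len(per_chrom[name])
        if k == 0:
            continue
        length = config_lengths[name]
        gap = length // (k + 1)
        if gap <= width:
            raise ValueError("too many regions for chromosome length")
        for j in range(k):
            start = (j + 1) * gap
            regions.append(Interval(name, start, start + width))
    return tuple(regions)


def _parse_region(spec: str | Sequence) -> Interval:
    if isinstance(spec, str):
        chrom, span = spec.split(":")
        start, end = span.split("-")
        return Interval(chrom, int(start), int(end))
    chrom, start, end = spec
    return Interval(chrom, int(start), int(end))


def load_config(path: str | Path) -> SimConfig:
    """Load a YAML simulation config; unknown keys are rejected."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    unknown = set(raw) - _KNOWN_KEYS
    if unknown:
        raise ValueError(f"unknown config key(s): {sorted(unknown)}")
    if "peak_regions" in raw:
        raw["peak_regions"] = tuple(_parse_region(r) for r in raw["peak_regions"])
    if "motif_plants" in raw:
        plants = []
        for entry in raw["motif_plants"]:
            spec = MotifSpec.from_labels(
                entry["base"], entry["stringency"], int(entry["max_loop"])
            )
            plants.append((spec, int(entry.get("inside", 0)), int(entry.get("outside", 0))))
        raw["motif_plants"] = tuple(plants)
    return SimConfig(**raw)


# ---------------------------------------------------------------------------
# Genome


def simulate_genome(config: SimConfig) -> Genome:
    """IID bases with P(G) = P(C) = gc_fraction / 2."""
    rng = _substream(config.seed, "genome")
    gc = config.gc_fraction
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    alphabet = np.frombuffer(b"ACGT", dtype=np.uint8)
    seqs = []
    for name, length in config.chromosome_lengths.items():
        draws = rng.choice(4, size=length, p=probs)
        seqs.append((name, alphabet[draws].tobytes().decode("ascii")))
    return Genome(seqs)


# ---------------------------------------------------------------------------
# Motif planting


def plant_motifs(
    genome: Genome,
    plants: Sequence[tuple[MotifSpec, Sequence[Interval] | None, int]],
    seed: int = 0,
) -> tuple[Genome, list[MotifMatch]]:
    """Overwrite the genome with canonical motif instances.

    Each entry is (spec, region set or None for anywhere, count).  Planting
    positions are uniform over the allowed space and planted instances
    never overlap one another, so the returned list is an exact truth set.

    A buffer of 'A's, one base longer than the longest loop (13 bp), is
    cleared on each side of every instance.  Loops accept any base, so
    without the buffer a planted instance could fuse with a nearby genomic
    C/G run into a match with different coordinates; the buffer makes the
    recorded coordinates exactly what any scanner of the class reports.
    Padded footprints of different plants never overlap.
    """
    pad = 13  # max supported loop (12) + 1
    rng = np.random.default_rng(seed)
    seqs = {name: bytearray(seq, "ascii") for name, seq in genome}
    lengths = genome.lengths
    occupied: dict[str, list[tuple[int, int]]] = {name: [] for name in lengths}
    truth: list[MotifMatch] = []

    for spec, regions, count in plants:
        instance = spec.canonical_instance()
        width = len(instance)
        if regions is None:
            windows = [
                Interval(name, 0, length) for name, length in lengths.items()
            ]
        else:
            windows = list(regions)
        placed = 0
        attempts = 0
        max_attempts = 500 * max(count, 1)
        while placed < count:
            attempts += 1
            if attempts > max_attempts:
                raise ValueError(
                    f"insufficient space to plant {count} instances of "
                    f"{spec.label} (placed {placed})"
                )
            w = windows[int(rng.integers(len(windows)))]
            lo = max(w.start, pad)
            hi = min(w.end, lengths[w.chrom] - pad) - width
            if hi < lo:
                continue
            start = int(rng.integers(lo, hi + 1))
            end = start + width
            if any(
                s < end + pad and start - pad < e for s, e in occupied[w.chrom]
            ):
                continue
            seqs[w.chrom][start - pad : end + pad] = (
                b"A" * pad + instance.encode() + b"A" * pad
            )
            occupied[w.chrom].append((start - pad, end + pad))
            truth.append(MotifMatch(w.chrom, start, end, "+", spec))
            placed += 1

    planted_genome = Genome(
        [(name, bytes(seqs[name]).decode("ascii")) for name in lengths]
    )
    truth.sort(key=lambda m: (m.chrom, m.start))
    return planted_genome, truth


# ---------------------------------------------------------------------------
# Fragments


def simulate_fragments(
    config: SimConfig, genome: Genome
) -> list[list[Interval]]:
    """Per-replicate fragment interval sets from a two-rate midpoint mixture.

    A fragment midpoint lands inside a peak region with relative rate
    ``enrichment_ratio`` versus background; lengths are normal, truncated
    below at ``fragment_length_min`` and clipped at chromosome ends.  With
    ``duplicate_fraction`` d, only a fraction (1 - d) of fragments are
    drawn fresh; the remainder re-sample already-drawn fragments, giving
    exact duplicates for complexity-curve tests.
    """
    if genome.total_length == 0:
        raise ValueError("empty genome")
    if config.fragments_per_replicate <= 0:
        raise ValueError("zero fragments requested")

    lengths = genome.lengths
    names = list(lengths)
    chrom_len = np.array([lengths[n] for n in names], dtype=np.int64)
    total = int(chrom_len.sum())

    # per-base midpoint weights: background 1, in-region = enrichment_ratio.
    # Background midpoints are drawn from the complement of the regions so
    # the in-region fraction is exactly ratio*s / (ratio*s + (1-s)) for
    # region share s.
    region_share = sum(iv.width for iv in config.peak_regions) / total
    in_region_mass = config.enrichment_ratio * region_share
    background_mass = 1.0 - region_share
    p_region = in_region_mass / (in_region_mass + background_mass)

    # complement segments (chrom, start, end) of the merged region set
    merged: dict[str, list[tuple[int, int]]] = {n: [] for n in names}
    for iv in sorted(config.peak_regions, key=lambda r: (r.chrom, r.start)):
        runs = merged[iv.chrom]
        if runs and iv.start <= runs[-1][1]:
            runs[-1] = (runs[-1][0], max(runs[-1][1], iv.end))
        else:
            runs.append((iv.start, iv.end))
    bg_segments: list[tuple[str, int, int]] = []
    for name in names:
        pos = 0
        for s, e in merged[name]:
            if s > pos:
                bg_segments.append((name, pos, s))
            pos = e
        if pos < lengths[name]:
            bg_segments.append((name, pos, lengths[name]))
    bg_lens = np.array([e - s for _, s, e in bg_segments], dtype=np.int64)
    bg_offsets = np.concatenate([[0], np.cumsum(bg_lens)])
    bg_total = int(bg_lens.sum())

    region_widths = np.array([iv.width for iv in config.peak_regions], dtype=np.int64)
    replicates = []
    for rep in range(config.n_replicates):
        rng = _substream(config.seed, f"fragments/{rep}")
        n = config.fragments_per_replicate
        n_template = max(1, int(round(n * (1.0 - config.duplicate_fraction))))
        in_region = (
            rng.random(n_template) < p_region
            if config.peak_regions
            else np.zeros(n_template, dtype=bool)
        )
        mids = np.empty(n_template, dtype=np.int64)
        chroms = np.empty(n_template, dtype=object)
        # background draws: uniform over the complement of the regions
        n_bg = int((~in_region).sum())
        flat = rng.integers(0, bg_total, size=n_bg)
        si = np.searchsorted(bg_offsets, flat, side="right") - 1
        mids[~in_region] = flat - bg_offsets[si] + np.array(
            [bg_segments[i][1] for i in si], dtype=np.int64
        )
        chroms[~in_region] = np.array(
            [bg_segments[i][0] for i in si], dtype=object
        )
        # in-region draws: region by width, then uniform inside
        n_in = int(in_region.sum())
        if n_in:
            rw = region_widths / region_widths.sum()
            ri = rng.choice(len(config.peak_regions), size=n_in, p=rw)
            starts = np.array([config.peak_regions[i].start for i in ri])
            widths = region_widths[ri]
            mids[in_region] = starts + (rng.random(n_in) * widths).astype(np.int64)
            chroms[in_region] = np.array(
                [config.peak_regions[i].chrom for i in ri], dtype=object
            )
        frag_len = np.maximum(
            rng.normal(config.fragment_length_mean, config.fragment_length_sd, n_template),
            config.fragment_length_min,
        ).astype(np.int64)

        fragments = []
        for i in range(n_template):
            clen = lengths[chroms[i]]
            start = max(0, int(mids[i]) - int(frag_len[i]) // 2)
            end = min(clen, start + int(frag_len[i]))
            start = max(0, min(start, end - 1))
            fragments.append(
                Interval(chroms[i], start, end, ".", f"rep{rep}_frag{i}")
            )
        # duplicates: re-draw from the templates already generated
        n_dup = n - n_template
        if n_dup > 0:
            picks = rng.integers(0, n_template, size=n_dup)
            for j, pi in enumerate(picks):
                t = fragments[pi]
                fragments.append(
                    Interval(t.chrom, t.start, t.end, ".", f"rep{rep}_dup{j}")
                )
        replicates.append(fragments)
    return replicates


# ---------------------------------------------------------------------------
# Genes and expression


LABEL_MEDIANS = {"none": 1.0, "iM": 2.0, "G4": 8.0, "both": 10.0}


def simulate_genes_and_expression(
    config: SimConfig,
    genome: Genome,
    structure_labels: Mapping[str, str] | Sequence[str],
    gene_length: int = 2000,
    n_exons: int = 2,
    label_medians: Mapping[str, float] = LABEL_MEDIANS,
    log_sigma: float = 1.0,
    zero_fraction: float = 0.1,
) -> tuple[list[GeneModel], "pd.Series"]:
    """Non-overlapping genes tiled over the genome plus label-driven TPMs.

    ``structure_labels`` assigns each gene a structure label in
    {none, iM, G4, both}; TPM ~ LogNormal(log median(label), log_sigma),
    so sample medians are ordered like ``label_medians``.  A
    ``zero_fraction`` of genes (uniform over genes) gets TPM 0.
    """
    import pandas as pd

    if isinstance(structure_labels, Mapping):
        labels = dict(structure_labels)
        gene_ids = list(labels)
    else:
        gene_ids = [f"gene{i:05d}" for i in range(len(structure_labels))]
        labels = dict(zip(gene_ids, structure_labels))
    for lab in labels.values():
        if lab not in label_medians:
            raise ValueError(f"unknown structure label {lab!r}")
    if any(m < 0 for m in label_medians.values()):
        raise ValueError("negative TPM median")

    rng = _substream(config.seed, "genes")
    lengths = genome.lengths
    names = list(lengths)
    n_genes = len(gene_ids)
    # round-robin, evenly spaced, strictly non-overlapping
    per_chrom: dict[str, list[str]] = {n: [] for n in names}
    for i, gid in enumerate(gene_ids):
        per_chrom[names[i % len(names)]].append(gid)
    genes: list[GeneModel] = []
    for name in names:
        ids = per_chrom[name]
        if not ids:
            continue
        slot = lengths[name] // len(ids)
        if slot <= gene_length:
            raise ValueError(
                f"cannot fit {len(ids)} non-overlapping genes of "
                f"{gene_length} bp on {name}"
            )
        for j, gid in enumerate(ids):
            start = j * slot + (slot - gene_length) // 2
            end = start + gene_length
            strand = "+" if rng.random() < 0.5 else "-"
            exon_len = gene_length // (2 * n_exons)
            exons = []
            for k in range(n_exons):
                es = start + k * (gene_length // n_exons)
                exons.append((es, es + exon_len))
            genes.append(GeneModel(gid, name, start, end, strand, tuple(exons)))

    expr_rng = _substream(config.seed, "expression")
    tpm = {}
    for g in genes:
        median = label_medians[labels[g.gene_id]]
        if expr_rng.random() < zero_fraction or median == 0:
            tpm[g.gene_id] = 0.0
        else:
            tpm[g.gene_id] = float(
                np.exp(np.log(median) + log_sigma * expr_rng.standard_normal())
            )
    return genes, pd.Series(tpm, name="tpm")


# ---------------------------------------------------------------------------
# File outputs


def write_outputs(
    outdir: str | Path,
    genome: Genome,
    replicates: Sequence[Sequence[Interval]] | None = None,
    truth: Sequence[MotifMatch] | None = None,
    genes: Sequence[GeneModel] | None = None,
    tpm=None,
) -> dict[str, Path]:
    """Write the standard file set: FASTA genome, per-replicate fragment
    BED6, truth-set BED6, gene table TSV, expression TSV."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    fasta = outdir / "genome.fa"
    write_fasta(genome, fasta)
    written["genome"] = fasta
    if replicates is not None:
        for i, frags in enumerate(replicates):
            p = outdir / f"fragments_rep{i}.bed"
            write_bed(list(frags), p)
            written[f"fragments_rep{i}"] = p
    if truth is not None:
        p = outdir / "planted_motifs.bed"
        write_bed(
            [
                Interval(m.chrom, m.start, m.end, m.strand, m.spec.label, 0)
                for m in truth
            ],
            p,
        )
        written["truth"] = p
    if genes is not None:
        p = outdir / "genes.tsv"
        write_gene_table(list(genes), p)
        written["genes"] = p
    if tpm is not None:
        p = outdir / "expression.tsv"
        write_expression_table(tpm, p)
        written["expression"] = p
    return written
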