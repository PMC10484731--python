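"""Peak annotation, genomic-abundance-normalized feature distributions and
TSS-centered signal matrices.

Annotation uses a reduced category set (Promoter, Exon, Intron, Downstream,
Distal intergenic; no UTR classes, which simple gene tables cannot supply)
with a strict priority order, anchored at the peak midpoint so every peak
receives exactly one category.  The promoter window is a mandatory,
strand-aware parameter: for a minus-strand gene "upstream" means larger
coordinates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .genomeio import Genome, GeneModel, Interval

__all__ = [
    "AnnotationRecord",
    "CATEGORIES",
    "annotate_peaks",
    "normalized_feature_distribution",
    "tss_matrix",
]

CATEGORIES = ("Promoter", "Exon", "Intron", "Downstream", "Distal intergenic")


@dataclass(frozen=True)
class AnnotationRecord:
    peak: Interval
    category: str
    distance_to_tss: int | None  # signed; negative = upstream of nearest TSS
    gene_id: str | None


def _signed_tss_offset(mid: int, gene: GeneModel) -> int:
    """Offset of a position from the gene's TSS in the gene's reading
    direction; negative values are upstream."""
    return mid - gene.tss if gene.strand == "+" else gene.tss - mid


def annotate_peaks(
    peaks: Sequence[Interval],
    genes: Sequence[GeneModel],
    promoter_window: tuple[int, int] = (-1000, 1000),
    downstream_window: int = 3000,
) -> list[AnnotationRecord]:
    """One category per peak by priority:
    Promoter > Exon > Intron > Downstream > Distal intergenic.

    The peak is anchored at its midpoint.  Ties between genes are broken
    by smaller |distance to TSS|, then lexicographic gene id.
    """
    lo, hi = promoter_window
    if hi <= lo:
        raise ValueError("promoter window must be a nonempty (lo, hi) pair")
    if downstream_window <= 0:
        raise ValueError("downstream window must be positive")
    records = []
    for peak in peaks:
        mid = peak.midpoint
        same_chrom = [g for g in genes if g.chrom == peak.chrom]
        if not genes:
            records.append(AnnotationRecord(peak, "Distal intergenic", None, None))
            continue
        nearest = None
        if same_chrom:
            nearest = min(
                same_chrom,
                key=lambda g: (abs(_signed_tss_offset(mid, g)), g.gene_id),
            )
        category = "Distal intergenic"
        gene: GeneModel | None = nearest

        promoter_hits = [
            g for g in same_chrom if lo <= _signed_tss_offset(mid, g) <= hi
        ]
        exon_hits = [
            g
            for g in same_chrom
            if any(s <= mid < e for s, e in g.exons)
        ]
        intron_hits = [
            g for g in same_chrom if g.start <= mid < g.end and g not in exon_hits
        ]
        downstream_hits = []
        for g in same_chrom:
            if g.strand == "+" and g.end <= mid < g.end + downstream_window:
                downstream_hits.append(g)
            elif g.strand == "-" and g.start - downstream_window <= mid < g.start:
                downstream_hits.append(g)

        for cat, hits in (
            ("Promoter", promoter_hits),
            ("Exon", exon_hits),
            ("Intron", intron_hits),
            ("Downstream", downstream_hits),
        ):
            if hits:
                category = cat
                gene = min(
                    hits, key=lambda g: (abs(_signed_tss_offset(mid, g)), g.gene_id)
                )
                break
        distance = _signed_tss_offset(mid, gene) if gene is not None else None
        records.append(
            AnnotationRecord(
                peak, category, distance, gene.gene_id if gene else None
            )
        )
    return records


def _category_masks(
    genome: Genome,
    genes: Sequence[GeneModel],
    promoter_window: tuple[int, int],
    downstream_window: int,
) -> dict[str, int]:
    """Base counts per category under the same priority order used for
    peaks (each base belongs to exactly one category)."""
    lo, hi = promoter_window
    code = {c: i for i, c in enumerate(CATEGORIES)}
    totals = {c: 0 for c in CATEGORIES}
    for chrom, length in genome.lengths.items():
        mask = np.full(length, code["Distal intergenic"], dtype=np.uint8)
        chrom_genes = [g for g in genes if g.chrom == chrom]
        # paint lowest priority first so higher priorities overwrite
        for g in chrom_genes:
            if g.strand == "+":
                s, e = g.end, min(length, g.end + downstream_window)
            else:
                s, e = max(0, g.start - downstream_window), g.start
            if s < e:
                mask[s:e] = code["Downstream"]
        for g in chrom_genes:
            mask[g.start : g.end] = code["Intron"]
        for g in chrom_genes:
            for s, e in g.exons:
                mask[s:e] = code["Exon"]
        for g in chrom_genes:
            if g.strand == "+":
                s, e = g.tss + lo, g.tss + hi + 1
            else:
                s, e = g.tss - hi, g.tss - lo + 1
            s, e = max(0, s), min(length, e)
            if s < e:
                mask[s:e] = code["Promoter"]
        counts = np.bincount(mask, minlength=len(CATEGORIES))
        for c, i in code.items():
            totals[c] += int(counts[i])
    return totals


def normalized_feature_distribution(
    annotations: Sequence[AnnotationRecord],
    genome: Genome,
    genes: Sequence[GeneModel],
    promoter_window: tuple[int, int] = (-1000, 1000),
    downstream_window: int = 3000,
) -> dict[str, float]:
    """Peak-category percentages normalized by each category's genomic
    abundance: ratio_c = (peak fraction in c) / (genome base fraction in c),
    then rescaled so the ratios sum to 100."""
    if not annotations:
        raise ValueError("no annotations")
    totals = _category_masks(genome, genes, promoter_window, downstream_window)
    genome_total = sum(totals.values())
    n_peaks = len(annotations)
    peak_counts = {c: 0 for c in CATEGORIES}
    for rec in annotations:
        peak_counts[rec.category] += 1
    ratios = {}
    for c in CATEGORIES:
        base_frac = totals[c] / genome_total
        peak_frac = peak_counts[c] / n_peaks
        if base_frac == 0:
            if peak_frac > 0:
                warnings.warn(
                    f"category {c!r} has zero genomic footprint but "
                    f"{peak_counts[c]} peaks; excluded from normalization"
                )
            continue
        ratios[c] = peak_frac / base_frac
    total_ratio = sum(ratios.values())
    if total_ratio == 0:
        raise ValueError("all categories empty")
    return {c: 100.0 * r / total_ratio for c, r in ratios.items()}


def tss_matrix(
    track,
    genes: Sequence[GeneModel],
    genome: Genome,
    flank: int = 1000,
    bin_size: int = 25,
    scale: str = "none",
):
    """Gene x bin matrix of mean per-base signal across [TSS-flank,
    TSS+flank), oriented upstream -> downstream (minus-strand rows are
    flipped).  Bins clipped at chromosome edges are NaN and excluded from
    the column-mean profile.  ``scale='zscore'`` standardizes with the
    matrix-global mean and SD (SD 0 => all zeros).

    Returns (matrix, profile, gene_ids).
    """
    if flank % bin_size != 0:
        raise ValueError("flank must be divisible by bin_size")
    n_bins = 2 * flank // bin_size
    lengths = genome.lengths
    dense_cache: dict[str, np.ndarray] = {}
    matrix = np.full((len(genes), n_bins), np.nan)
    for gi, g in enumerate(genes):
        if g.chrom not in dense_cache:
            dense_cache[g.chrom] = track.dense(g.chrom, lengths[g.chrom])
        dense = dense_cache[g.chrom]
        window_start = g.tss - flank
        row = np.full(n_bins, np.nan)
        for b in range(n_bins):
            s = window_start + b * bin_size
            e = s + bin_size
            if s < 0 or e > lengths[g.chrom]:
                continue  # clipped bin stays missing
            row[b] = dense[s:e].mean()
        if g.strand == "-":
            row = row[::-1]
        matrix[gi] = row
    if scale == "zscore":
        finite = matrix[np.isfinite(matrix)]
        sd = finite.std() if finite.size else 0.0
        if sd == 0:
            matrix = np.where(np.isfinite(matrix), 0.0, np.nan)
        else:
            matrix = (matrix - finite.mean()) / sd
    elif scale != "none":
        raise ValueError(f"unknown scale {scale!r}")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        profile = np.nanmean(matrix, axis=0)
    return matrix, profile, [g.gene_id for g in genes]
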