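"""Normalized coverage tracks and CUT&Tag QC metrics.

RPGC (reads-per-genomic-content, "1x") normalization scales a raw coverage
track so that the genome-wide mean per-base coverage is exactly 1.  Because
the inputs here are fragments rather than reads, the scale factor is
(total genome length) / (summed fragment lengths), which makes the 1x
contract exact rather than approximate.

QC metrics: FRiP (exact fragment-fraction and position-sampled estimate),
replicate Pearson correlation over genome-wide bins, saturation curves by
fragment subsampling, and library-complexity curves (expected distinct
fragments among n drawn without replacement, by the exact hypergeometric
formula or empirical subsampling).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.special import gammaln

from .genomeio import Genome, Interval, SignalTrack, intervals_to_pyranges

__all__ = [
    "coverage_track",
    "pearson_correlation",
    "frip",
    "saturation_curve",
    "complexity_curve",
    "QcReport",
    "qc_report",
]


def coverage_track(
    fragments: Sequence[Interval],
    genome: Genome,
    bin_size: int = 5,
    normalization: str = "RPGC",
) -> SignalTrack:
    """Binned fragment coverage; bin value = mean per-base coverage in bin.

    With RPGC the genome-wide mean per-base coverage is exactly 1.
    """
    if not fragments:
        raise ValueError("empty fragment set")
    if bin_size < 1:
        raise ValueError("bin_size must be >= 1")
    lengths = genome.lengths
    diffs = {chrom: np.zeros(length + 1) for chrom, length in lengths.items()}
    total_frag_bases = 0
    for f in fragments:
        if f.chrom not in lengths or f.end > lengths[f.chrom]:
            raise ValueError(f"fragment {f} outside genome")
        diffs[f.chrom][f.start] += 1
        diffs[f.chrom][f.end] -= 1
        total_frag_bases += f.width
    if normalization == "RPGC":
        scale = genome.total_length / total_frag_bases
    elif normalization in (None, "none", "raw"):
        scale = 1.0
    else:
        raise ValueError(f"unknown normalization {normalization!r}")
    dense = {}
    for chrom, length in lengths.items():
        cov = np.cumsum(diffs[chrom][:-1]) * scale
        n_bins = -(-length // bin_size)
        padded = np.zeros(n_bins * bin_size)
        padded[:length] = cov
        sums = padded.reshape(n_bins, bin_size).sum(axis=1)
        widths = np.full(n_bins, bin_size, dtype=float)
        if length % bin_size:
            widths[-1] = length % bin_size
        per_bin = sums / widths
        dense[chrom] = np.repeat(per_bin, bin_size)[:length]
    return SignalTrack.from_dense(dense)


def pearson_correlation(
    track_a: SignalTrack, track_b: SignalTrack, genome: Genome, bin_size: int
) -> float:
    """Product-moment correlation over all genome bins, zeros included."""
    a = track_a.binned(genome, bin_size)
    b = track_b.binned(genome, bin_size)
    if a.size < 2:
        raise ValueError("need at least 2 bins")
    if np.std(a) == 0 or np.std(b) == 0:
        raise ValueError("undefined correlation: zero variance in a binned track")
    return float(np.corrcoef(a, b)[0, 1])


def frip(
    fragments: Sequence[Interval],
    peaks: Sequence[Interval],
    genome: Genome | None = None,
    method: str = "exact",
    n_positions: int = 10000,
    seed: int = 0,
) -> float:
    """Fraction of fragments in peaks.

    exact: share of fragments overlapping >= 1 peak by >= 1 bp.
    sampled: fragment-coverage mass at uniformly sampled 1-bp genome
    positions inside peaks over the mass at all sampled positions
    (a coverage-weighted estimate in the style of position-sampling tools).
    An empty peak set gives 0.0 by definition.
    """
    if not fragments:
        raise ValueError("empty fragment set")
    if not peaks:
        return 0.0
    if method == "exact":
        frag_pr = intervals_to_pyranges(fragments)
        hit = frag_pr.overlap(intervals_to_pyranges(peaks))
        n_hit = 0 if hit.empty else len(hit.df)
        return n_hit / len(fragments)
    if method == "sampled":
        if genome is None:
            raise ValueError("sampled FRiP needs a genome")
        if n_positions < 1:
            raise ValueError("n_positions must be >= 1")
        rng = np.random.default_rng(seed)
        lengths = genome.lengths
        names = list(lengths)
        chrom_len = np.array([lengths[n] for n in names], dtype=np.int64)
        total = int(chrom_len.sum())
        flat = rng.choice(total, size=min(n_positions, total), replace=False)
        offsets = np.concatenate([[0], np.cumsum(chrom_len)])
        cov = {c: np.zeros(l) for c, l in lengths.items()}
        for f in fragments:
            cov[f.chrom][f.start : f.end] += 1
        in_peak = {c: np.zeros(l, dtype=bool) for c, l in lengths.items()}
        for p in peaks:
            in_peak[p.chrom][p.start : p.end] = True
        num = den = 0.0
        ci = np.searchsorted(offsets, flat, side="right") - 1
        pos = flat - offsets[ci]
        for c_idx, p in zip(ci, pos):
            chrom = names[c_idx]
            den += cov[chrom][p]
            if in_peak[chrom][p]:
                num += cov[chrom][p]
        return num / den if den > 0 else 0.0
    raise ValueError(f"unknown FRiP method {method!r}")


def saturation_curve(
    replicate_fragments: Sequence[Sequence[Interval]],
    genome: Genome,
    fractions: Sequence[float],
    threshold: float = 0.01,
    bin_size: int = 5,
    seed: int = 0,
) -> list[tuple[float, float]]:
    """Mean fragments-in-called-peaks across replicates at each subsampling
    depth.  Each replicate is subsampled without replacement, its track is
    rebuilt, peaks are re-called, and its subsampled fragments counted
    against its own called peaks."""
    from .peakcall import call_peaks

    if list(fractions) != sorted(fractions):
        raise ValueError("fractions must be sorted ascending")
    if any(f <= 0 or f > 1 for f in fractions):
        raise ValueError("fractions must lie in (0, 1]")
    if not replicate_fragments:
        raise ValueError("need >= 1 replicate")
    rng = np.random.default_rng(seed)
    curve = []
    for f in fractions:
        per_rep = []
        for frags in replicate_fragments:
            n_sub = max(1, int(round(f * len(frags))))
            if n_sub >= len(frags):
                sub = list(frags)
            else:
                idx = rng.choice(len(frags), size=n_sub, replace=False)
                sub = [frags[i] for i in sorted(idx)]
            track = coverage_track(sub, genome, bin_size=bin_size)
            peaks = call_peaks(track, threshold=threshold)
            peak_ivs = [p.interval for p in peaks]
            if peak_ivs:
                hit = intervals_to_pyranges(sub).overlap(
                    intervals_to_pyranges(peak_ivs)
                )
                per_rep.append(0 if hit.empty else len(hit.df))
            else:
                per_rep.append(0)
        curve.append((float(f), float(np.mean(per_rep))))
    return curve


def _fragment_key(f: Interval) -> tuple:
    return (f.chrom, f.start, f.end, f.strand)


def complexity_curve(
    fragments: Sequence[Interval],
    step: int,
    method: str = "exact",
    n_rounds: int = 20,
    seed: int = 0,
) -> list[tuple[int, float]]:
    """Expected distinct fragments among n drawn without replacement, for
    n = step, 2*step, ... <= total.

    Duplicate identity is the exact (chrom, start, end, strand) tuple.
    exact: E[distinct] = sum_u 1 - C(N - c_u, n) / C(N, n) over unique
    fragments u with copy count c_u.  empirical: mean over ``n_rounds``
    random subsamples.
    """
    if step <= 0:
        raise ValueError("step must be >= 1")
    if not fragments:
        raise ValueError("empty fragment set")
    keys = [_fragment_key(f) for f in fragments]
    N = len(keys)
    counts: dict[tuple, int] = {}
    for k in keys:
        counts[k] = counts.get(k, 0) + 1
    copy_counts = np.array(list(counts.values()), dtype=np.int64)
    ns = list(range(step, N + 1, step))
    curve = []
    if method == "exact":
        for n in ns:
            # log C(N-c, n) - log C(N, n), exactly 0 distinct prob when n > N-c
            expected = 0.0
            for c, mult in zip(*np.unique(copy_counts, return_counts=True)):
                if n > N - c:
                    p_absent = 0.0
                else:
                    p_absent = np.exp(
                        _log_comb(N - c, n) - _log_comb(N, n)
                    )
                expected += mult * (1.0 - p_absent)
            curve.append((n, float(expected)))
        return curve
    if method == "empirical":
        rng = np.random.default_rng(seed)
        key_idx = np.array([list(counts).index(k) for k in keys])
        for n in ns:
            distinct = [
                len(np.unique(key_idx[rng.choice(N, size=n, replace=False)]))
                for _ in range(n_rounds)
            ]
            curve.append((n, float(np.mean(distinct))))
        return curve
    raise ValueError(f"unknown method {method!r}")


def _log_comb(n: int, k: int) -> float:
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


@dataclass
class QcReport:
    frip_exact: float
    frip_sampled: float
    pearson: dict[tuple[int, int], float]
    saturation: list[tuple[float, float]]
    complexity: dict[int, list[tuple[int, float]]]
    seed: int

    def to_dict(self) -> dict:
        return {
            "frip_exact": self.frip_exact,
            "frip_sampled": self.frip_sampled,
            "pearson": {f"{a}_vs_{b}": r for (a, b), r in self.pearson.items()},
            "saturation": self.saturation,
            "complexity": {str(k): v for k, v in self.complexity.items()},
            "seed": self.seed,
        }


def qc_report(
    replicate_fragments: Sequence[Sequence[Interval]],
    peaks: Sequence[Interval],
    genome: Genome,
    bin_size: int = 5,
    frip_positions: int = 10000,
    fractions: Sequence[float] = (0.25, 0.5, 0.75, 1.0),
    threshold: float = 0.01,
    complexity_step: int | None = None,
    seed: int = 0,
) -> QcReport:
    """One-call QC summary over all replicates (pooled FRiP, pairwise
    Pearson, saturation and per-replicate complexity curves)."""
    pooled = [f for rep in replicate_fragments for f in rep]
    tracks = [
        coverage_track(rep, genome, bin_size=bin_size) for rep in replicate_fragments
    ]
    pearson = {}
    for i in range(len(tracks)):
        for j in range(i + 1, len(tracks)):
            pearson[(i, j)] = pearson_correlation(
                tracks[i], tracks[j], genome, bin_size
            )
    step = complexity_step or max(1, len(replicate_fragments[0]) // 10)
    complexity = {
        i: complexity_curve(rep, step=step)
        for i, rep in enumerate(replicate_fragments)
    }
    return QcReport(
        frip_exact=frip(pooled, peaks, method="exact"),
        frip_sampled=frip(
            pooled, peaks, genome, method="sampled",
            n_positions=frip_positions, seed=seed,
        ),
        pearson=pearson,
        saturation=saturation_curve(
            replicate_fragments, genome, fractions,
            threshold=threshold, bin_size=bin_size, seed=seed,
        ),
        complexity=complexity,
        seed=seed,
    )
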