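"""SEACR-style peak calling, replicate consensus and peak-set comparison.

The caller emulates the numeric-threshold ("stringent", no-control) mode of
block-AUC peak callers for sparse CUT&Tag tracks: maximal contiguous blocks
of strictly positive signal are enumerated, each is scored by its total
signal (area under the curve, value x bp), and the top ceil(threshold x B)
blocks by AUC are retained, where B is the number of blocks; blocks tied
with the cutoff AUC are all kept.  Exact parity with any external caller
is a non-goal.

High-confidence peaks are the coordinate-wise intersections present in
every replicate (chained pairwise interval intersection, >= 1 bp at each
step).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .genomeio import (
    Genome,
    Interval,
    SignalTrack,
    intervals_to_pyranges,
    pyranges_to_intervals,
)

__all__ = [
    "Peak",
    "SignalClass",
    "call_peaks",
    "consensus_peaks",
    "classify_signal_quartiles",
    "shared_unique",
    "peak_width_stats",
]


@dataclass(frozen=True)
class Peak:
    """A called block with its AUC (total signal) and maximum run value."""

    chrom: str
    start: int
    end: int
    total_signal: float
    max_signal: float
    sample_id: str = ""

    def __post_init__(self):
        if self.start >= self.end:
            raise ValueError("empty peak interval")
        if self.total_signal <= 0 or self.max_signal <= 0:
            raise ValueError("peak signal must be positive")

    @property
    def interval(self) -> Interval:
        return Interval(self.chrom, self.start, self.end, ".", self.sample_id or None)

    @property
    def width(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class SignalClass:
    label: str  # bottom | middle | top
    q1: float
    q3: float


def _signal_blocks(track: SignalTrack) -> list[Peak]:
    """Maximal contiguous blocks of strictly positive signal."""
    blocks = []
    for chrom in track.chroms:
        starts, ends, values = track.runs(chrom)
        pos = values > 0
        starts, ends, values = starts[pos], ends[pos], values[pos]
        if starts.size == 0:
            continue
        block_start = starts[0]
        block_auc = 0.0
        block_max = 0.0
        prev_end = starts[0]
        for s, e, v in zip(starts, ends, values):
            if s > prev_end:
                blocks.append(
                    Peak(chrom, int(block_start), int(prev_end), block_auc, block_max)
                )
                block_start = s
                block_auc = 0.0
                block_max = 0.0
            block_auc += float(v) * (e - s)
            block_max = max(block_max, float(v))
            prev_end = e
        blocks.append(Peak(chrom, int(block_start), int(prev_end), block_auc, block_max))
    return blocks


def call_peaks(
    track: SignalTrack, threshold: float = 0.01, sample_id: str = ""
) -> list[Peak]:
    """Top ceil(threshold x B) signal blocks by AUC, cutoff ties included."""
    if not (0 < threshold < 1):
        raise ValueError("threshold must lie in (0, 1)")
    blocks = _signal_blocks(track)
    if not blocks:
        warnings.warn("all-zero track: no signal blocks, empty peak list")
        return []
    n_keep = math.ceil(threshold * len(blocks))
    aucs = sorted((b.total_signal for b in blocks), reverse=True)
    cutoff = aucs[n_keep - 1]
    kept = [b for b in blocks if b.total_signal >= cutoff]
    kept.sort(key=lambda b: (b.chrom, b.start))
    if sample_id:
        kept = [
            Peak(b.chrom, b.start, b.end, b.total_signal, b.max_signal, sample_id)
            for b in kept
        ]
    return kept


def consensus_peaks(
    replicate_peaks: Sequence[Sequence[Peak] | Sequence[Interval]],
) -> list[Interval]:
    """Chained pairwise intersection across all replicates.

    Output regions are the maximal spans present (>= 1 bp) in every
    replicate, sorted and non-overlapping.
    """
    if len(replicate_peaks) < 2:
        raise ValueError("consensus needs >= 2 replicates")

    def to_intervals(peaks):
        return [p.interval if isinstance(p, Peak) else p for p in peaks]

    current = intervals_to_pyranges(to_intervals(replicate_peaks[0])).merge()
    for rep in replicate_peaks[1:]:
        nxt = intervals_to_pyranges(to_intervals(rep)).merge()
        if current.empty or nxt.empty:
            return []
        current = current.intersect(nxt).merge()
        if current.empty:
            return []
    return sorted(pyranges_to_intervals(current))


def classify_signal_quartiles(peaks: Sequence[Peak]) -> list[tuple[Peak, SignalClass]]:
    """bottom <= Q1, middle strictly inside the IQR, top >= Q3.

    Quartiles are linear-interpolation ("type 7") quantiles of total
    signal.  Assignment checks top first, then bottom, so an all-equal
    distribution is labelled entirely top.
    """
    if not peaks:
        raise ValueError("empty peak list")
    signals = np.array([p.total_signal for p in peaks])
    q1, q3 = np.quantile(signals, [0.25, 0.75])
    out = []
    for p in peaks:
        if p.total_signal >= q3:
            label = "top"
        elif p.total_signal <= q1:
            label = "bottom"
        else:
            label = "middle"
        out.append((p, SignalClass(label, float(q1), float(q3))))
    return out


def shared_unique(
    set_a: Sequence[Interval], set_b: Sequence[Interval]
) -> dict:
    """Anchored overlap counts between two peak sets.

    shared_a counts A intervals overlapping >= 1 B interval (and shared_b
    the converse); the two need not be equal.  Percentages are rounded
    half-up to integers for reporting.
    """

    def count_overlapping(xs, ys):
        if not xs or not ys:
            return 0
        hit = intervals_to_pyranges(xs).overlap(intervals_to_pyranges(ys))
        return 0 if hit.empty else len(hit.df)

    shared_a = count_overlapping(list(set_a), list(set_b))
    shared_b = count_overlapping(list(set_b), list(set_a))

    def pct(shared, total):
        if total == 0:
            return 0
        return int(math.floor(100 * shared / total + 0.5))

    return {
        "shared_a": shared_a,
        "shared_b": shared_b,
        "unique_a": len(set_a) - shared_a,
        "unique_b": len(set_b) - shared_b,
        "pct_shared_a": pct(shared_a, len(set_a)),
        "pct_shared_b": pct(shared_b, len(set_b)),
    }


def peak_width_stats(
    peaks: Sequence[Peak] | Sequence[Interval], hist_bin_width: int = 50
) -> dict:
    """Median and quartiles of peak widths plus a fixed-width histogram."""
    if not peaks:
        raise ValueError("empty peak set")
    widths = np.array(
        [p.width for p in peaks]
        if isinstance(peaks[0], Peak)
        else [iv.end - iv.start for iv in peaks]
    )
    q1, med, q3 = np.quantile(widths, [0.25, 0.5, 0.75])
    edges = np.arange(0, widths.max() + hist_bin_width, hist_bin_width)
    if edges.size < 2:
        edges = np.array([0, hist_bin_width])
    counts, edges = np.histogram(widths, bins=edges)
    return {
        "median": float(med),
        "q1": float(q1),
        "q3": float(q3),
        "histogram": list(zip(edges[:-1].tolist(), counts.tolist())),
    }
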