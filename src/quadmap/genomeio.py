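"""Shared genomic types and flat-file I/O.

Every coordinate in this package is 0-based, half-open, exactly as in BED.
This module is the single place where that convention meets the file
formats (FASTA, BED3/BED6, bedGraph, gene-table TSV, expression TSV).
All TSVs are tab-separated with one header line starting ``#``.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

VALID_BASES = frozenset("ACGTN")
STRANDS = ("+", "-", ".")

__all__ = [
    "Genome",
    "Interval",
    "SignalTrack",
    "GeneModel",
    "read_fasta",
    "write_fasta",
    "read_bed",
    "write_bed",
    "read_bedgraph",
    "write_bedgraph",
    "read_gene_table",
    "write_gene_table",
    "read_expression_table",
    "write_expression_table",
    "intervals_to_pyranges",
    "pyranges_to_intervals",
]


class Genome:
    """An ordered set of named chromosome sequences.

    Sequences are uppercase strings over {A, C, G, T, N}; chromosome order
    is preserved everywhere (FASTA round-trips are order-identical).
    """

    def __init__(self, sequences: dict[str, str] | Iterable[tuple[str, str]]):
        items = sequences.items() if isinstance(sequences, dict) else list(sequences)
        self._seqs: dict[str, str] = {}
        for name, seq in items:
            if not name:
                raise ValueError("empty chromosome name")
            if name in self._seqs:
                raise ValueError(f"duplicate chromosome name: {name!r}")
            seq = seq.upper()
            if not seq:
                raise ValueError(f"chromosome {name!r} has zero length")
            bad = set(seq) - VALID_BASES
            if bad:
                raise ValueError(
                    f"illegal character(s) {sorted(bad)} in chromosome {name!r}"
                )
            self._seqs[name] = seq

    @property
    def names(self) -> list[str]:
        return list(self._seqs)

    @property
    def lengths(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self._seqs.items()}

    @property
    def total_length(self) -> int:
        return sum(len(s) for s in self._seqs.values())

    def sequence(self, chrom: str) -> str:
        return self._seqs[chrom]

    def fetch(self, chrom: str, start: int, end: int) -> str:
        seq = self._seqs[chrom]
        if not (0 <= start < end <= len(seq)):
            raise ValueError(
                f"span [{start}, {end}) out of bounds for {chrom} (len {len(seq)})"
            )
        return seq[start:end]

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._seqs

    def __iter__(self):
        return iter(self._seqs.items())

    def __eq__(self, other) -> bool:
        return isinstance(other, Genome) and self._seqs == other._seqs

    def __repr__(self) -> str:
        return f"Genome({len(self._seqs)} chromosomes, {self.total_length} bp)"


@dataclass(frozen=True, order=True)
class Interval:
    """A 0-based half-open genomic span."""

    chrom: str
    start: int
    end: int
    strand: str = "."
    name: str | None = field(default=None, compare=False)
    score: float | None = field(default=None, compare=False)

    def __post_init__(self):
        if self.start < 0 or self.start >= self.end:
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}) on {self.chrom}"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"strand must be one of {STRANDS}, got {self.strand!r}")

    @property
    def width(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def validate_against(self, genome: Genome) -> "Interval":
        if self.chrom not in genome:
            raise ValueError(f"unknown chromosome {self.chrom!r}")
        if self.end > genome.lengths[self.chrom]:
            raise ValueError(
                f"interval [{self.start}, {self.end}) exceeds {self.chrom} "
                f"length {genome.lengths[self.chrom]}"
            )
        return self


class SignalTrack:
    """Per-chromosome sorted, non-overlapping value runs (bedGraph semantics).

    The value function is zero wherever no run covers a base.  Runs with
    equal value that touch may be merged; the value function is the
    invariant, not the run decomposition.
    """

    def __init__(self, runs: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]]):
        self._runs: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        for chrom, (starts, ends, values) in runs.items():
            starts = np.asarray(starts, dtype=np.int64)
            ends = np.asarray(ends, dtype=np.int64)
            values = np.asarray(values, dtype=np.float64)
            order = np.argsort(starts, kind="stable")
            starts, ends, values = starts[order], ends[order], values[order]
            if np.any(starts >= ends):
                raise ValueError(f"empty or inverted run on {chrom}")
            if np.any(starts[1:] < ends[:-1]):
                raise ValueError(f"overlapping runs on {chrom}")
            if np.any(~np.isfinite(values)) or np.any(values < 0):
                raise ValueError(f"values must be finite and >= 0 on {chrom}")
            self._runs[chrom] = (starts, ends, values)

    @property
    def chroms(self) -> list[str]:
        return list(self._runs)

    def runs(self, chrom: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        return self._runs.get(
            chrom,
            (np.empty(0, np.int64), np.empty(0, np.int64), np.empty(0, np.float64)),
        )

    def dense(self, chrom: str, length: int) -> np.ndarray:
        """Per-base values on [0, length); zero outside runs."""
        out = np.zeros(length, dtype=np.float64)
        starts, ends, values = self.runs(chrom)
        for s, e, v in zip(starts, ends, values):
            out[s:e] = v
        return out

    def binned(self, genome: Genome, bin_size: int) -> np.ndarray:
        """Mean per-base value per bin, concatenated over chromosomes in
        genome order.  The final (possibly partial) bin of each chromosome
        averages only over its real bases."""
        if bin_size < 1:
            raise ValueError("bin_size must be >= 1")
        pieces = []
        for chrom, length in genome.lengths.items():
            dense = self.dense(chrom, length)
            n_bins = -(-length // bin_size)
            padded = np.zeros(n_bins * bin_size)
            padded[:length] = dense
            sums = padded.reshape(n_bins, bin_size).sum(axis=1)
            widths = np.full(n_bins, bin_size, dtype=np.float64)
            if length % bin_size:
                widths[-1] = length % bin_size
            pieces.append(sums / widths)
        return np.concatenate(pieces) if pieces else np.empty(0)

    def value_at(self, chrom: str, pos: int) -> float:
        starts, ends, values = self.runs(chrom)
        i = np.searchsorted(starts, pos, side="right") - 1
        if i >= 0 and pos < ends[i]:
            return float(values[i])
        return 0.0

    def mean_coverage(self, genome: Genome) -> float:
        total = 0.0
        for chrom in self._runs:
            starts, ends, values = self._runs[chrom]
            total += float(np.sum((ends - starts) * values))
        return total / genome.total_length

    def scaled(self, factor: float) -> "SignalTrack":
        return SignalTrack(
            {c: (s.copy(), e.copy(), v * factor) for c, (s, e, v) in self._runs.items()}
        )

    @classmethod
    def from_dense(
        cls, per_chrom: dict[str, np.ndarray], drop_zero: bool = True
    ) -> "SignalTrack":
        runs = {}
        for chrom, arr in per_chrom.items():
            arr = np.asarray(arr, dtype=np.float64)
            if arr.size == 0:
                continue
            change = np.flatnonzero(arr[1:] != arr[:-1]) + 1
            starts = np.concatenate([[0], change])
            ends = np.concatenate([change, [arr.size]])
            values = arr[starts]
            if drop_zero:
                keep = values != 0
                starts, ends, values = starts[keep], ends[keep], values[keep]
            if starts.size:
                runs[chrom] = (starts, ends, values)
        return cls(runs)


@dataclass(frozen=True)
class GeneModel:
    """A gene span with strand, derived TSS, and exon structure.

    TSS is the gene start on '+' and ``end - 1`` on '-' (the last covered
    base, since coordinates are half-open).
    """

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    exons: tuple[tuple[int, int], ...] = ()

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene strand must be + or -, got {self.strand!r}")
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid gene span [{self.start}, {self.end})")
        prev_end = self.start
        for s, e in self.exons:
            if s < prev_end or e > self.end or s >= e:
                raise ValueError(
                    f"exons of {self.gene_id} must be sorted, non-overlapping "
                    f"and inside the gene span"
                )
            prev_end = e

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end - 1

    @property
    def span(self) -> Interval:
        return Interval(self.chrom, self.start, self.end, self.strand, self.gene_id)


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path) -> Genome:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    pairs = []
    seen = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate FASTA header: {rec.id!r}")
        seen.add(rec.id)
        pairs.append((rec.id, str(rec.seq)))
    if not pairs:
        raise ValueError(f"no FASTA records in {path}")
    return Genome(pairs)


def write_fasta(genome: Genome, path: str | Path, line_width: int = 70) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in genome
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=line_width)
        writer.write_file(records)


# ---------------------------------------------------------------------------
# BED


def read_bed(path: str | Path, genome: Genome | None = None) -> list[Interval]:
    intervals = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: expected >= 3 BED fields")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinate") from exc
            name = fields[3] if len(fields) > 3 and fields[3] != "." else None
            score = None
            if len(fields) > 4 and fields[4] not in (".", ""):
                score = float(fields[4])
            strand = fields[5] if len(fields) > 5 else "."
            try:
                iv = Interval(chrom, start, end, strand, name, score)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
            if genome is not None:
                iv.validate_against(genome)
            intervals.append(iv)
    return intervals


def write_bed(intervals: Sequence[Interval], path: str | Path) -> None:
    """BED6 when any interval carries a name/score/strand, else BED3."""
    bed6 = any(
        iv.name is not None or iv.score is not None or iv.strand != "."
        for iv in intervals
    )
    with open(path, "w") as fh:
        for iv in intervals:
            if bed6:
                score = "0" if iv.score is None else format_number(iv.score)
                fh.write(
                    f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name or '.'}\t"
                    f"{score}\t{iv.strand}\n"
                )
            else:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")


def format_number(x: float) -> str:
    return str(int(x)) if float(x).is_integer() else repr(float(x))


# ---------------------------------------------------------------------------
# bedGraph


def read_bedgraph(path: str | Path) -> SignalTrack:
    per_chrom: dict[str, list[tuple[int, int, float]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ValueError(f"{path}:{lineno}: expected 4 bedGraph fields")
            try:
                value = float(fields[3])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-numeric value field") from exc
            if value < 0:
                raise ValueError(f"{path}:{lineno}: negative value {value}")
            per_chrom.setdefault(fields[0], []).append(
                (int(fields[1]), int(fields[2]), value)
            )
    runs = {}
    for chrom, triples in per_chrom.items():
        arr = np.array(triples, dtype=np.float64)
        runs[chrom] = (
            arr[:, 0].astype(np.int64),
            arr[:, 1].astype(np.int64),
            arr[:, 2],
        )
    return SignalTrack(runs)


def write_bedgraph(track: SignalTrack, path: str | Path) -> None:
    """Zero-valued runs are dropped on write (the value function is
    unchanged: absent spans read back as zero)."""
    with open(path, "w") as fh:
        for chrom in track.chroms:
            starts, ends, values = track.runs(chrom)
            for s, e, v in zip(starts, ends, values):
                if v != 0:
                    fh.write(f"{chrom}\t{s}\t{e}\t{format_number(v)}\n")


# ---------------------------------------------------------------------------
# Gene table / expression TSV


GENE_TABLE_HEADER = "#gene_id\tchrom\tstart\tend\tstrand\texon_starts\texon_ends"


def write_gene_table(genes: Sequence[GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(GENE_TABLE_HEADER + "\n")
        for g in genes:
            exon_starts = ",".join(str(s) for s, _ in g.exons)
            exon_ends = ",".join(str(e) for _, e in g.exons)
            fh.write(
                f"{g.gene_id}\t{g.chrom}\t{g.start}\t{g.end}\t{g.strand}\t"
                f"{exon_starts}\t{exon_ends}\n"
            )


def read_gene_table(path: str | Path) -> list[GeneModel]:
    genes = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) != 7:
                raise ValueError(f"{path}:{lineno}: expected 7 gene-table fields")
            exon_starts = [int(x) for x in f[5].split(",") if x]
            exon_ends = [int(x) for x in f[6].split(",") if x]
            if len(exon_starts) != len(exon_ends):
                raise ValueError(f"{path}:{lineno}: exon start/end count mismatch")
            genes.append(
                GeneModel(
                    gene_id=f[0],
                    chrom=f[1],
                    start=int(f[2]),
                    end=int(f[3]),
                    strand=f[4],
                    exons=tuple(zip(exon_starts, exon_ends)),
                )
            )
    return genes


def write_expression_table(tpm: dict[str, float] | pd.Series, path: str | Path) -> None:
    series = pd.Series(tpm, dtype=float)
    with open(path, "w") as fh:
        fh.write("#gene_id\ttpm\n")
        for gene_id, value in series.items():
            fh.write(f"{gene_id}\t{format_number(value)}\n")


def read_expression_table(path: str | Path) -> pd.Series:
    df = pd.read_csv(
        path, sep="\t", comment=None, names=["gene_id", "tpm"], skiprows=1
    )
    series = pd.Series(df["tpm"].to_numpy(float), index=df["gene_id"], name="tpm")
    if (series < 0).any():
        raise ValueError("negative TPM in expression table")
    return series


# ---------------------------------------------------------------------------
# pyranges bridge (interval set algebra is delegated to pyranges)


def intervals_to_pyranges(intervals: Sequence[Interval]):
    import pyranges as pr

    if not intervals:
        return pr.PyRanges()
    return pr.PyRanges(
        pd.DataFrame(
            {
                "Chromosome": [iv.chrom for iv in intervals],
                "Start": [iv.start for iv in intervals],
                "End": [iv.end for iv in intervals],
            }
        )
    )


def pyranges_to_intervals(granges) -> list[Interval]:
    if granges.empty:
        return []
    df = granges.df
    return [
        Interval(str(row.Chromosome), int(row.Start), int(row.End))
        for row in df.itertuples()
    ]
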