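"""Putative i-motif / G-quadruplex sequence prediction and enrichment.

A quadruplex pattern class is defined by the tract base (C for i-motifs,
G for G-quadruplexes), a minimum tract length, a tract count, and a maximum
loop length.  Three stringency levels are used in the field:

* low     — four tracts of at least two bases each
* medium  — four tracts of at least three bases each
* high    — five tracts of at least three bases each (the "spare tyre"
            arrangement with a fifth tract)

combined with two loop-length ranges, 0–7 (short) and 0–12 (long), giving
six classes per base.  Matching is the classic quadparser-style regular
expression: greedy tracts, loops over {A,C,G,T}, leftmost non-overlapping
matches.  N never matches inside a tract or a loop.

Fold enrichment of a class within a region set is the observed match count
on the extracted region sequences divided by the mean count over
length-preserving random relocations of the regions (a shuffle null).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .genomeio import Genome, Interval

__all__ = [
    "MotifSpec",
    "MotifMatch",
    "EnrichmentResult",
    "STRINGENCY_PARAMS",
    "all_specs",
    "build_pattern",
    "scan",
    "scan_genome",
    "shuffle_regions",
    "fold_enrichment",
    "gc_enrichment",
]

COMPLEMENT = {"C": "G", "G": "C"}

# stringency -> (min tract length, tract count)
STRINGENCY_PARAMS = {"low": (2, 4), "medium": (3, 4), "high": (3, 5)}
LOOP_LABELS = {7: "short", 12: "long"}


@dataclass(frozen=True)
class MotifSpec:
    """One quadruplex pattern class."""

    base: str  # "C" (iM) or "G" (G4)
    min_tract: int
    n_tracts: int
    max_loop: int

    def __post_init__(self):
        if self.base not in ("C", "G"):
            raise ValueError("base must be 'C' or 'G'")
        if (self.min_tract, self.n_tracts) not in STRINGENCY_PARAMS.values():
            raise ValueError(
                f"unsupported tract geometry ({self.min_tract}, {self.n_tracts})"
            )
        if self.max_loop < 0:
            raise ValueError("max_loop must be >= 0")

    @property
    def stringency(self) -> str:
        for label, params in STRINGENCY_PARAMS.items():
            if params == (self.min_tract, self.n_tracts):
                return label
        raise AssertionError("unreachable")

    @property
    def loop_label(self) -> str:
        return LOOP_LABELS.get(self.max_loop, f"loop{self.max_loop}")

    @property
    def label(self) -> str:
        structure = "iM" if self.base == "C" else "G4"
        return f"{structure}_{self.stringency}_{self.loop_label}"

    @classmethod
    def from_labels(cls, base: str, stringency: str, max_loop: int) -> "MotifSpec":
        m, k = STRINGENCY_PARAMS[stringency]
        return cls(base=base, min_tract=m, n_tracts=k, max_loop=max_loop)

    def canonical_instance(self) -> str:
        """Minimal-tract, single-base-loop realization of the class.

        Loops use 'A' (never the tract base) so class membership of the
        planted string is unambiguous and the instance cannot extend into
        surrounding sequence on the tract side.
        """
        tract = self.base * self.min_tract
        return ("%sA" % tract) * (self.n_tracts - 1) + tract


@dataclass(frozen=True)
class MotifMatch:
    """A scanner hit in plus-strand coordinates."""

    chrom: str
    start: int
    end: int
    strand: str
    spec: MotifSpec

    @property
    def interval(self) -> Interval:
        return Interval(self.chrom, self.start, self.end, self.strand)


@dataclass
class EnrichmentResult:
    spec: MotifSpec
    observed: int
    shuffled_counts: list[int]
    seed: int
    infinite: bool = False

    @property
    def mean_shuffled(self) -> float:
        return float(np.mean(self.shuffled_counts))

    @property
    def sd_shuffled(self) -> float:
        return float(np.std(self.shuffled_counts, ddof=1)) if len(
            self.shuffled_counts
        ) > 1 else 0.0

    @property
    def fold(self) -> float:
        mean = self.mean_shuffled
        if mean == 0:
            # flagged infinite when observed > 0; fold reported as observed
            return float(self.observed)
        return self.observed / mean


def all_specs(
    bases: Iterable[str] = ("C", "G"), loops: Iterable[int] = (7, 12)
) -> list[MotifSpec]:
    """The full class grid: stringency x loop for each requested base."""
    return [
        MotifSpec.from_labels(base, stringency, loop)
        for base in bases
        for stringency in STRINGENCY_PARAMS
        for loop in loops
    ]


def build_pattern(spec: MotifSpec) -> str:
    """The class as a regular-expression string.

    ``n_tracts - 1`` repetitions of (greedy tract)(loop of 0..max_loop any
    base), terminated by a final tract.  Loops draw from {A,C,G,T}; N is
    excluded everywhere.
    """
    tract = f"{spec.base}{{{spec.min_tract},}}"
    loop = f"[ACGT]{{0,{spec.max_loop}}}"
    return f"(?:{tract}{loop}){{{spec.n_tracts - 1}}}{tract}"


def scan(
    sequence: str,
    specs: Sequence[MotifSpec],
    chrom: str = "seq",
    strands: str = "both",
    offset: int = 0,
) -> list[MotifMatch]:
    """Leftmost, greedy, non-overlapping matches per (spec, strand).

    Minus-strand search scans the plus-strand sequence for the
    complementary-base pattern and reports plus-strand coordinates with
    strand '-'.  Matches of different specs may overlap; within one
    (spec, strand) they never do.
    """
    sequence = sequence.upper()
    matches: list[MotifMatch] = []
    want = ("+", "-") if strands == "both" else (strands,)
    for spec in specs:
        for strand in want:
            search_spec = (
                spec
                if strand == "+"
                else MotifSpec(
                    COMPLEMENT[spec.base], spec.min_tract, spec.n_tracts, spec.max_loop
                )
            )
            pattern = re.compile(build_pattern(search_spec))
            for m in pattern.finditer(sequence):
                matches.append(
                    MotifMatch(chrom, offset + m.start(), offset + m.end(), strand, spec)
                )
    matches.sort(key=lambda x: (x.chrom, x.start, x.end, x.strand, x.spec.label))
    return matches


def scan_genome(
    genome: Genome, specs: Sequence[MotifSpec], strands: str = "both"
) -> list[MotifMatch]:
    out: list[MotifMatch] = []
    for chrom, seq in genome:
        out.extend(scan(seq, specs, chrom=chrom, strands=strands))
    return out


def shuffle_regions(
    regions: Sequence[Interval], genome: Genome, seed: int | np.random.Generator
) -> list[Interval]:
    """Relocate each region independently, preserving its width.

    Chromosome drawn with probability proportional to length among those
    that can hold the region; start uniform in [0, chrom_len - width].
    Shuffled regions may overlap each other.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    names = list(genome.lengths)
    lengths = np.array([genome.lengths[n] for n in names], dtype=np.int64)
    out = []
    for iv in regions:
        fits = lengths >= iv.width
        if not fits.any():
            raise ValueError(
                f"region of width {iv.width} fits no chromosome "
                f"(max length {int(lengths.max())})"
            )
        probs = np.where(fits, lengths, 0).astype(float)
        probs /= probs.sum()
        ci = rng.choice(len(names), p=probs)
        start = int(rng.integers(0, lengths[ci] - iv.width + 1))
        out.append(Interval(names[ci], start, start + iv.width))
    return out


def _count_in_regions(
    regions: Sequence[Interval],
    genome: Genome,
    specs: Sequence[MotifSpec],
    mode: str,
) -> dict[MotifSpec, int]:
    """Match counts per spec on the extracted region sequences.

    mode='matches' counts scanner hits; mode='regions' counts regions
    containing at least one hit.
    """
    counts = {spec: 0 for spec in specs}
    for iv in regions:
        seq = genome.fetch(iv.chrom, iv.start, iv.end)
        hits = scan(seq, specs, chrom=iv.chrom, offset=iv.start)
        if mode == "matches":
            for h in hits:
                counts[h.spec] += 1
        elif mode == "regions":
            for spec in {h.spec for h in hits}:
                counts[spec] += 1
        else:
            raise ValueError(f"unknown counting mode {mode!r}")
    return counts


def fold_enrichment(
    regions: Sequence[Interval],
    genome: Genome,
    specs: Sequence[MotifSpec] | None = None,
    n: int = 10,
    seed: int = 0,
    mode: str = "matches",
) -> list[EnrichmentResult]:
    """Observed motif counts within regions vs a shuffle null.

    One shared set of ``n`` shuffles serves every spec.  ``fold`` is
    observed / mean(shuffled); a zero null with nonzero observed is
    flagged infinite, never a division error.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if specs is None:
        specs = all_specs()
    for iv in regions:
        iv.validate_against(genome)
    observed = _count_in_regions(regions, genome, specs, mode)
    rng = np.random.default_rng(seed)
    shuffled: dict[MotifSpec, list[int]] = {spec: [] for spec in specs}
    for _ in range(n):
        relocated = shuffle_regions(regions, genome, rng)
        counts = _count_in_regions(relocated, genome, specs, mode)
        for spec in specs:
            shuffled[spec].append(counts[spec])
    results = []
    for spec in specs:
        obs = observed[spec]
        null = shuffled[spec]
        results.append(
            EnrichmentResult(
                spec=spec,
                observed=obs,
                shuffled_counts=null,
                seed=seed,
                infinite=(np.mean(null) == 0 and obs > 0),
            )
        )
    return results


def gc_enrichment(
    regions: Sequence[Interval],
    genome: Genome,
    n: int = 100,
    seed: int = 0,
) -> dict:
    """Permutation test of region GC content against shuffled placements.

    p = (1 + #{null >= observed}) / (n + 1), one-sided for enrichment.
    """
    if not regions:
        raise ValueError("empty region set")
    rng = np.random.default_rng(seed)

    def gc_fraction(ivs: Sequence[Interval]) -> float:
        gc = total = 0
        for iv in ivs:
            seq = genome.fetch(iv.chrom, iv.start, iv.end)
            gc += seq.count("G") + seq.count("C")
            total += len(seq)
        return gc / total

    observed = gc_fraction(regions)
    null = np.array(
        [gc_fraction(shuffle_regions(regions, genome, rng)) for _ in range(n)]
    )
    p = (1 + int(np.sum(null >= observed))) / (n + 1)
    return {
        "observed_gc": observed,
        "null_mean_gc": float(null.mean()),
        "effect_size": observed - float(null.mean()),
        "p_value": p,
        "n_shuffles": n,
    }
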