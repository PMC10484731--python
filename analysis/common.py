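"""Shared study design for the analysis drivers.

A two-antibody synthetic experiment on a 2 Mb genome: 200 genes, of which
10 carry both structures at their promoter, 10 iM only, 10 G4 only.  Peak
regions are 1 kb windows centred on the TSSs of the structure-carrying
genes; iM-motif instances are planted in iM regions, G4 instances in G4
regions, and a sparse background of both everywhere else.  Each antibody
gets three fragment replicates enriched (ratio 10) at its own region set.
TPM medians are ordered none < iM < G4 < both.

Every driver reads its inputs from, and writes its outputs to,
``results/`` so the stages communicate only through the standard formats.
"""

from pathlib import Path

import numpy as np

from quadmap import synthgen
from quadmap.genomeio import Interval
from quadmap.quadmotif import MotifSpec

ROOT = Path(__file__).resolve().parent.parent
RESULTS = ROOT / "results"
# bulky regenerable intermediates (FASTA, fragment BEDs, bedGraphs) live
# under scratch/; only the small result tables go to results/
DATA = ROOT / "scratch" / "analysis_data"
TRACKS = ROOT / "scratch" / "tracks"

SEED = 0
GENOME_LENGTHS = {"chr1": 1_000_000, "chr2": 1_000_000}
GC = 0.45
N_GENES = 200
N_BOTH, N_IM_ONLY, N_G4_ONLY = 10, 10, 10
REGION_HALF_WIDTH = 500
FRAGMENTS_PER_REPLICATE = 8000
N_REPLICATES = 3
ENRICHMENT_RATIO = 10.0
BIN_SIZE = 5
CORRELATION_BIN = 500  # replicate correlation uses coarser bins than tracks
SEACR_THRESHOLD = 0.01
PROMOTER_WINDOW = (-1000, 1000)
TSS_WINDOW = 3000
N_SHUFFLES = 10


def gene_structure_labels(rng: np.random.Generator) -> dict[str, str]:
    ids = [f"gene{i:05d}" for i in range(N_GENES)]
    chosen = rng.choice(N_GENES, size=N_BOTH + N_IM_ONLY + N_G4_ONLY, replace=False)
    labels = {gid: "none" for gid in ids}
    for j, gi in enumerate(chosen):
        labels[ids[gi]] = (
            "both" if j < N_BOTH else "iM" if j < N_BOTH + N_IM_ONLY else "G4"
        )
    return labels


def tss_region(gene, half_width=REGION_HALF_WIDTH) -> Interval:
    start = max(0, gene.tss - half_width)
    return Interval(gene.chrom, start, gene.tss + half_width)


def sim_config(peak_regions=(), seed=SEED) -> synthgen.SimConfig:
    return synthgen.SimConfig(
        chromosome_lengths=GENOME_LENGTHS,
        gc_fraction=GC,
        peak_regions=tuple(peak_regions),
        fragments_per_replicate=FRAGMENTS_PER_REPLICATE,
        n_replicates=N_REPLICATES,
        enrichment_ratio=ENRICHMENT_RATIO,
        seed=seed,
    )


PLANT_SPECS = [
    MotifSpec.from_labels(base, stringency, 7)
    for base in "CG"
    for stringency in ("low", "medium", "high")
]
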