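"""Generate the synthetic two-antibody study: genome, planted motifs,
iM/G4 fragment replicates, gene models and expression table.

Writes results/data/: genome.fa, {im,g4}_fragments_rep{0..2}.bed,
planted_motifs.bed, {im,g4}_regions.bed, genes.tsv, expression.tsv.
"""

import sys
from pathlib import Path

import numpy as np

sys.path.insert(0, str(Path(__file__).resolve().parent))
import common
from common import DATA, PLANT_SPECS, SEED

from quadmap import synthgen
from quadmap.genomeio import write_bed


def main() -> None:
    DATA.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(SEED)
    labels = common.gene_structure_labels(rng)

    # gene models first (on a throwaway config: placement only needs lengths)
    base_cfg = common.sim_config()
    genome = synthgen.simulate_genome(base_cfg)
    genes, tpm = synthgen.simulate_genes_and_expression(base_cfg, genome, labels)
    by_id = {g.gene_id: g for g in genes}

    im_regions = [
        common.tss_region(by_id[gid])
        for gid, lab in labels.items()
        if lab in ("iM", "both")
    ]
    g4_regions = [
        common.tss_region(by_id[gid])
        for gid, lab in labels.items()
        if lab in ("G4", "both")
    ]

    # plant C-instances in iM regions, G-instances in G4 regions, plus a
    # genome-wide background of every class
    im_specs = [s for s in PLANT_SPECS if s.base == "C"]
    g4_specs = [s for s in PLANT_SPECS if s.base == "G"]
    plants = (
        [(s, im_regions, 8) for s in im_specs]
        + [(s, g4_regions, 8) for s in g4_specs]
        + [(s, None, 20) for s in PLANT_SPECS]
    )
    genome, truth = synthgen.plant_motifs(genome, plants, seed=SEED)

    im_frags = synthgen.simulate_fragments(
        common.sim_config(im_regions, seed=SEED), genome
    )
    g4_frags = synthgen.simulate_fragments(
        common.sim_config(g4_regions, seed=SEED + 1), genome
    )

    synthgen.write_outputs(DATA, genome, truth=truth, genes=genes, tpm=tpm)
    for name, reps in (("im", im_frags), ("g4", g4_frags)):
        for i, frags in enumerate(reps):
            write_bed(frags, DATA / f"{name}_fragments_rep{i}.bed")
    write_bed(im_regions, DATA / "im_regions.bed")
    write_bed(g4_regions, DATA / "g4_regions.bed")

    n_shared = sum(1 for lab in labels.values() if lab == "both")
    print(
        f"genome {genome.total_length:,} bp; {len(genes)} genes "
        f"({n_shared} both, {len(im_regions)} iM regions, "
        f"{len(g4_regions)} G4 regions); planted {len(truth)} motif instances; "
        f"2 antibodies x {len(im_frags)} replicates x "
        f"{len(im_frags[0]):,} fragments"
    )


if __name__ == "__main__":
    main()
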