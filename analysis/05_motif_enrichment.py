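"""Quadruplex-motif prediction within the consensus peaks: fold enrichment
of every stringency x loop class against the shuffle null, plus the GC
permutation test.

Reads results/data/ and results/peaks/, writes
results/motif_enrichment_{im,g4}.tsv and results/gc_enrichment.json.
"""

import json
import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
from common import DATA, N_SHUFFLES, RESULTS, SEED

from quadmap import quadmotif
from quadmap.genomeio import read_bed, read_fasta
from quadmap.quadmotif import all_specs


def main() -> None:
    genome = read_fasta(DATA / "genome.fa")
    gc_results = {}
    for antibody, bases in (("im", ("C",)), ("g4", ("G",))):
        consensus = read_bed(RESULTS / "peaks" / f"{antibody}_consensus.bed", genome)
        results = quadmotif.fold_enrichment(
            consensus, genome, all_specs(bases=bases), n=N_SHUFFLES, seed=SEED
        )
        df = pd.DataFrame(
            {
                "label": [r.spec.label for r in results],
                "observed": [r.observed for r in results],
                "mean_null": [r.mean_shuffled for r in results],
                "sd_null": [r.sd_shuffled for r in results],
                "fold": [r.fold for r in results],
            }
        )
        df.to_csv(RESULTS / f"motif_enrichment_{antibody}.tsv", sep="\t", index=False)
        print(f"{antibody} consensus ({len(consensus)} regions):")
        print(df.to_string(index=False, float_format=lambda x: f"{x:.2f}"))
        by_stringency = {
            s: df[df.label.str.contains(s)].fold.mean()
            for s in ("low", "medium", "high")
        }
        print(
            "  mean fold low -> medium -> high: "
            + " -> ".join(f"{by_stringency[s]:.2f}" for s in ("low", "medium", "high"))
        )
        gc_results[antibody] = quadmotif.gc_enrichment(
            consensus, genome, n=199, seed=SEED
        )
        print(
            f"  GC: observed {gc_results[antibody]['observed_gc']:.3f} vs "
            f"null {gc_results[antibody]['null_mean_gc']:.3f} "
            f"(p = {gc_results[antibody]['p_value']:.4f})\n"
        )
    (RESULTS / "gc_enrichment.json").write_text(json.dumps(gc_results, indent=2))


if __name__ == "__main__":
    main()
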