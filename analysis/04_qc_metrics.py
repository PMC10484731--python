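"""QC of the simulated CUT&Tag reactions: FRiP against the consensus
peaks, saturation curves by subsampling, and library-complexity curves.

Reads results/data/ and results/peaks/, writes results/qc_{im,g4}.json.
"""

import json
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
from common import BIN_SIZE, DATA, N_REPLICATES, RESULTS, SEACR_THRESHOLD, SEED

from quadmap import tracks
from quadmap.genomeio import read_bed, read_fasta


def main() -> None:
    genome = read_fasta(DATA / "genome.fa")
    for antibody in ("im", "g4"):
        replicates = [
            read_bed(DATA / f"{antibody}_fragments_rep{i}.bed", genome)
            for i in range(N_REPLICATES)
        ]
        consensus = read_bed(RESULTS / "peaks" / f"{antibody}_consensus.bed", genome)
        report = tracks.qc_report(
            replicates,
            consensus,
            genome,
            bin_size=BIN_SIZE,
            frip_positions=10_000,
            fractions=(0.25, 0.5, 0.75, 1.0),
            threshold=SEACR_THRESHOLD,
            seed=SEED,
        )
        (RESULTS / f"qc_{antibody}.json").write_text(
            json.dumps(report.to_dict(), indent=2)
        )
        sat = ", ".join(f"{f:.2f}:{v:.0f}" for f, v in report.saturation)
        print(
            f"{antibody}: FRiP exact {report.frip_exact:.3f} "
            f"(sampled {report.frip_sampled:.3f}); saturation {sat}"
        )


if __name__ == "__main__":
    main()
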