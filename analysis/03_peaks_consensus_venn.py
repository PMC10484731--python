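"""Call block-AUC peaks per replicate, intersect the three replicates into
high-confidence consensus sets, classify peaks by signal quartiles, and
compare the iM and G4 consensus sets (shared/unique counts).

Reads results/tracks/, writes results/peaks/ and results/venn.json.
"""

import json
import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
from common import N_REPLICATES, RESULTS, SEACR_THRESHOLD, TRACKS

from quadmap import peakcall
from quadmap.genomeio import read_bed, read_bedgraph, write_bed


def main() -> None:
    outdir = RESULTS / "peaks"
    outdir.mkdir(parents=True, exist_ok=True)
    consensus = {}
    for antibody in ("im", "g4"):
        replicate_peaks = []
        for i in range(N_REPLICATES):
            track = read_bedgraph(TRACKS / f"{antibody}_rep{i}.bedgraph")
            peaks = peakcall.call_peaks(
                track, threshold=SEACR_THRESHOLD, sample_id=f"{antibody}_rep{i}"
            )
            replicate_peaks.append(peaks)
            pd.DataFrame(
                {
                    "chrom": [p.chrom for p in peaks],
                    "start": [p.start for p in peaks],
                    "end": [p.end for p in peaks],
                    "total_signal": [p.total_signal for p in peaks],
                    "max_signal": [p.max_signal for p in peaks],
                }
            ).to_csv(outdir / f"{antibody}_rep{i}.tsv", sep="\t", index=False)
        cons = peakcall.consensus_peaks(replicate_peaks)
        consensus[antibody] = cons
        write_bed(cons, outdir / f"{antibody}_consensus.bed")
        widths = peakcall.peak_width_stats(cons)
        classes = peakcall.classify_signal_quartiles(replicate_peaks[0])
        n_top = sum(1 for _, c in classes if c.label == "top")
        print(
            f"{antibody}: {[len(p) for p in replicate_peaks]} peaks/replicate, "
            f"{len(cons)} high-confidence consensus regions, "
            f"median width {widths['median']:.0f} bp "
            f"(rep0 signal classes: {n_top} top of {len(classes)})"
        )

    venn = peakcall.shared_unique(consensus["im"], consensus["g4"])
    (RESULTS / "venn.json").write_text(json.dumps(venn, indent=2))
    print(
        f"\niM vs G4 consensus: {venn['shared_a']} shared iM-peaks "
        f"({venn['pct_shared_a']}% of iM), {venn['unique_b']} unique G4-peaks "
        f"({100 - venn['pct_shared_b']}% of G4)"
    )


if __name__ == "__main__":
    main()
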