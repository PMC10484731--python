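"""Integrate consensus peaks with the expression table: quartile-based
expression categories, structure-by-expression tables, and overlap of the
iM set with the G4 set as an external comparator.

Reads results/data/ and results/peaks/; writes
results/structure_by_expression.tsv, results/expression_by_category.tsv
and results/external_overlap.json.
"""

import json
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
from common import DATA, RESULTS, TSS_WINDOW

from quadmap import expression as expr
from quadmap.genomeio import read_bed, read_expression_table, read_fasta, read_gene_table


def main() -> None:
    genome = read_fasta(DATA / "genome.fa")
    genes = read_gene_table(DATA / "genes.tsv")
    tpm = read_expression_table(DATA / "expression.tsv")
    im = read_bed(RESULTS / "peaks" / "im_consensus.bed", genome)
    g4 = read_bed(RESULTS / "peaks" / "g4_consensus.bed", genome)

    result = expr.structure_by_expression(genes, im, g4, tpm, tss_window=TSS_WINDOW)
    result["by_structure"].to_csv(RESULTS / "structure_by_expression.tsv", sep="\t")
    result["by_category"].to_csv(RESULTS / "expression_by_category.tsv", sep="\t")

    print("expression-category percentages per structure label:")
    print(result["by_structure"].round(1).to_string())
    med = {k: v["median"] for k, v in result["tpm_summary"].items()}
    print(
        "\nmedian TPM (1.5xIQR-trimmed): "
        + ", ".join(f"{k} {v:.2f}" for k, v in sorted(med.items(), key=lambda x: x[1]))
    )

    overlap = expr.external_overlap(im, g4)
    (RESULTS / "external_overlap.json").write_text(json.dumps(overlap, indent=2))
    print(
        f"\n{100 * overlap['fraction']:.0f}% of iM consensus peaks overlap "
        f"the G4 set ({overlap['shared']} of {len(im)})"
    )


if __name__ == "__main__":
    main()
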