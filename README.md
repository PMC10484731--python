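# quadmap

Downstream analysis of i-motif (iM) and G-quadruplex (G4) CUT&Tag
experiments: peak calling, replicate consensus, quadruplex-motif
prediction with a shuffle-based enrichment null, genomic annotation, QC
metrics, and integration with gene-expression categories.

i-motifs are four-stranded structures formed by hemiprotonated C–C⁺ pairs
in cytosine-rich DNA; G-quadruplexes are their guanine-rich counterparts.
CUT&Tag maps where antibodies against these structures bind in the genome,
producing fragment sets concentrated at structure-forming loci.  This
package implements every computational stage downstream of alignment, and
ships a synthetic-data generator that emulates the statistical structure
of such an experiment (enriched fragment mixtures, planted motif
instances, replicate noise, expression–structure coupling), so the whole
pipeline runs and is tested end-to-end on a 2 Mb toy genome with no
external downloads.  It is aimed at analysts who want a transparent,
reproducible re-implementation of this analysis style — every stage is a
plain Python function over BED/bedGraph/FASTA/TSV files.

## Methods at a glance

**Peak calling** emulates the numeric-threshold "stringent" mode of
block-AUC callers for sparse CUT&Tag tracks (SEACR style): maximal
contiguous blocks of strictly positive signal are scored by total signal
AUC = Σ value·bp, and the top ⌈θ·B⌉ of B blocks are kept (θ = 0.01 by
default, ties included).  High-confidence peaks are the coordinate-wise
intersections present in all replicates.

**Motif prediction** uses the classic quadparser pattern family

    (B{m,} N{0,L}){k−1} B{m,}     B ∈ {C, G}

with (m, k) = (2, 4) low, (3, 4) medium, (3, 5) high stringency ("spare
tyre" fifth tract), and loop lengths L ∈ {7, 12} — six classes per base.
Fold enrichment of a class within peak regions is

    F = n_observed / mean_i(n_shuffled,i),   i = 1..10,

where each shuffle relocates every region uniformly at random
(width-preserving) and re-scans the extracted sequence.

**Coverage tracks** are RPGC-normalized (scale factor = genome length /
summed fragment length) so genome-wide mean coverage is exactly 1×.
**QC** covers FRiP (exact fragment fraction and a 10,000-position sampled
estimate), replicate Pearson correlation over genome-wide bins,
saturation curves by subsampling, and library-complexity curves via the
exact hypergeometric expectation of distinct fragments.

**Annotation** assigns each peak midpoint one category by priority
Promoter > Exon > Intron > Downstream > Distal intergenic, and feature
distributions are normalized by each category's genomic abundance.
**Expression integration** splits expressed genes (TPM > 0) by quartiles
into low/medium/high, labels genes both/A-only/B-only/none by peak
presence within 3 kb of the TSS, and tabulates the two against each other.

## Worked example

The `analysis/` scripts run the complete study on a simulated
two-antibody experiment (2 Mb genome, 200 genes, 3 replicates × 8,000
fragments per antibody, enrichment ratio 10):

```sh
python analysis/01_simulate.py
python analysis/02_coverage_tracks.py
python analysis/03_peaks_consensus_venn.py
python analysis/04_qc_metrics.py
python analysis/05_motif_enrichment.py
python analysis/06_annotation_profiles.py
python analysis/07_expression_integration.py
```

Stage 03 prints

```
im: [42, 42, 41] peaks/replicate, 25 high-confidence consensus regions, median width 985 bp ...
iM vs G4 consensus: 13 shared iM-peaks (52% of iM), 11 unique G4-peaks (46% of G4)
```

— the caller recovers the planted peak regions, and the shared/unique
split reflects the simulated design (10 of 20 structure loci carry both
structures).  Stage 05 prints the motif fold enrichments for the iM
consensus peaks:

```
          label  observed  mean_null  sd_null  fold
   iM_low_short        70      40.60     4.27  1.72
    iM_low_long       128      90.10     9.65  1.42
iM_medium_short        27       2.10     2.64 12.86
 iM_medium_long        27       2.80     2.57  9.64
  iM_high_short        12       1.00     1.89 12.00
   iM_high_long        12       1.00     1.89 12.00
  mean fold low -> medium -> high: 1.57 -> 11.25 -> 12.00
```

Every class is enriched (fold > 1) and enrichment rises with prediction
stringency: low-stringency patterns also match abundant background C/G
runs (high null counts), while medium/high matches are almost all planted
instances.  Stage 07 closes the loop with expression:

```
median TPM (1.5xIQR-trimmed): none 0.85, A-only 1.27, B-only 3.58, both 6.36
```

recovering the simulated ordering none < iM-only < G4-only < both.  All
tables land in `results/`; bulky intermediates (FASTA, fragment BEDs,
bedGraph tracks) are regenerated under `scratch/`.

The same stages are available as subcommands of the `quadmap` console
script (`simulate`, `callpeaks`, `consensus`, `venn`, `scan`, `enrich`,
`gc`, `annotate`, `profile`, `qc`, `integrate`, `run`, `demo`); `quadmap
demo --outdir out --seed 0` runs the whole pipeline in one call and
writes a manifest with every seed and output digest.

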