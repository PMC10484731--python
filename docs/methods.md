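# Methods

## Scope and data model

The package implements the downstream computational analysis of
quadruplex-structure CUT&Tag experiments.  Inputs are aligned fragment
intervals (BED), per-replicate signal tracks (bedGraph), a genome (FASTA),
gene models (TSV) and a TPM expression table; everything upstream of
aligned fragments (read QC, alignment) is out of scope.  All coordinates
are 0-based half-open everywhere in the code and in every file the
package writes; the `genomeio` readers and writers are the only place the
convention meets a file format.

## Synthetic data generator

Because real quadruplex CUT&Tag data require multi-gigabase genomes and
deposited sequencing runs, every stage is exercised on synthetic genomes
whose statistical structure matches what the analysis assumes:

* **Genome.**  IID bases with P(G) = P(C) = GC/2; default GC 0.45,
  2 × 1 Mb chromosomes.
* **Planted motifs.**  Each pattern class has a canonical minimal
  instance (minimal tracts, single-A loops; e.g. `CCACCACCACC` for
  low-stringency iM).  Instances are placed uniformly at random within
  the allowed windows with a 13 bp cleared `A` buffer on each side — one
  base longer than the longest loop — so a planted instance can never
  fuse with a neighbouring C/G run into a match with different
  coordinates.  The recorded plant list is therefore an exact truth set:
  scanner recall at the recorded coordinates is 1 by construction, and
  tested.
* **Fragments.**  Midpoints follow a two-rate mixture: inside designated
  peak regions the per-base rate is `enrichment_ratio` (default 10)
  times the background rate, and background midpoints are drawn from the
  complement of the regions, so the expected in-region fragment fraction
  is exactly r·s / (r·s + 1 − s) for region share s.  Lengths are normal
  (mean 150 bp, SD 25, floor 50 — tagmentation-scale fragments), clipped
  at chromosome ends.  Replicates are independent sub-streams of the
  root seed; an optional duplicate fraction re-samples already-drawn
  fragments for complexity-curve tests.
* **Genes and expression.**  Non-overlapping genes tiled round-robin
  across chromosomes; TSS = start on `+`, end − 1 on `-`.  TPM is
  log-normal with the median set by the gene's structure label (defaults
  none 1 < iM 2 < G4 8 ≤ both 10, σ_log = 1) plus a zero-TPM fraction
  (default 0.1), so quartile-based integration can recover the label
  ordering.
* **Determinism.**  All randomness flows from one integer seed through
  named sub-streams (CRC-tagged `SeedSequence` children), so identical
  configurations give byte-identical outputs across processes.

Default study conditions (peak regions 1 kb wide, 20 regions on 2 Mb,
8,000 fragments/replicate, ratio 10) were chosen so the full analysis
runs in seconds while each stage operates in its intended regime.  The
peak-region width of 1 kb exceeds the experimentally typical ~150 bp
because a called block extends roughly half a fragment length beyond the
planted region on each side; recovering planted regions at base-level
Jaccard ≥ 0.8 requires the planted width to dominate that overhang.
With ~150 bp regions the same caller recovers the loci but the Jaccard
criterion would measure mostly fragment-length geometry, not caller
quality.

What the generator does **not** emulate: sequence-composition structure
of real promoters (GC elevation, CpG islands), batch effects between
replicates, fragment-length biases, chromatin accessibility confounds,
or multi-isoform gene structure.  Consequences worth noting: the GC
permutation test on synthetic peak regions is expected to be a null
result (the planted `A` buffers actually depress region GC slightly), so
the GC test's machinery is validated on explicitly planted GC-rich zones
instead; and passing recovery tests demonstrates correctness of the
computational stages, not performance on real data.

## Peak calling

The caller emulates the numeric-threshold ("stringent", no control
track) mode of block-AUC peak callers for sparse CUT&Tag signal:

1. maximal contiguous blocks of strictly positive signal are enumerated
   (touching runs merge; a zero gap splits);
2. each block is scored by total signal, AUC = Σ value × width, and its
   maximum run value is kept;
3. the top ⌈θ·B⌉ blocks by AUC are retained (θ default 0.01), where B is
   the total block count; blocks tied with the cutoff AUC are all kept.

Exact parity with any external caller is a non-goal; the stringent /
relaxed distinction of the original tool only exists in its
control-track mode, which is not implemented.  Consensus ("high
confidence") peaks are chained pairwise intersections across all
replicates — the reported regions are the maximal spans covered in every
replicate, which is symmetric in replicate order.  Peak signal classes
use linear-interpolation ("type 7") quartiles of total signal with
assignment order top (≥ Q3) before bottom (≤ Q1) before middle, so a
degenerate all-equal distribution is all-top.

Shared/unique comparisons between two peak sets report both anchored
counts (A intervals overlapping ≥ 1 B interval, and the converse)
because the two are not equal in general; percentages are rounded
half-up for reports.

## Motif scanning and enrichment

Patterns are the quadparser family `(B{m,}[ACGT]{0,L}){k−1}B{m,}` with
greedy tracts and loops; `N` matches nowhere.  Matching is leftmost,
greedy, non-overlapping per (class, strand); minus-strand search scans
the plus strand for the complementary-base pattern and reports
plus-strand coordinates.  The test suite pins the scanner to an
independent recursive backtracking matcher (no regex) with exact
coordinate equality on random sequences.

Enrichment counts matches on the sequences extracted from the regions
(region-level counting — regions containing ≥ 1 match — is available as
an option).  The null relocates each region independently: chromosome
drawn with probability proportional to length among those that fit,
start uniform; widths preserved; shuffled regions may overlap.  Fold =
observed / mean over n shuffles (default 10, per the standard protocol);
one shared shuffle set serves all classes for efficiency.  A zero null
with nonzero observed is flagged infinite rather than raising.  Region
GC enrichment uses the same shuffle as a permutation test,
p = (1 + #{null ≥ obs}) / (n + 1), one-sided, with the effect size
reported — no distributional assumption.

Numerical notes: matches straddling a region boundary are lost equally
in observed and null counts (both scan extracted sequences), so the null
calibration fold ≈ 1 on random regions holds despite edge effects.

## Coverage and QC

RPGC normalization scales raw per-base fragment coverage by
(genome length) / (summed fragment length), making the genome-wide mean
coverage exactly 1× (asserted to 1e-9); the factor uses fragment lengths,
not read counts, because the pipeline's unit is the fragment.  Tracks
are binned (default 5 bp) with the bin value equal to the mean per-base
coverage in the bin, so the 1× identity is preserved under binning.

* **FRiP** — exact: fraction of fragments overlapping ≥ 1 peak by ≥ 1 bp;
  sampled: fragment-coverage mass at uniformly sampled 1 bp positions
  inside peaks over mass at all sampled positions (default 10,000
  positions), a coverage-weighted estimate in the style of
  position-sampling tools.  The exact value is the default in reports.
  An empty peak set yields FRiP 0 by definition.
* **Pearson correlation** between replicate tracks is computed over all
  genome bins including zeros; the bin size is a mandatory explicit
  parameter (the analysis drivers use 500 bp, coarser than the 5 bp
  track bins, to measure co-localization rather than per-bin shot
  noise).  Zero variance raises instead of returning NaN.
* **Saturation curves** subsample each replicate without replacement at
  each depth fraction, rebuild the track, re-call peaks, and count the
  subsampled fragments in the newly called peaks, averaged over
  replicates.
* **Complexity curves** give the expected number of distinct fragments
  among n drawn without replacement, either exactly,
  E[distinct] = Σ_u (1 − C(N−c_u, n)/C(N, n)) over unique fragments u
  with copy count c_u (log-gamma arithmetic; exact up to float
  rounding), or empirically over ≥ 20 subsampling rounds; the two agree
  within Monte-Carlo error by test.  Duplicate identity is the exact
  (chrom, start, end, strand) tuple — no alignment metadata exists in
  this pipeline.

## Annotation and TSS profiles

Each peak is anchored at its midpoint and receives exactly one category
by priority Promoter > Exon > Intron > Downstream > Distal intergenic.
The category set is reduced (no UTR classes) because simple gene tables
carry no UTR structure; UTR bases fold into Exon.  The promoter window
is strand-aware and mandatory everywhere it is used (the commonly cited
annotator defaults to ±3 kb while this analysis family uses ±1 kb, so a
silent default would be a trap); the downstream window defaults to 3 kb
past the 3′ end.  Ties between genes are broken by smaller |distance to
TSS|, then lexicographic gene id.  Normalized feature distributions
divide the peak fraction per category by the category's genomic base
fraction — computed with the same priority order at base level — and
rescale the ratios to percentages.

TSS matrices average the track over fixed-width bins (default 25 bp)
across ±flank (default 1 kb) around each TSS; minus-strand rows are
flipped so columns always run upstream → downstream; bins clipped at
chromosome edges are missing and excluded from the column-mean profile.
Z-scoring is matrix-global (per-row scaling is not the default because
it erases between-gene amplitude); SD 0 maps to all zeros.

## Expression integration

Expressed means TPM > 0 ("at least one transcript").  Expressed genes
split at the interpolated Q1/Q3 of the expressed-TPM distribution: high
≥ Q3 (checked first), low ≤ Q1, else medium; TPM 0 is the separate "no"
category.  Structure labels (both / A-only / B-only / none) come from
peak presence within a fixed TSS window, 3 kb by default — deliberately
independent of the annotation promoter window.  Because the direction of
the percentage table is genuinely ambiguous (share of expression
categories within a structure group, or share of structure groups within
an expression category), both orientations are emitted.  TPM
distribution summaries exclude outliers by the two-sided 1.5×IQR rule;
the exclusion never affects category assignment.

## Pipeline and reproducibility

`pipeline.run_pipeline` runs simulate → tracks → peaks → consensus →
QC → motif enrichment → annotation → profiles → expression integration
from one validated config (unknown keys rejected; the promoter window
must be stated explicitly).  Every stage seed derives from the root seed
via stable CRC-tagged sub-streams and is recorded, with SHA256 digests
of every output, in a JSON manifest; re-running a config reproduces the
output tree byte-identically (tested).

`scripts/acceptance.py` re-runs the headline computation at the standard
study conditions — 2 Mb genome, 500 × 200 bp regions, a 10-fold
inside/outside planted density contrast (25 inside vs 48 outside per
class over a 5% region share), 10 shuffles — and reports the minimum
fold across all pattern classes.

## Known limitations

* The block-AUC caller approximates, not reproduces, the external tool's
  selection; control-track mode, summit refinement and broad/narrow
  distinctions are absent.
* The shuffle ignores gap/exclusion files (synthetic genomes have none)
  and does not preserve chromosome of origin by default (available as an
  option).
* One TSS per gene record; no isoform collapsing.
* Scanner counts non-overlapping matches per class; overlapping-match
  enumeration and imperfect (bulged) tracts are out of scope, as is any
  thermodynamic stability scoring.
* Sampled FRiP is coverage-weighted and therefore systematically close
  to, but not an unbiased estimator of, the exact fragment fraction.
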