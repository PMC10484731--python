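"""End-to-end pipeline: simulate -> tracks -> peaks -> consensus ->
motif enrichment -> annotation -> expression integration.

``run_pipeline`` takes one structured config (a dict, typically loaded
from YAML), runs the stages in dependency order, writes every declared
output under the configured directory, and returns a RunManifest holding
the config snapshot, every derived seed, per-stage parameters and a SHA256
digest of every file written.  Re-running with the same config reproduces
every output byte-identically.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from . import genefeatures, peakcall, quadmotif, synthgen, tracks
from .genomeio import Interval, write_bed, write_bedgraph
from .quadmotif import all_specs

logger = logging.getLogger("quadmap")

DEFAULT_CONFIG: dict[str, Any] = {
    "outdir": "quadmap_demo",
    "seed": 0,
    "simulate": {
        "chromosome_lengths": {"chr1": 1_000_000, "chr2": 1_000_000},
        "gc_fraction": 0.45,
        "n_peak_regions": 20,
        "peak_region_width": 1000,
        "fragments_per_replicate": 8000,
        "n_replicates": 3,
        "enrichment_ratio": 10.0,
        "motifs_inside_per_class": 10,
        "motifs_outside_per_class": 10,
        "n_genes": 200,
    },
    "tracks": {"bin_size": 5, "frip_positions": 10000},
    "peaks": {"seacr_threshold": 0.01},
    "motifs": {"n_shuffles": 10, "loop_lengths": [7, 12]},
    "annotation": {"promoter_window": [-1000, 1000], "downstream_window": 3000},
    "profile": {"flank": 1000, "tss_bin": 25},
    "expression": {"tss_window": 3000},
}

_REQUIRED_SECTIONS = set(DEFAULT_CONFIG) - {"outdir", "seed"}


@dataclass
class RunManifest:
    config: dict
    seeds: dict[str, int]
    parameters: dict[str, Any]
    outputs: dict[str, str] = field(default_factory=dict)  # path -> sha256

    def to_json(self) -> str:
        return json.dumps(
            {
                "config": self.config,
                "seeds": self.seeds,
                "parameters": self.parameters,
                "outputs": self.outputs,
            },
            indent=2,
            sort_keys=True,
            default=str,
        )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _stage_seed(root: int, stage: str) -> int:
    return int(
        np.random.SeedSequence(
            (root, zlib.crc32(stage.encode()) & 0x7FFFFFFF)
        ).generate_state(1)[0]
        % (2**31)
    )


def validate_config(config: Mapping[str, Any]) -> dict[str, Any]:
    """Merge over defaults; reject unknown sections/keys; require the
    promoter window to be stated explicitly."""
    unknown = set(config) - set(DEFAULT_CONFIG)
    if unknown:
        raise ValueError(f"unknown config section(s): {sorted(unknown)}")
    merged = json.loads(json.dumps(DEFAULT_CONFIG))
    if "annotation" not in config or "promoter_window" not in config.get(
        "annotation", {}
    ):
        raise ValueError(
            "config must state annotation.promoter_window explicitly"
        )
    for key, value in config.items():
        if key in _REQUIRED_SECTIONS:
            bad = set(value) - set(DEFAULT_CONFIG[key])
            if bad:
                raise ValueError(f"unknown key(s) in [{key}]: {sorted(bad)}")
            merged[key].update(value)
        else:
            merged[key] = value
    return merged


def load_pipeline_config(path: str | Path) -> dict[str, Any]:
    with open(path) as fh:
        return validate_config(yaml.safe_load(fh) or {})


def demo_config(outdir: str | Path, seed: int = 0) -> dict[str, Any]:
    cfg = json.loads(json.dumps(DEFAULT_CONFIG))
    cfg["outdir"] = str(outdir)
    cfg["seed"] = seed
    return cfg


def run_pipeline(config: Mapping[str, Any]) -> RunManifest:
    cfg = validate_config(config)
    outdir = Path(cfg["outdir"])
    outdir.mkdir(parents=True, exist_ok=True)
    root_seed = int(cfg["seed"])
    seeds = {
        stage: _stage_seed(root_seed, stage)
        for stage in ("simulate", "qc", "motifs", "shuffle_gc", "labels")
    }
    logging.basicConfig(stream=sys.stderr, level=logging.INFO, force=False)

    # --- stage: simulate -------------------------------------------------
    sim = cfg["simulate"]
    lengths = {k: int(v) for k, v in sim["chromosome_lengths"].items()}
    regions = synthgen.default_peak_regions(
        lengths, sim["n_peak_regions"], sim["peak_region_width"]
    )
    specs = all_specs(loops=tuple(cfg["motifs"]["loop_lengths"]))
    sim_config = synthgen.SimConfig(
        chromosome_lengths=lengths,
        gc_fraction=sim["gc_fraction"],
        peak_regions=regions,
        fragments_per_replicate=sim["fragments_per_replicate"],
        n_replicates=sim["n_replicates"],
        enrichment_ratio=sim["enrichment_ratio"],
        seed=seeds["simulate"],
    )
    genome = synthgen.simulate_genome(sim_config)
    plants = [
        (spec, regions, sim["motifs_inside_per_class"]) for spec in specs
    ] + [(spec, None, sim["motifs_outside_per_class"]) for spec in specs]
    genome, truth = synthgen.plant_motifs(genome, plants, seed=seeds["simulate"])
    replicates = synthgen.simulate_fragments(sim_config, genome)
    label_rng = np.random.default_rng(seeds["labels"])
    gene_labels = {
        f"gene{i:05d}": ["none", "iM", "G4", "both"][
            int(label_rng.integers(0, 4))
        ]
        for i in range(sim["n_genes"])
    }
    genes, tpm = synthgen.simulate_genes_and_expression(
        sim_config, genome, gene_labels
    )
    written = synthgen.write_outputs(
        outdir, genome, replicates, truth, genes, tpm
    )
    write_bed(list(regions), outdir / "planted_regions.bed")
    written["planted_regions"] = outdir / "planted_regions.bed"
    logger.info(
        "simulated %d bp genome, %d replicates x %d fragments, %d genes",
        genome.total_length,
        len(replicates),
        len(replicates[0]),
        len(genes),
    )

    # --- stage: tracks + peaks -------------------------------------------
    bin_size = cfg["tracks"]["bin_size"]
    threshold = cfg["peaks"]["seacr_threshold"]
    replicate_peaks = []
    for i, frags in enumerate(replicates):
        track = tracks.coverage_track(frags, genome, bin_size=bin_size)
        bg_path = outdir / f"coverage_rep{i}.bedgraph"
        write_bedgraph(track, bg_path)
        written[f"coverage_rep{i}"] = bg_path
        peaks = peakcall.call_peaks(track, threshold=threshold, sample_id=f"rep{i}")
        replicate_peaks.append(peaks)
        peak_df = pd.DataFrame(
            {
                "chrom": [p.chrom for p in peaks],
                "start": [p.start for p in peaks],
                "end": [p.end for p in peaks],
                "total_signal": [p.total_signal for p in peaks],
                "max_signal": [p.max_signal for p in peaks],
            }
        )
        p_path = outdir / f"peaks_rep{i}.tsv"
        peak_df.to_csv(p_path, sep="\t", index=False)
        written[f"peaks_rep{i}"] = p_path
    consensus = peakcall.consensus_peaks(replicate_peaks)
    cons_path = outdir / "consensus_peaks.bed"
    write_bed(consensus, cons_path)
    written["consensus_peaks"] = cons_path
    logger.info(
        "called %s peaks per replicate; %d consensus regions",
        [len(p) for p in replicate_peaks],
        len(consensus),
    )
    width_stats = peakcall.peak_width_stats(consensus) if consensus else {}
    quartiles = peakcall.classify_signal_quartiles(replicate_peaks[0])
    quart_df = pd.DataFrame(
        {
            "chrom": [p.chrom for p, _ in quartiles],
            "start": [p.start for p, _ in quartiles],
            "end": [p.end for p, _ in quartiles],
            "total_signal": [p.total_signal for p, _ in quartiles],
            "signal_class": [c.label for _, c in quartiles],
        }
    )
    quart_path = outdir / "signal_classes_rep0.tsv"
    quart_df.to_csv(quart_path, sep="\t", index=False)
    written["signal_classes"] = quart_path

    # --- stage: QC --------------------------------------------------------
    qc = tracks.qc_report(
        replicates,
        consensus,
        genome,
        bin_size=bin_size,
        frip_positions=cfg["tracks"]["frip_positions"],
        threshold=threshold,
        seed=seeds["qc"],
    )
    qc_path = outdir / "qc_report.json"
    qc_path.write_text(json.dumps(qc.to_dict(), indent=2))
    written["qc_report"] = qc_path
    logger.info("FRiP exact %.3f, sampled %.3f", qc.frip_exact, qc.frip_sampled)

    # --- stage: motif enrichment -----------------------------------------
    enrich = quadmotif.fold_enrichment(
        consensus, genome, specs,
        n=cfg["motifs"]["n_shuffles"], seed=seeds["motifs"],
    )
    enrich_df = pd.DataFrame(
        {
            "label": [r.spec.label for r in enrich],
            "observed": [r.observed for r in enrich],
            "mean_null": [r.mean_shuffled for r in enrich],
            "sd_null": [r.sd_shuffled for r in enrich],
            "fold": [r.fold for r in enrich],
            "infinite": [r.infinite for r in enrich],
        }
    )
    enrich_path = outdir / "motif_enrichment.tsv"
    enrich_df.to_csv(enrich_path, sep="\t", index=False)
    written["motif_enrichment"] = enrich_path
    gc_res = quadmotif.gc_enrichment(
        consensus, genome, n=100, seed=seeds["shuffle_gc"]
    )
    gc_path = outdir / "gc_enrichment.json"
    gc_path.write_text(json.dumps(gc_res, indent=2))
    written["gc_enrichment"] = gc_path

    # --- stage: annotation + profile -------------------------------------
    ann_cfg = cfg["annotation"]
    annotations = genefeatures.annotate_peaks(
        consensus,
        genes,
        promoter_window=tuple(ann_cfg["promoter_window"]),
        downstream_window=ann_cfg["downstream_window"],
    )
    ann_df = pd.DataFrame(
        {
            "chrom": [a.peak.chrom for a in annotations],
            "start": [a.peak.start for a in annotations],
            "end": [a.peak.end for a in annotations],
            "category": [a.category for a in annotations],
            "distance_to_tss": [a.distance_to_tss for a in annotations],
            "gene_id": [a.gene_id for a in annotations],
        }
    )
    ann_path = outdir / "annotations.tsv"
    ann_df.to_csv(ann_path, sep="\t", index=False)
    written["annotations"] = ann_path
    norm = (
        genefeatures.normalized_feature_distribution(
            annotations,
            genome,
            genes,
            promoter_window=tuple(ann_cfg["promoter_window"]),
            downstream_window=ann_cfg["downstream_window"],
        )
        if annotations
        else {}
    )
    track0 = tracks.coverage_track(replicates[0], genome, bin_size=bin_size)
    matrix, profile, gene_ids = genefeatures.tss_matrix(
        track0,
        genes,
        genome,
        flank=cfg["profile"]["flank"],
        bin_size=cfg["profile"]["tss_bin"],
    )
    prof_path = outdir / "tss_profile.tsv"
    pd.DataFrame({"bin": range(len(profile)), "mean_signal": profile}).to_csv(
        prof_path, sep="\t", index=False
    )
    written["tss_profile"] = prof_path

    # --- stage: expression integration ------------------------------------
    peaks_a = [
        Interval(m.chrom, m.start, m.end)
        for m in truth
        if m.spec.base == "C"
    ]
    peaks_b = [
        Interval(m.chrom, m.start, m.end)
        for m in truth
        if m.spec.base == "G"
    ]
    from . import expression as expr_mod

    integration = expr_mod.structure_by_expression(
        genes, peaks_a, peaks_b, tpm,
        tss_window=cfg["expression"]["tss_window"],
    )
    integ_path = outdir / "structure_by_expression.tsv"
    integration["by_structure"].to_csv(integ_path, sep="\t")
    written["structure_by_expression"] = integ_path

    summary = {
        "consensus_peak_count": len(consensus),
        "peak_width_stats": {
            k: v for k, v in width_stats.items() if k != "histogram"
        },
        "normalized_feature_distribution": norm,
        "gc_enrichment": gc_res,
        "min_fold": min((r.fold for r in enrich), default=None),
    }
    summary_path = outdir / "summary.json"
    summary_path.write_text(json.dumps(summary, indent=2, default=float))
    written["summary"] = summary_path

    manifest = RunManifest(
        config=cfg,
        seeds={"root": root_seed, **seeds},
        parameters={
            "bin_size": bin_size,
            "seacr_threshold": threshold,
            "n_shuffles": cfg["motifs"]["n_shuffles"],
            "frip_positions": cfg["tracks"]["frip_positions"],
            "promoter_window": ann_cfg["promoter_window"],
            "downstream_window": ann_cfg["downstream_window"],
            "tss_bin": cfg["profile"]["tss_bin"],
            "tss_window": cfg["expression"]["tss_window"],
            "motif_specs": [s.label for s in specs],
        },
        outputs={str(p): _sha256(Path(p)) for p in written.values()},
    )
    (outdir / "manifest.json").write_text(manifest.to_json())
    return manifest
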