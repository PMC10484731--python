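"""Integration of structure calls with gene expression.

Expressed genes (TPM > 0) are split by quartiles of the expressed-TPM
distribution: low <= Q1, high >= Q3 (checked first), medium otherwise;
TPM = 0 is its own "no expression" category.  Genes are labelled
{both, A-only, B-only, none} by the presence of a peak within a fixed
window of their TSS (default 3 kb), and the two-way table of structure
label by expression category is reported in both orientations.
"""

from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np
import pandas as pd

from .genomeio import GeneModel, Interval, intervals_to_pyranges
from .peakcall import shared_unique

__all__ = [
    "EXPRESSION_CATEGORIES",
    "expression_categories",
    "assign_structure_labels",
    "structure_by_expression",
    "external_overlap",
]

EXPRESSION_CATEGORIES = ("no", "low", "medium", "high")
STRUCTURE_LABELS = ("both", "A-only", "B-only", "none")


def expression_categories(tpm: pd.Series) -> tuple[pd.Series, tuple[float, float]]:
    """Per-gene category in {no, low, medium, high} plus the (Q1, Q3)
    cutoffs of the expressed-TPM distribution (linear interpolation)."""
    if len(tpm) == 0:
        raise ValueError("empty expression table")
    if (tpm < 0).any():
        raise ValueError("negative TPM")
    expressed = tpm[tpm > 0]
    if expressed.empty:
        return pd.Series("no", index=tpm.index, name="category"), (np.nan, np.nan)
    q1, q3 = np.quantile(expressed.to_numpy(), [0.25, 0.75])
    cats = pd.Series("medium", index=tpm.index, name="category")
    cats[tpm >= q3] = "high"  # checked first: all-equal => all high
    cats[tpm <= q1] = "low"
    cats[tpm == 0] = "no"
    # precedence: high before low; re-apply for all-equal expressed values
    cats[(tpm >= q3) & (tpm > 0)] = "high"
    return cats, (float(q1), float(q3))


def _genes_with_peak_near_tss(
    genes: Sequence[GeneModel], peaks: Sequence[Interval], window: int
) -> set[str]:
    if not peaks:
        return set()
    import pyranges as pr

    win_pr = pr.PyRanges(
        pd.DataFrame(
            {
                "Chromosome": [g.chrom for g in genes],
                "Start": [max(0, g.tss - window) for g in genes],
                "End": [g.tss + window + 1 for g in genes],
                "Name": [g.gene_id for g in genes],
            }
        )
    )
    hit = win_pr.overlap(intervals_to_pyranges(list(peaks)))
    if hit.empty:
        return set()
    return set(hit.df["Name"].astype(str))


def assign_structure_labels(
    genes: Sequence[GeneModel],
    peaks_a: Sequence[Interval],
    peaks_b: Sequence[Interval],
    tss_window: int = 3000,
) -> pd.Series:
    """Label each gene both / A-only / B-only / none by peak presence
    within ``tss_window`` bp of its TSS."""
    if tss_window <= 0:
        raise ValueError("tss_window must be positive")
    near_a = _genes_with_peak_near_tss(genes, peaks_a, tss_window)
    near_b = _genes_with_peak_near_tss(genes, peaks_b, tss_window)
    labels = {}
    for g in genes:
        a, b = g.gene_id in near_a, g.gene_id in near_b
        labels[g.gene_id] = "both" if a and b else "A-only" if a else (
            "B-only" if b else "none"
        )
    return pd.Series(labels, name="structure")


def _iqr_trim(values: np.ndarray) -> np.ndarray:
    """Two-sided 1.5 x IQR outlier exclusion (summaries only)."""
    if values.size == 0:
        return values
    q1, q3 = np.quantile(values, [0.25, 0.75])
    iqr = q3 - q1
    keep = (values >= q1 - 1.5 * iqr) & (values <= q3 + 1.5 * iqr)
    return values[keep]


def structure_by_expression(
    genes: Sequence[GeneModel],
    peaks_a: Sequence[Interval],
    peaks_b: Sequence[Interval],
    tpm: pd.Series,
    tss_window: int = 3000,
) -> dict:
    """Structure label x expression category tables plus per-label TPM
    summaries (median/quartiles after 1.5xIQR outlier exclusion; the
    exclusion never affects category assignment).

    Returns a dict with:
      by_structure — rows = structure labels, row percentages over
                     expression categories (each row sums to 100);
      by_category  — rows = expression categories, row percentages over
                     structure labels;
      tpm_summary  — per-label TPM median/q1/q3/n after outlier trimming;
      labels, categories, cutoffs.
    """
    labels = assign_structure_labels(genes, peaks_a, peaks_b, tss_window)
    missing = [g.gene_id for g in genes if g.gene_id not in tpm.index]
    if missing:
        warnings.warn(
            f"{len(missing)} gene(s) absent from expression table; "
            "treated as not expressed"
        )
    full_tpm = pd.Series(
        {g.gene_id: float(tpm.get(g.gene_id, 0.0)) for g in genes}, name="tpm"
    )
    cats, cutoffs = expression_categories(full_tpm)
    df = pd.DataFrame({"structure": labels, "category": cats, "tpm": full_tpm})

    counts = (
        df.groupby(["structure", "category"], observed=False)
        .size()
        .unstack(fill_value=0)
        .reindex(
            index=[l for l in STRUCTURE_LABELS if l in df["structure"].unique()],
            columns=list(EXPRESSION_CATEGORIES),
            fill_value=0,
        )
    )
    counts = counts.loc[counts.sum(axis=1) > 0]
    by_structure = counts.div(counts.sum(axis=1), axis=0) * 100
    cat_counts = counts.T.loc[lambda t: t.sum(axis=1) > 0]
    by_category = cat_counts.div(cat_counts.sum(axis=1), axis=0) * 100
    tpm_summary = {}
    for label, group in df.groupby("structure", observed=False):
        trimmed = _iqr_trim(group["tpm"].to_numpy())
        if trimmed.size:
            q1, med, q3 = np.quantile(trimmed, [0.25, 0.5, 0.75])
        else:
            q1 = med = q3 = np.nan
        tpm_summary[label] = {
            "median": float(med),
            "q1": float(q1),
            "q3": float(q3),
            "n": int(len(group)),
            "n_after_trim": int(trimmed.size),
        }
    return {
        "by_structure": by_structure,
        "by_category": by_category,
        "tpm_summary": tpm_summary,
        "labels": labels,
        "categories": cats,
        "cutoffs": cutoffs,
    }


def external_overlap(
    peaks: Sequence[Interval],
    external: Sequence[Interval],
    promoter_peaks: Sequence[Interval] | None = None,
) -> dict:
    """Overlap of a peak set with an external set (ATAC / R-loop style).

    Peak-anchored >= 1 bp overlap counting (shared_unique); optionally also
    restricted to a supplied promoter-annotated subset of the peaks.
    """
    base = shared_unique(list(peaks), list(external))
    result = {
        "shared": base["shared_a"],
        "fraction": base["shared_a"] / len(peaks) if peaks else 0.0,
    }
    if promoter_peaks is not None:
        sub = shared_unique(list(promoter_peaks), list(external))
        result["promoter_fraction"] = (
            sub["shared_a"] / len(promoter_peaks) if promoter_peaks else 0.0
        )
    return result
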