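"""Depth normalization, RPKM, unspliced-RNA counts, fold enrichment and
Poisson tail tests across strains.

The statistical model is deliberately simple, matching the scale of the
comparisons it supports: each wild-type count, scaled to the mutant's
sequencing depth, is treated as the rate of a Poisson variable, and the
p-value of a mutant count k is the upper tail P(X ≥ k) — the probability of
observing at least that many reads if the mutant were drawn from the
wild-type distribution.  No dispersion modeling is attempted; a
Benjamini–Hochberg adjusted column is available behind a flag for reuse.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import GeneModel
from .spliced_alignment import SplicedAlignment

DEFAULT_PSEUDOCOUNT = 0.5
DEFAULT_RPKM_CAP = 2300.0


def intronic_unspliced_counts(
    alignments: Iterable[SplicedAlignment],
    genes: Mapping[str, GeneModel],
) -> dict[str, int]:
    """Per-gene unspliced-RNA read counts.

    A read counts once for a gene when any of its aligned blocks overlaps one
    of the gene's introns by ≥ 1 nt (reads fully intronic or crossing an
    exon-intron boundary).  Gapped reads whose skipped interval exactly
    equals one of the gene's introns are spliced at that intron and do not
    count.  Returns a count for every intron-containing gene (0 included).
    """
    from intervaltree import IntervalTree

    trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
    intron_keys: dict[str, set[tuple[int, int]]] = {}
    for gene in genes.values():
        if not gene.is_icg:
            continue
        intron_keys[gene.gene_id] = set(gene.introns)
        for s, e in gene.introns:
            trees[gene.chrom_id].addi(s, e + 1, gene.gene_id)  # half-open tree

    counts = {g: 0 for g in intron_keys}
    for aln in alignments:
        tree = trees.get(aln.chrom_id)
        if tree is None:
            continue
        hit_genes: set[str] = set()
        for s, e in aln.blocks:
            for iv in tree.overlap(s, e + 1):
                hit_genes.add(iv.data)
        if not hit_genes:
            continue
        gap = aln.gap_interval
        for g in hit_genes:
            if gap is not None and gap in intron_keys[g]:
                continue
            counts[g] += 1
    return counts


def depth_normalize(
    counts: pd.DataFrame, totals: Mapping[str, int], reference: str | None = None
) -> pd.DataFrame:
    """Scale per-sample counts to a common sequencing depth.

    ``counts`` has one column per sample; each column is multiplied by
    ``totals[reference] / totals[sample]`` (reference defaults to the first
    column), which preserves within-sample count ratios exactly.
    """
    if reference is None:
        reference = counts.columns[0]
    for sample in counts.columns:
        if totals[sample] <= 0:
            raise ValueError(f"sample {sample!r} has non-positive total_mapped")
    return counts.astype(float).mul(
        {s: totals[reference] / totals[s] for s in counts.columns}
    )


def poisson_upper_p(lam: float, k: int) -> float:
    """Upper-tail Poisson probability P(X ≥ k) for X ~ Poisson(lam)."""
    if lam < 0 or k < 0:
        raise ValueError("lam and k must be non-negative")
    if k == 0:
        return 1.0
    return float(stats.poisson.sf(k - 1, lam))


def rpkm(count: float, feature_length_nt: int, total_mapped: int) -> float:
    """Reads per kilobase of feature per million mapped reads."""
    if feature_length_nt <= 0 or total_mapped <= 0:
        raise ValueError("feature length and total mapped reads must be positive")
    return count / ((feature_length_nt / 1000.0) * (total_mapped / 1e6))


@dataclass
class EnrichmentResult:
    """Depth-normalized mutant vs. wild-type comparison for one unit."""

    unit_id: str
    sample_id: str
    wt_norm: float
    mut_norm: float
    fold: float          # NaN when undefined (WT 0 with pseudocount off)
    pvalue: float


def enrichment_table(
    counts: pd.DataFrame,
    totals: Mapping[str, int],
    wt: str,
    pseudocount: float | None = DEFAULT_PSEUDOCOUNT,
    bh_adjust: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-unit and aggregate depth-adjusted enrichment vs. wild-type.

    ``counts`` holds raw counts (rows = units: genes, events or categories;
    columns = samples); ``totals`` the per-sample total mapped reads used for
    depth scaling (wild-type depth is the reference).  For each mutant sample
    and unit, fold = normalized mutant / normalized WT and the p-value is the
    Poisson upper tail with λ = the depth-scaled WT count (``pseudocount``
    replaces λ = 0 so folds and p-values stay defined; pass None to disable,
    in which case such folds are NaN).  The aggregate row sums raw counts
    over units before normalizing.

    Returns ``(per_unit, aggregate)`` frames.
    """
    if wt not in counts.columns:
        raise ValueError(f"wild-type sample {wt!r} not in counts")
    muts = [c for c in counts.columns if c != wt]
    norm = depth_normalize(counts, totals, reference=wt)

    def _rows(raw: pd.DataFrame, normed: pd.DataFrame) -> list[EnrichmentResult]:
        out = []
        for unit in raw.index:
            wt_n = float(normed.loc[unit, wt])
            for m in muts:
                mut_n = float(normed.loc[unit, m])
                lam = wt_n
                if lam == 0 and pseudocount is not None:
                    lam = pseudocount
                fold = mut_n / lam if lam > 0 else float("nan")
                # p-value: probability of the mutant's raw count under a
                # Poisson with the WT count scaled to the mutant's depth.
                lam_mut_scale = lam * totals[m] / totals[wt]
                p = poisson_upper_p(lam_mut_scale, int(round(raw.loc[unit, m])))
                out.append(
                    EnrichmentResult(str(unit), m, wt_n, mut_n, fold, p)
                )
        return out

    per_unit = pd.DataFrame([vars(r) for r in _rows(counts, norm)])
    agg_counts = counts.sum(axis=0).to_frame().T
    agg_counts.index = ["aggregate"]
    agg_norm = depth_normalize(agg_counts, totals, reference=wt)
    aggregate = pd.DataFrame([vars(r) for r in _rows(agg_counts, agg_norm)])
    if bh_adjust and not per_unit.empty:
        per_unit["pvalue_bh"] = _benjamini_hochberg(per_unit["pvalue"].to_numpy())
    return per_unit, aggregate


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    return stats.false_discovery_control(p, method="bh")


def event_count_matrix(
    junctions: Iterable,
    samples: Sequence[str],
    status: str | None = "alternative",
    ptc_only: bool = False,
    unique_events: bool = False,
) -> pd.DataFrame:
    """Counts per junction event (rows) × sample (columns).

    With ``unique_events`` each cell is 1 if the event has any support in the
    sample (the unit the published Venn-style comparisons count), otherwise
    the supporting-read count.  ``status`` filters by classification;
    ``ptc_only`` keeps PTC-generating events.
    """
    rows = {}
    for j in junctions:
        if status is not None and j.status != status:
            continue
        if ptc_only and not j.is_ptc:
            continue
        key = "{}:{}-{}({})".format(j.chrom_id, j.intron_start, j.intron_end, j.strand)
        rows[key] = {
            s: (1 if j.counts.get(s, 0) > 0 else 0)
            if unique_events
            else j.counts.get(s, 0)
            for s in samples
        }
    frame = pd.DataFrame.from_dict(rows, orient="index", columns=list(samples))
    if frame.empty:
        frame = pd.DataFrame(columns=list(samples), dtype=int)
    return frame.fillna(0).astype(int)


def abundance_stratification(
    rpkm_values: Mapping[str, float],
    has_alt_event: Mapping[str, bool],
    bin_width: float = 100.0,
    cap: float = DEFAULT_RPKM_CAP,
) -> dict:
    """Histogram of ICG abundance for genes with vs. without alternative
    splicing, with a terminal catch-all bin at ``cap`` RPKM, plus group
    medians (None for an empty group)."""
    edges = np.arange(0.0, cap + bin_width, bin_width)
    edges = np.append(edges, np.inf)
    groups = {}
    for label, flag in (("alt", True), ("no_alt", False)):
        vals = np.array(
            [v for g, v in rpkm_values.items() if has_alt_event.get(g, False) == flag]
        )
        hist, _ = np.histogram(vals, bins=edges) if len(vals) else (
            np.zeros(len(edges) - 1, dtype=int),
            edges,
        )
        groups[label] = {
            "n": int(len(vals)),
            "median": float(np.median(vals)) if len(vals) else None,
            "histogram": hist.tolist(),
        }
    return {"bin_edges": edges[:-1].tolist(), "cap": cap, "groups": groups}
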