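"""Collapse gapped alignments into junctions and classify them within genes.

A *junction* is one distinct skipped genomic interval (the observed intron).
Junctions that exactly match an annotated intron are *annotated*; junctions
contained in an intron-containing gene (ICG) but not matching any annotated
intron are *alternative* splicing events; everything else is *outside_icg*
and excluded from event statistics.  Because the sequencing protocol is
unstranded, an unannotated junction inherits the strand of its containing
gene.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from itertools import combinations
from typing import Hashable, Iterable, Mapping, Sequence

from .io_formats import GeneModel, GenomeModel, Interval, revcomp
from .spliced_alignment import SplicedAlignment

DONOR_LEN = 6       # covers the GTATGT consensus
ACCEPTOR_LEN = 8    # terminal YAG plus polypyrimidine context

STATUS_ANNOTATED = "annotated"
STATUS_ALTERNATIVE = "alternative"
STATUS_OUTSIDE = "outside_icg"


@dataclass
class JunctionEvent:
    """One observed splice junction with per-sample read support.

    ``intron_start``/``intron_end`` are the 1-based inclusive first and last
    intronic bases.  ``donor_seq`` is the first 6 intronic nt and
    ``acceptor_window`` the last 8 intronic nt, both in transcript
    orientation.  ``ambiguous_counts`` tracks support from flagged
    multi-mapping reads (kept, but counted separately for auditability).
    """

    chrom_id: str
    strand: str
    intron_start: int
    intron_end: int
    gene_id: str | None = None
    status: str = STATUS_OUTSIDE
    donor_seq: str | None = None
    acceptor_window: str | None = None
    counts: dict[str, int] = field(default_factory=dict)
    ambiguous_counts: dict[str, int] = field(default_factory=dict)
    norm_counts: dict[str, float] = field(default_factory=dict)
    is_ptc: bool | None = None
    truncated_sites: bool = False
    extra_gene_ids: list[str] = field(default_factory=list)

    @property
    def key(self) -> tuple[str, str, int, int]:
        return (self.chrom_id, self.strand, self.intron_start, self.intron_end)

    @property
    def intron_length(self) -> int:
        return self.intron_end - self.intron_start + 1

    @property
    def total_count(self) -> int:
        return sum(self.counts.values())


def extract_junctions(
    alignments_by_sample: Mapping[str, Iterable[SplicedAlignment]],
    min_support: int = 1,
) -> list[JunctionEvent]:
    """Collapse gapped alignments into one event per distinct skipped interval.

    Counts are summed per sample; alignments flagged as multi-mapping
    (``n_best_locations > 1``) are additionally tallied in
    ``ambiguous_counts``.  Events with total support < ``min_support`` are
    dropped.  Junction strand is unknown at this stage (unstranded protocol)
    and recorded as '+' until :func:`classify_events` assigns a gene.
    """
    counts: dict[tuple[str, int, int], dict[str, int]] = defaultdict(dict)
    ambiguous: dict[tuple[str, int, int], dict[str, int]] = defaultdict(dict)
    for sample, alignments in alignments_by_sample.items():
        for aln in alignments:
            if not aln.has_gap:
                continue
            gs, ge = aln.gap_interval
            k = (aln.chrom_id, gs, ge)
            counts[k][sample] = counts[k].get(sample, 0) + 1
            if aln.n_best_locations > 1:
                ambiguous[k][sample] = ambiguous[k].get(sample, 0) + 1
    out = []
    for (chrom, gs, ge), per_sample in sorted(counts.items()):
        if sum(per_sample.values()) < min_support:
            continue
        out.append(
            JunctionEvent(
                chrom_id=chrom,
                strand="+",
                intron_start=gs,
                intron_end=ge,
                counts=dict(per_sample),
                ambiguous_counts=dict(ambiguous.get((chrom, gs, ge), {})),
            )
        )
    return out


def classify_events(
    junctions: Iterable[JunctionEvent],
    genes: Mapping[str, GeneModel],
    genome: Mapping[str, GenomeModel] | None = None,
) -> list[JunctionEvent]:
    """Assign junctions to genes and label annotated/alternative/outside_icg.

    A junction is assigned to a gene when its intron interval lies fully
    within the gene's transcript span; it is *annotated* iff it exactly
    matches one of the gene's introns.  A junction contained in several genes
    is assigned to the first (by gene id) and the others are recorded in
    ``extra_gene_ids`` rather than silently dropped.  When a genome is given,
    donor/acceptor site sequences are filled in.  Input order does not matter
    and re-classification is idempotent.
    """
    annotated: dict[tuple[str, int, int], str] = {}
    for gene in genes.values():
        for iv in gene.introns:
            annotated[(gene.chrom_id, *iv)] = gene.gene_id
    by_chrom: dict[str, list[GeneModel]] = defaultdict(list)
    for gene in genes.values():
        by_chrom[gene.chrom_id].append(gene)
    for lst in by_chrom.values():
        lst.sort(key=lambda g: g.gene_id)

    out = []
    for j in sorted(junctions, key=lambda j: j.key):
        hit = annotated.get((j.chrom_id, j.intron_start, j.intron_end))
        if hit is not None:
            gene = genes[hit]
            j.gene_id, j.status, j.strand = hit, STATUS_ANNOTATED, gene.strand
        else:
            containing = [
                g
                for g in by_chrom.get(j.chrom_id, [])
                if g.is_icg
                and g.span[0] <= j.intron_start
                and j.intron_end <= g.span[1]
            ]
            if containing:
                gene = containing[0]
                j.gene_id = gene.gene_id
                j.status = STATUS_ALTERNATIVE
                j.strand = gene.strand
                j.extra_gene_ids = [g.gene_id for g in containing[1:]]
            else:
                j.gene_id, j.status = None, STATUS_OUTSIDE
        if genome is not None and j.status != STATUS_OUTSIDE:
            j.donor_seq, j.acceptor_window, j.truncated_sites = site_sequences(
                j, genome
            )
        out.append(j)
    return out


def site_sequences(
    junction: JunctionEvent,
    genome: Mapping[str, GenomeModel],
    donor_len: int = DONOR_LEN,
    acceptor_len: int = ACCEPTOR_LEN,
) -> tuple[str, str, bool]:
    """Donor and acceptor-window sequences in transcript orientation.

    The donor is the first ``donor_len`` intronic nt and the acceptor window
    the last ``acceptor_len`` intronic nt, read 5'→3' on the transcript
    (reverse-complemented for minus-strand junctions).  Introns shorter than
    ``donor_len + acceptor_len`` yield truncated, flagged windows.
    """
    chrom = genome[junction.chrom_id]
    s, e = junction.intron_start, junction.intron_end
    n = e - s + 1
    truncated = n < donor_len + acceptor_len
    d = min(donor_len, n)
    a = min(acceptor_len, n)
    if junction.strand == "+":
        donor = chrom.fetch(s, s + d - 1)
        acceptor = chrom.fetch(e - a + 1, e)
    else:
        donor = revcomp(chrom.fetch(e - d + 1, e))
        acceptor = revcomp(chrom.fetch(s, s + a - 1))
    return donor, acceptor, truncated


def strain_overlap(
    event_sets: Mapping[str, Iterable[Hashable]],
) -> dict[frozenset[str], int]:
    """Venn-region counts for k strains' event sets.

    Returns, for every non-empty subset R of strains, the number of events
    present in exactly the strains of R (the 2^k − 1 membership regions).
    """
    membership: dict[Hashable, set[str]] = defaultdict(set)
    for strain, events in event_sets.items():
        for ev in events:
            membership[ev].add(strain)
    regions: dict[frozenset[str], int] = {}
    strains = list(event_sets)
    for r in range(1, len(strains) + 1):
        for combo in combinations(strains, r):
            regions[frozenset(combo)] = 0
    for members in membership.values():
        regions[frozenset(members)] += 1
    return regions
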