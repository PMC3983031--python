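"""Splice-product construction and premature-termination-codon classification.

For each alternative junction the product mRNA is rebuilt by applying the
novel excision to the otherwise-canonical transcript: the single annotated
intron the event overlaps is replaced by the event's excised interval while
all other introns are spliced canonically.  The product is then translated
from the annotated start codon; a stop strictly upstream of the canonical
stop's mapped position is a PTC, and a CDS length change that is not a
multiple of 3 is a frameshift.  PTC products are NMD candidates unless an
optional faux-3'-UTR threshold declares their 3' UTR too short to trigger
decay.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

from Bio.Seq import Seq

from .io_formats import (
    GeneModel,
    GenomeModel,
    Interval,
    extract_spliced,
    genomic_to_transcript,
    transcript_to_genomic,
)
from .junction_discovery import JunctionEvent

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})


class UnsupportedEventError(ValueError):
    """The event cannot be interpreted against a single annotated intron."""


@dataclass
class SpliceProduct:
    """The mRNA produced by applying one junction to the canonical transcript."""

    gene_id: str
    event_key: tuple
    mrna_seq: str
    blocks: list[Interval]            # kept genomic intervals, ascending
    delta: int                        # product length − canonical length
    cds_start: int | None = None      # product transcript coords
    canonical_stop_pos: int | None = None  # canonical stop start, product coords
    first_stop_tx_pos: int | None = None   # first in-frame stop start
    is_ptc: bool = False
    is_frameshift: bool = False
    utr3_len: int | None = None
    nmd_candidate: bool = False
    start_lost: bool = False
    nonstop: bool = False
    protein_delta: str | None = None


def _overlaps(a: Interval, b: Interval) -> bool:
    return a[0] <= b[1] and b[0] <= a[1]


def _subtract(span: Interval, removed: list[Interval]) -> list[Interval]:
    """Kept sub-intervals of ``span`` after excising ``removed`` (sorted)."""
    kept = []
    pos = span[0]
    for s, e in sorted(removed):
        if s > pos:
            kept.append((pos, s - 1))
        pos = max(pos, e + 1)
    if pos <= span[1]:
        kept.append((pos, span[1]))
    return kept


def build_splice_product(
    gene: GeneModel,
    event: JunctionEvent,
    genome: Mapping[str, GenomeModel],
) -> SpliceProduct:
    """Rebuild the product mRNA with ``event``'s excision replacing the single
    annotated intron it overlaps; all other introns are spliced canonically.

    Raises :class:`UnsupportedEventError` when the event interval overlaps
    zero or more than one annotated intron: such events cannot be phrased as
    one junction in the otherwise-canonical transcript.
    """
    ev = (event.intron_start, event.intron_end)
    overlapped = [iv for iv in gene.introns if _overlaps(iv, ev)]
    if len(overlapped) != 1:
        raise UnsupportedEventError(
            f"{gene.gene_id}: event {ev} overlaps {len(overlapped)} annotated "
            "introns; exactly one is required"
        )
    other_introns = [iv for iv in gene.introns if iv != overlapped[0]]
    for iv in other_introns:
        if _overlaps(iv, ev):  # pragma: no cover - excluded by len check above
            raise UnsupportedEventError("event spans multiple introns")
    span = gene.span
    if not (span[0] <= ev[0] and ev[1] <= span[1]):
        raise UnsupportedEventError(
            f"{gene.gene_id}: event {ev} extends outside the transcript span"
        )
    removed = sorted(other_introns + [ev])
    for (s1, e1), (s2, e2) in zip(removed, removed[1:]):
        if s2 <= e1:
            raise UnsupportedEventError(
                f"{gene.gene_id}: event {ev} collides with another intron"
            )
    blocks = _subtract(span, removed)
    mrna = extract_spliced(genome[gene.chrom_id], blocks, gene.strand)
    delta = len(mrna) - gene.transcript_length
    return SpliceProduct(
        gene_id=gene.gene_id,
        event_key=event.key,
        mrna_seq=mrna,
        blocks=blocks,
        delta=delta,
    )


def _map_to_product(gpos: int, product: SpliceProduct, strand: str) -> int | None:
    """Product transcript coordinate of a genomic position, None if excised."""
    try:
        return genomic_to_transcript(gpos, product.blocks, strand)
    except ValueError:
        return None


def call_ptc(
    product: SpliceProduct,
    gene: GeneModel,
    utr3_threshold: int = 0,
) -> SpliceProduct:
    """Annotate ``product`` with PTC / frameshift / 3'-UTR / NMD-candidate calls.

    Translation starts at the canonical start codon's position mapped onto the
    product.  ``is_ptc`` is true iff the first in-frame stop lies strictly
    upstream of the canonical stop's mapped position; ``is_frameshift`` iff
    the excision length change is not a multiple of 3.  A PTC product is an
    NMD candidate iff its 3' UTR is longer than ``utr3_threshold`` nt (the
    default 0 makes every PTC a candidate; a positive value enables the
    faux-3'-UTR interpretation under which short 3' UTRs escape decay).
    """
    if gene.cds_start is None:
        raise ValueError(f"{gene.gene_id}: no CDS defined; excluded from PTC analysis")
    product.is_frameshift = bool(product.delta % 3)

    g_start = transcript_to_genomic(gene.cds_start, gene.exons, gene.strand)
    g_canon_stop = transcript_to_genomic(gene.cds_stop - 2, gene.exons, gene.strand)
    cds_start = _map_to_product(g_start, product, gene.strand)
    if cds_start is None:
        product.start_lost = True
        return product
    product.cds_start = cds_start
    canon_stop = _map_to_product(g_canon_stop, product, gene.strand)
    product.canonical_stop_pos = canon_stop

    mrna = product.mrna_seq
    stop_pos = None
    for i in range(cds_start - 1, len(mrna) - 2, 3):
        if mrna[i : i + 3] in STOP_CODONS:
            stop_pos = i + 1
            break
    if stop_pos is None:
        product.nonstop = True
        product.is_ptc = False
        return product
    product.first_stop_tx_pos = stop_pos
    product.utr3_len = len(mrna) - (stop_pos + 2)
    if canon_stop is None:
        # The canonical stop codon itself was excised; any stop found is
        # necessarily premature relative to the canonical protein end.
        product.is_ptc = True
    else:
        product.is_ptc = stop_pos < canon_stop
    product.nmd_candidate = product.is_ptc and product.utr3_len > utr3_threshold
    return product


def _translate_cds(mrna: str, cds_start: int) -> str:
    """Amino acids from ``cds_start`` (1-based) to the first stop, exclusive."""
    end = len(mrna) - (len(mrna) - cds_start + 1) % 3
    aa = str(Seq(mrna[cds_start - 1 : end]).translate())
    stop = aa.find("*")
    return aa if stop < 0 else aa[:stop]


def protein_consequence(
    product: SpliceProduct,
    gene: GeneModel,
    genome: Mapping[str, GenomeModel],
) -> str:
    """Human-readable protein change: substitution, Δn deletion, insertion,
    truncation, or "no change".

    The canonical and product proteins are compared by their longest common
    prefix and suffix; the differing stretch is reported with its flanking
    canonical positions, e.g. ``p.2-4 VCT>QTSVDST``.
    """
    if product.start_lost:
        product.protein_delta = "start_lost"
        return product.protein_delta
    canonical = _translate_cds(gene.spliced_sequence(genome), gene.cds_start)
    alt = _translate_cds(product.mrna_seq, product.cds_start)
    if alt == canonical:
        product.protein_delta = "no change"
        return product.protein_delta
    pre = 0
    while pre < min(len(canonical), len(alt)) and canonical[pre] == alt[pre]:
        pre += 1
    suf = 0
    while (
        suf < min(len(canonical), len(alt)) - pre
        and canonical[len(canonical) - 1 - suf] == alt[len(alt) - 1 - suf]
    ):
        suf += 1
    lost = canonical[pre : len(canonical) - suf]
    gained = alt[pre : len(alt) - suf]
    if product.is_ptc or product.nonstop or suf == 0 and len(alt) < len(canonical):
        product.protein_delta = (
            f"truncation at aa {pre + len(gained) + 1}/{len(canonical)}"
            + (f" after {gained}" if gained else "")
        )
    elif not gained:
        product.protein_delta = f"p.{pre + 1}-{pre + len(lost)} Δ{len(lost)}"
    elif not lost:
        product.protein_delta = f"p.{pre}^{pre + 1} ins{gained}"
    else:
        product.protein_delta = f"p.{pre + 1}-{pre + len(lost)} {lost}>{gained}"
    return product.protein_delta
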