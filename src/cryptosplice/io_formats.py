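"""Readers/writers for the standard formats the pipeline touches, and the
canonical in-memory coordinate model.

Coordinate conventions
----------------------
All genomic intervals are 1-based and inclusive (GFF3 convention) everywhere
inside the package.  BED output is the single 0-based, half-open surface, and
the conversion happens only at the BED boundary.

A gene's *transcript* coordinate system is 1-based along its spliced mRNA in
transcript orientation: for minus-strand genes transcript position 1 sits at
the highest genomic coordinate of the last exon.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import pandas as pd
from Bio import SeqIO

log = logging.getLogger(__name__)

_VALID_BASES = frozenset("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

Interval = tuple[int, int]


class FormatError(ValueError):
    """A file violated the format contract (duplicate ids, bad alphabet, ...)."""


class AnnotationWarning(UserWarning):
    """Non-fatal annotation problem; the offending gene is degraded, not dropped."""


def revcomp(seq: str) -> str:
    """Reverse-complement of an upper-case {A,C,G,T,N} string."""
    return seq.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GenomeModel:
    """One named chromosome: the reference for alignment, splicing and motifs."""

    chrom_id: str
    sequence: str

    def __post_init__(self) -> None:
        bad = set(self.sequence) - _VALID_BASES
        if bad:
            raise FormatError(
                f"chromosome {self.chrom_id!r} contains invalid base(s) "
                f"{sorted(bad)}; only A,C,G,T,N are allowed"
            )

    @property
    def length(self) -> int:
        return len(self.sequence)

    def fetch(self, start: int, end: int) -> str:
        """Sequence of the 1-based inclusive interval [start, end]."""
        if start < 1 or end > self.length or start > end:
            raise ValueError(
                f"interval [{start}, {end}] out of bounds for "
                f"{self.chrom_id} (length {self.length})"
            )
        return self.sequence[start - 1 : end]


@dataclass
class GeneModel:
    """One intron-containing (or intronless) gene on a strand.

    ``exons`` are genomic intervals sorted ascending on the genome regardless
    of strand; ``cds_start``/``cds_stop`` are 1-based transcript coordinates
    on the spliced canonical mRNA (``cds_stop`` is the last base of the stop
    codon).  ``cds_start is None`` marks a gene excluded from PTC analysis.
    """

    gene_id: str
    chrom_id: str
    strand: str
    exons: list[Interval]
    cds_start: int | None = None
    cds_stop: int | None = None

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"{self.gene_id}: strand must be '+' or '-'")
        if not self.exons:
            raise ValueError(f"{self.gene_id}: at least one exon required")
        self.exons = sorted(tuple(e) for e in self.exons)
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            if s2 <= e1 + 1:  # abutting exons would imply a zero-length intron
                raise FormatError(
                    f"{self.gene_id}: overlapping or abutting exons "
                    f"[{s1},{e1}] and [{s2},{e2}]"
                )
        for s, e in self.exons:
            if s > e:
                raise ValueError(f"{self.gene_id}: empty exon [{s},{e}]")
        if self.cds_start is not None:
            n = self.transcript_length
            if not (1 <= self.cds_start < self.cds_stop <= n):
                raise ValueError(f"{self.gene_id}: CDS outside transcript")
            if (self.cds_stop - self.cds_start + 1) % 3:
                raise ValueError(f"{self.gene_id}: CDS length not divisible by 3")

    # -- structure -----------------------------------------------------------

    @property
    def introns(self) -> list[Interval]:
        """Gaps between consecutive exons, genomic ascending, 1-based inclusive."""
        return [
            (e1 + 1, s2 - 1) for (_, e1), (s2, _) in zip(self.exons, self.exons[1:])
        ]

    @property
    def is_icg(self) -> bool:
        return len(self.exons) > 1

    @property
    def span(self) -> Interval:
        return (self.exons[0][0], self.exons[-1][1])

    @property
    def transcript_length(self) -> int:
        return sum(e - s + 1 for s, e in self.exons)

    # -- coordinate mapping ---------------------------------------------------

    def genomic_to_transcript(self, gpos: int) -> int:
        return genomic_to_transcript(gpos, self.exons, self.strand)

    def transcript_to_genomic(self, tpos: int) -> int:
        return transcript_to_genomic(tpos, self.exons, self.strand)

    def spliced_sequence(self, genome: Mapping[str, GenomeModel]) -> str:
        """Canonical mRNA sequence in transcript orientation."""
        return extract_spliced(genome[self.chrom_id], self.exons, self.strand)


# ---------------------------------------------------------------------------
# Coordinate helpers (shared by the simulator, the PTC builder and the CLI)
# ---------------------------------------------------------------------------

def genomic_to_transcript(gpos: int, blocks: Sequence[Interval], strand: str) -> int:
    """Map a genomic position inside ``blocks`` to 1-based transcript coords."""
    offset = 0
    for s, e in blocks:
        if s <= gpos <= e:
            plus_pos = offset + (gpos - s) + 1
            total = sum(b - a + 1 for a, b in blocks)
            return plus_pos if strand == "+" else total - plus_pos + 1
        offset += e - s + 1
    raise ValueError(f"genomic position {gpos} not covered by blocks {blocks}")


def transcript_to_genomic(tpos: int, blocks: Sequence[Interval], strand: str) -> int:
    total = sum(b - a + 1 for a, b in blocks)
    if not 1 <= tpos <= total:
        raise ValueError(f"transcript position {tpos} outside [1, {total}]")
    plus_pos = tpos if strand == "+" else total - tpos + 1
    offset = 0
    for s, e in blocks:
        n = e - s + 1
        if plus_pos <= offset + n:
            return s + (plus_pos - offset) - 1
        offset += n
    raise AssertionError("unreachable")


def extract_spliced(chrom: GenomeModel, blocks: Sequence[Interval], strand: str) -> str:
    """Concatenated block sequence, reverse-complemented for minus strand."""
    seq = "".join(chrom.fetch(s, e) for s, e in blocks)
    return seq if strand == "+" else revcomp(seq)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def load_genome(path: str | Path) -> dict[str, GenomeModel]:
    """Load a genome FASTA into ``{chrom_id: GenomeModel}``.

    Lowercase input is uppercased; IUPAC ambiguity codes other than N are
    rejected with the offending character named.
    """
    genome: dict[str, GenomeModel] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in genome:
            raise FormatError(f"duplicate chromosome id {rec.id!r}")
        genome[rec.id] = GenomeModel(rec.id, str(rec.seq).upper())
    if not genome:
        raise FormatError(f"no FASTA records found in {path}")
    return genome


def write_genome(genome: Mapping[str, GenomeModel], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for chrom in genome.values():
            fh.write(f">{chrom.chrom_id}\n")
            for i in range(0, chrom.length, width):
                fh.write(chrom.sequence[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------

def load_annotation(path: str | Path) -> dict[str, GeneModel]:
    """Load gene models from GFF3 (gene/mRNA/exon/CDS features).

    Introns are derived from the gaps between consecutive exons.  Only the
    first (alphabetically) transcript of a gene is used.  Genes whose CDS
    length is not divisible by 3 are kept but flagged out of PTC analysis
    (``cds_start is None``) with a warning.
    """
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    genes: dict[str, GeneModel] = {}
    for g in db.features_of_type("gene"):
        gene_id = g.id
        transcripts = sorted(db.children(g, featuretype="mRNA"), key=lambda t: t.id)
        scope = transcripts[0] if transcripts else g
        exons = sorted((f.start, f.end) for f in db.children(scope, featuretype="exon"))
        if not exons:
            exons = [(g.start, g.end)]
        cds = sorted((f.start, f.end) for f in db.children(scope, featuretype="CDS"))
        model = GeneModel(gene_id, g.seqid, g.strand, exons)
        if cds:
            cds_len = sum(e - s + 1 for s, e in cds)
            if cds_len % 3:
                warnings.warn(
                    f"gene {gene_id}: CDS length {cds_len} not divisible by 3; "
                    "excluded from PTC analysis",
                    AnnotationWarning,
                    stacklevel=2,
                )
            else:
                five = cds[0][0] if g.strand == "+" else cds[-1][1]
                three = cds[-1][1] if g.strand == "+" else cds[0][0]
                model.cds_start = model.genomic_to_transcript(five)
                model.cds_stop = model.genomic_to_transcript(three)
        if gene_id in genes:
            raise FormatError(f"duplicate gene id {gene_id!r}")
        genes[gene_id] = model
    if not genes:
        raise FormatError(f"no gene features found in {path}")
    return genes


def _cds_genomic_intervals(gene: GeneModel) -> list[Interval]:
    """Genomic intervals of the CDS, split across exons, ascending."""
    if gene.cds_start is None:
        return []
    g1 = gene.transcript_to_genomic(gene.cds_start)
    g2 = gene.transcript_to_genomic(gene.cds_stop)
    lo, hi = min(g1, g2), max(g1, g2)
    out = [(max(s, lo), min(e, hi)) for s, e in gene.exons]
    return [(s, e) for s, e in out if s <= e]


def write_annotation(genes: Mapping[str, GeneModel], path: str | Path) -> None:
    """Write gene models as GFF3 (gene → mRNA → exon/CDS)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for gene in genes.values():
            s, e = gene.span
            base = (gene.chrom_id, "cryptosplice")
            fh.write(
                "\t".join(map(str, (*base, "gene", s, e, ".", gene.strand, ".",
                                    f"ID={gene.gene_id}"))) + "\n"
            )
            mrna = f"{gene.gene_id}.t1"
            fh.write(
                "\t".join(map(str, (*base, "mRNA", s, e, ".", gene.strand, ".",
                                    f"ID={mrna};Parent={gene.gene_id}"))) + "\n"
            )
            for i, (xs, xe) in enumerate(gene.exons, 1):
                fh.write(
                    "\t".join(map(str, (*base, "exon", xs, xe, ".", gene.strand, ".",
                                        f"ID={mrna}.exon{i};Parent={mrna}"))) + "\n"
                )
            for i, (cs, ce) in enumerate(_cds_genomic_intervals(gene), 1):
                fh.write(
                    "\t".join(map(str, (*base, "CDS", cs, ce, ".", gene.strand, "0",
                                        f"ID={mrna}.cds{i};Parent={mrna}"))) + "\n"
                )


# ---------------------------------------------------------------------------
# SAM
# ---------------------------------------------------------------------------

def read_alignments(path: str | Path) -> Iterator["SplicedAlignment"]:
    """Stream a SAM file as :class:`SplicedAlignment` records.

    N CIGAR operators become inter-block gaps, soft clips are excluded from
    the blocks, and records with I/D operators are rejected (the mapping
    policy allows mismatches and one long gap, not indels).  Unmapped and
    malformed records are skipped with a logged counter.
    """
    import pysam

    from .spliced_alignment import SplicedAlignment

    skipped = {"unmapped": 0, "indel": 0, "malformed": 0}
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for rec in sam:
            if rec.is_unmapped:
                skipped["unmapped"] += 1
                continue
            try:
                ops = {op for op, _ in rec.cigartuples}
            except TypeError:
                skipped["malformed"] += 1
                log.warning("record %s has no CIGAR; skipped", rec.query_name)
                continue
            if ops & {1, 2}:  # I, D
                skipped["indel"] += 1
                log.warning("record %s contains indels; skipped", rec.query_name)
                continue
            if not ops <= {0, 3, 4, 7, 8}:  # M, N, S, =, X
                skipped["malformed"] += 1
                log.warning("record %s has unsupported CIGAR; skipped", rec.query_name)
                continue
            blocks: list[Interval] = []
            read_blocks: list[Interval] = []
            gpos = rec.reference_start + 1  # to 1-based
            rpos = 1
            for op, ln in rec.cigartuples:
                if op == 4:  # S
                    rpos += ln
                elif op == 3:  # N
                    gpos += ln
                else:  # M/=/X
                    if blocks and blocks[-1][1] == gpos - 1:
                        blocks[-1] = (blocks[-1][0], gpos + ln - 1)
                        read_blocks[-1] = (read_blocks[-1][0], rpos + ln - 1)
                    else:
                        blocks.append((gpos, gpos + ln - 1))
                        read_blocks.append((rpos, rpos + ln - 1))
                    gpos += ln
                    rpos += ln
            yield SplicedAlignment(
                read_id=rec.query_name,
                chrom_id=rec.reference_name,
                strand="-" if rec.is_reverse else "+",
                blocks=blocks,
                read_blocks=read_blocks,
                mismatches=int(rec.get_tag("NM")) if rec.has_tag("NM") else 0,
                n_best_locations=int(rec.get_tag("NH")) if rec.has_tag("NH") else 1,
                step="gapped" if len(blocks) > 1 else "ungapped",
            )
    if any(skipped.values()):
        log.info("read_alignments skipped records: %s", skipped)


def write_alignments(
    alignments: Iterable["SplicedAlignment"],
    path: str | Path,
    genome: Mapping[str, GenomeModel],
) -> None:
    """Write alignments as SAM with NM (mismatches) and NH (locations) tags."""
    import pysam

    header = {
        "HD": {"VN": "1.6", "SO": "unknown"},
        "SQ": [{"SN": c.chrom_id, "LN": c.length} for c in genome.values()],
    }
    ref_ids = {c.chrom_id: i for i, c in enumerate(genome.values())}
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for aln in alignments:
            rec = pysam.AlignedSegment(out.header)
            rec.query_name = aln.read_id
            rec.flag = 16 if aln.strand == "-" else 0
            rec.reference_id = ref_ids[aln.chrom_id]
            rec.reference_start = aln.blocks[0][0] - 1
            cigar = []
            prev_end = None
            for (gs, ge) in aln.blocks:
                if prev_end is not None:
                    cigar.append((3, gs - prev_end - 1))
                cigar.append((0, ge - gs + 1))
                prev_end = ge
            rec.cigartuples = cigar
            rec.mapping_quality = 255
            if aln.sequence is not None:
                rec.query_sequence = aln.sequence
                rec.query_qualities = pysam.qualitystring_to_array("I" * len(aln.sequence))
            rec.set_tag("NM", aln.mismatches)
            rec.set_tag("NH", aln.n_best_locations)
            out.write(rec)


# ---------------------------------------------------------------------------
# FASTQ
# ---------------------------------------------------------------------------

def write_fastq(reads: Iterable[tuple[str, str]], path: str | Path) -> None:
    """Write ``(read_id, sequence)`` pairs as FASTQ with uniform quality."""
    with open(path, "w") as fh:
        for read_id, seq in reads:
            fh.write(f"@{read_id}\n{seq}\n+\n{'I' * len(seq)}\n")


def read_fastq(path: str | Path) -> Iterator[tuple[str, str]]:
    for rec in SeqIO.parse(str(path), "fastq"):
        yield rec.id, str(rec.seq).upper()


# ---------------------------------------------------------------------------
# Junction tables (BED6 + TSV)
# ---------------------------------------------------------------------------

def junctions_to_frame(junctions: Iterable["JunctionEvent"]) -> pd.DataFrame:
    """One row per junction: identity, status, site sequences and counts.

    Count columns cover the union of samples seen anywhere; junctions without
    support in a sample get an explicit 0.
    """
    junctions = list(junctions)
    samples = sorted({s for j in junctions for s in j.counts})
    amb_samples = sorted({s for j in junctions for s in j.ambiguous_counts})
    norm_samples = sorted({s for j in junctions for s in j.norm_counts})
    rows = []
    for j in junctions:
        row = {
            "chrom": j.chrom_id,
            "intron_start": j.intron_start,
            "intron_end": j.intron_end,
            "strand": j.strand,
            "gene_id": j.gene_id or "",
            "status": j.status,
            "donor_seq": j.donor_seq or "",
            "acceptor_window": j.acceptor_window or "",
            "is_ptc": j.is_ptc if j.is_ptc is not None else "",
        }
        for sample in samples:
            row[f"count_{sample}"] = j.counts.get(sample, 0)
        for sample in amb_samples:
            row[f"ambiguous_{sample}"] = j.ambiguous_counts.get(sample, 0)
        for sample in norm_samples:
            row[f"norm_{sample}"] = j.norm_counts.get(sample, 0.0)
        rows.append(row)
    return pd.DataFrame(rows)


def write_junctions(
    junctions: Sequence["JunctionEvent"],
    bed_path: str | Path,
    tsv_path: str | Path,
) -> None:
    """Serialize junctions as BED6 (0-based half-open introns) and a TSV table."""
    with open(bed_path, "w") as bed:
        for j in junctions:
            name = f"{j.gene_id or 'NA'}|{j.status}"
            score = min(1000, sum(j.counts.values()))
            bed.write(
                f"{j.chrom_id}\t{j.intron_start - 1}\t{j.intron_end}\t"
                f"{name}\t{score}\t{j.strand}\n"
            )
    frame = junctions_to_frame(junctions)
    if frame.empty:
        frame = pd.DataFrame(
            columns=["chrom", "intron_start", "intron_end", "strand", "gene_id",
                     "status", "donor_seq", "acceptor_window", "is_ptc"]
        )
    frame.to_csv(tsv_path, sep="\t", index=False)


def read_junctions_tsv(path: str | Path) -> list["JunctionEvent"]:
    """Round-trip reader for :func:`write_junctions` TSV output."""
    from .junction_discovery import JunctionEvent

    frame = pd.read_csv(path, sep="\t", dtype={"gene_id": str}, keep_default_na=False)
    out = []
    for _, row in frame.iterrows():
        counts = {
            c[len("count_"):]: int(float(row[c]))
            for c in frame.columns
            if c.startswith("count_") and str(row[c]) != ""
        }
        amb = {
            c[len("ambiguous_"):]: int(float(row[c]))
            for c in frame.columns
            if c.startswith("ambiguous_") and str(row[c]) != ""
        }
        norm = {
            c[len("norm_"):]: float(row[c]) for c in frame.columns if c.startswith("norm_")
        }
        out.append(
            JunctionEvent(
                chrom_id=row["chrom"],
                strand=row["strand"],
                intron_start=int(row["intron_start"]),
                intron_end=int(row["intron_end"]),
                gene_id=row["gene_id"] or None,
                status=row["status"],
                donor_seq=row["donor_seq"] or None,
                acceptor_window=row["acceptor_window"] or None,
                is_ptc=None if str(row["is_ptc"]) == "" else str(row["is_ptc"]) == "True",
                counts=counts,
                ambiguous_counts=amb,
                norm_counts=norm,
            )
        )
    return out
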