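"""Toy-scale two-step read mapping: ungapped first, then single-gap spliced.

The policy mirrors the classic two-step RNA-seq strategy for short single-end
reads: reads are first placed without gaps allowing up to four mismatches;
only reads that fail that step are re-aligned allowing one gap of 10-20000 nt
(an intron) and up to three mismatches.  A read is kept only if its best score
is achieved at no more than two genomic locations, and gapped placements whose
optimal gap would be shorter than ten nucleotides are never produced.

This aligner does exhaustive scans and is meant for toy genomes (tens of kb);
for real data the pipeline ingests externally produced SAM instead
(:func:`cryptosplice.io_formats.read_alignments`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .io_formats import GenomeModel, Interval, read_fastq, revcomp

_BIG = np.int32(10**6)
_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}

DEFAULT_MAX_MISMATCH_UNGAPPED = 4
DEFAULT_MAX_MISMATCH_GAPPED = 3
DEFAULT_MIN_GAP = 10
DEFAULT_MAX_GAP = 20000
DEFAULT_MIN_ANCHOR = 12


class ReadError(ValueError):
    """A read violated the input contract (alphabet, length)."""


@dataclass
class SplicedAlignment:
    """One placement of a read: 1 block (ungapped) or 2 blocks around a gap.

    ``blocks`` are genomic, 1-based inclusive, ascending; ``read_blocks`` are
    the matching 1-based intervals along the read in aligned (genome-forward)
    orientation.  ``sequence``, when present, is likewise the aligned-
    orientation read sequence, as a SAM writer expects it.
    """

    read_id: str
    chrom_id: str
    strand: str
    blocks: list[Interval]
    read_blocks: list[Interval]
    mismatches: int
    n_best_locations: int = 1
    step: str = "ungapped"
    sequence: str | None = None

    def __post_init__(self) -> None:
        if len(self.blocks) not in (1, 2):
            raise ValueError("an alignment has one block or one gap (two blocks)")

    @property
    def has_gap(self) -> bool:
        return len(self.blocks) == 2

    @property
    def gap_length(self) -> int:
        if not self.has_gap:
            return 0
        return self.blocks[1][0] - self.blocks[0][1] - 1

    @property
    def gap_interval(self) -> Interval | None:
        """The skipped genomic interval (candidate intron), 1-based inclusive."""
        if not self.has_gap:
            return None
        return (self.blocks[0][1] + 1, self.blocks[1][0] - 1)


def _encode(seq: str, *, read: bool) -> np.ndarray:
    bad = set(seq) - set(_CODE)
    if bad:
        raise ReadError(f"sequence contains invalid base(s) {sorted(bad)}")
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    out = np.empty(len(seq), dtype=np.uint8)
    for base, code in _CODE.items():
        out[arr == ord(base)] = code
    if read:
        out[out == 4] = 5  # read N never matches, not even genome N
    return out


def _check_read(read: str) -> None:
    if len(read) < 20:
        raise ReadError(f"read length {len(read)} < 20")


def align_ungapped(
    read: str,
    genome: Mapping[str, GenomeModel],
    max_mismatch: int = DEFAULT_MAX_MISMATCH_UNGAPPED,
    read_id: str = "read",
) -> list[SplicedAlignment]:
    """All best-scoring ungapped placements of ``read`` on both strands.

    Returns every location achieving the minimum mismatch count when that
    minimum is ≤ ``max_mismatch``, else an empty list.  Any N (in read or
    genome) counts as a mismatch.
    """
    read = read.upper()
    _check_read(read)
    L = len(read)
    hits: list[tuple[str, str, int, int]] = []  # (chrom, strand, pos0, mm)
    best = _BIG
    for chrom in genome.values():
        if chrom.length < L:
            continue
        garr = _encode(chrom.sequence, read=False)
        windows = sliding_window_view(garr, L)
        for strand, rseq in (("+", read), ("-", revcomp(read))):
            rarr = _encode(rseq, read=True)
            mm = np.count_nonzero(windows != rarr, axis=1)
            lo = int(mm.min())
            if lo > max_mismatch or lo > best:
                continue
            if lo < best:
                best = lo
                hits = []
            for p in np.nonzero(mm == lo)[0]:
                hits.append((chrom.chrom_id, strand, int(p), lo))
    hits = [h for h in hits if h[3] == best]
    out = []
    for chrom_id, strand, p, mmc in sorted(hits):
        out.append(
            SplicedAlignment(
                read_id=read_id,
                chrom_id=chrom_id,
                strand=strand,
                blocks=[(p + 1, p + L)],
                read_blocks=[(1, L)],
                mismatches=mmc,
                n_best_locations=len(hits),
                step="ungapped",
                sequence=read if strand == "+" else revcomp(read),
            )
        )
    return out


def _forward_window_min(x: np.ndarray, w: int) -> np.ndarray:
    """``m[i] = min(x[i:i+w])`` with implicit +inf padding past the end."""
    n = len(x)
    pad = (-n) % w + w
    xp = np.concatenate([x, np.full(pad, _BIG, x.dtype)])
    k = len(xp) // w
    blocks = xp.reshape(k, w)
    suf = np.minimum.accumulate(blocks[:, ::-1], axis=1)[:, ::-1].ravel()
    pre = np.minimum.accumulate(blocks, axis=1).ravel()
    return np.minimum(suf[:n], pre[w - 1 : w - 1 + n])


def align_gapped(
    read: str,
    genome: Mapping[str, GenomeModel],
    max_mismatch: int = DEFAULT_MAX_MISMATCH_GAPPED,
    min_gap: int = DEFAULT_MIN_GAP,
    max_gap: int = DEFAULT_MAX_GAP,
    min_anchor: int = DEFAULT_MIN_ANCHOR,
    read_id: str = "read",
) -> list[SplicedAlignment]:
    """All best-scoring single-gap placements of ``read`` on both strands.

    The search is exhaustive over split points (each anchor ≥ ``min_anchor``
    nt) and gap lengths in [``min_gap``, ``max_gap``]; score is the mismatch
    count.  Placements whose optimal gap would be < ``min_gap`` are simply
    never produced: they belong to the ungapped step or are discarded.
    """
    read = read.upper()
    _check_read(read)
    L = len(read)
    if L < 2 * min_anchor:
        return []
    splits = range(min_anchor, L - min_anchor + 1)

    # Per (chrom, strand): prefix/suffix mismatch tables from one cumulative
    # mismatch matrix over a sentinel-padded genome; the windowed minimum over
    # admissible gap lengths prunes the (position, split, gap) search.
    best = int(_BIG)
    state: list[tuple[str, str, np.ndarray, int]] = []
    for chrom in genome.values():
        G = chrom.length
        if G < L:
            continue
        garr = np.full(G + L, 255, dtype=np.uint8)
        garr[:G] = _encode(chrom.sequence, read=False)
        windows = sliding_window_view(garr, L)  # (G + 1, L)
        for strand, rseq in (("+", read), ("-", revcomp(read))):
            rarr = _encode(rseq, read=True)
            neq = windows != rarr
            C = np.zeros((neq.shape[0], L + 1), dtype=np.int32)
            np.cumsum(neq, axis=1, out=C[:, 1:])
            state.append((chrom.chrom_id, strand, C, G))
            for s in splits:
                P = C[:, s].copy()
                P[max(0, G - s + 1) :] = _BIG  # prefix must fit the chromosome
                S = (C[:, L] - C[:, s]).copy()
                S[max(0, G - L + 1) :] = _BIG  # suffix must fit too
                span = min(max_gap, len(S)) - min_gap + 1
                if span <= 0:
                    continue
                wmin = _forward_window_min(S, span)
                tot = P[: max(0, len(S) - min_gap)]
                if len(tot) == 0:
                    continue
                tot = tot + wmin[min_gap : min_gap + len(tot)]
                lo = int(tot.min())
                if lo < best:
                    best = lo
    if best > max_mismatch:
        return []

    hits: list[tuple[str, str, int, int, int]] = []  # (chrom, strand, p, s, j)
    for chrom_id, strand, C, G in state:
        for s in splits:
            P = C[:, s].copy()
            P[max(0, G - s + 1) :] = _BIG
            S = (C[:, L] - C[:, s]).copy()
            S[max(0, G - L + 1) :] = _BIG
            for p in np.nonzero(P <= best)[0]:
                lo_j = p + min_gap
                hi_j = min(p + max_gap, len(S) - 1)
                if lo_j > hi_j:
                    continue
                need = best - int(P[p])
                for off in np.nonzero(S[lo_j : hi_j + 1] == need)[0]:
                    hits.append((chrom_id, strand, int(p), s, int(lo_j + off)))
    out = []
    for chrom_id, strand, p, s, j in sorted(hits):
        q = j + s
        out.append(
            SplicedAlignment(
                read_id=read_id,
                chrom_id=chrom_id,
                strand=strand,
                blocks=[(p + 1, p + s), (q + 1, q + L - s)],
                read_blocks=[(1, s), (s + 1, L)],
                mismatches=best,
                n_best_locations=len(hits),
                step="gapped",
                sequence=read if strand == "+" else revcomp(read),
            )
        )
    return out


def map_library(
    reads: str | Path | Iterable[tuple[str, str]],
    genome: Mapping[str, GenomeModel],
    max_mismatch_ungapped: int = DEFAULT_MAX_MISMATCH_UNGAPPED,
    max_mismatch_gapped: int = DEFAULT_MAX_MISMATCH_GAPPED,
    min_gap: int = DEFAULT_MIN_GAP,
    max_gap: int = DEFAULT_MAX_GAP,
    min_anchor: int = DEFAULT_MIN_ANCHOR,
    max_locations: int = 2,
) -> tuple[list[SplicedAlignment], dict[str, int]]:
    """Two-step mapping of a read library with the acceptance filters.

    Reads are first aligned ungapped; only reads with *no* ungapped placement
    within the mismatch budget proceed to the gapped step.  A read is kept iff
    its best score is reached at ≤ ``max_locations`` genomic locations; kept
    multi-mapping reads contribute one (flagged) alignment at each location.

    ``reads`` may be a FASTQ path or an iterable of ``(read_id, sequence)``.
    Returns the accepted alignments and a mapping report.
    """
    if isinstance(reads, (str, Path)):
        reads = read_fastq(reads)
    report = {
        "total_reads": 0,
        "step1_mapped": 0,
        "step1_rejected_multimapped": 0,
        "step2_mapped": 0,
        "step2_rejected_multimapped": 0,
        "unmapped": 0,
        "ambiguous_reads": 0,
        "accepted_alignments": 0,
    }
    accepted: list[SplicedAlignment] = []
    for read_id, seq in reads:
        report["total_reads"] += 1
        hits = align_ungapped(seq, genome, max_mismatch_ungapped, read_id=read_id)
        step = "step1"
        if not hits:
            hits = align_gapped(
                seq, genome, max_mismatch_gapped, min_gap, max_gap, min_anchor,
                read_id=read_id,
            )
            step = "step2"
        if not hits:
            report["unmapped"] += 1
            continue
        if len(hits) > max_locations:
            report[f"{step}_rejected_multimapped"] += 1
            continue
        report[f"{step}_mapped"] += 1
        if len(hits) > 1:
            report["ambiguous_reads"] += 1
        accepted.extend(hits)
        report["accepted_alignments"] += len(hits)
    return accepted, report
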