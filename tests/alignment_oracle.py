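"""Independent brute-force oracle for the two-step mapping policy.

Mismatch vectors are built by looping over read offsets (a different
organization from the package's sliding-window matrices), and gapped
placements are found by direct enumeration of (prefix position, split,
suffix position) triples under the explicit gap constraints — no windowed-
minimum search.  Used only by tests.
"""

from __future__ import annotations

import numpy as np

from cryptosplice.io_formats import GenomeModel, revcomp


def _codes(seq: str) -> np.ndarray:
    table = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 9}
    return np.array([table[b] for b in seq], dtype=np.int8)


def _mismatch_columns(garr: np.ndarray, rarr: np.ndarray) -> list[np.ndarray]:
    """col[i][p] = 1 iff genome[p + i] != read[i], for p in [0, G - L]."""
    G, L = len(garr), len(rarr)
    n = G - L + 1
    return [(garr[i : i + n] != rarr[i]).astype(np.int16) for i in range(L)]


def oracle_ungapped(read: str, genome: dict[str, GenomeModel], max_mm: int):
    """All best-score ungapped placements as (chrom, strand, pos0, mm)."""
    L = len(read)
    results = []
    for chrom in genome.values():
        if chrom.length < L:
            continue
        garr = _codes(chrom.sequence)
        for strand, rseq in (("+", read), ("-", revcomp(read))):
            cols = _mismatch_columns(garr, _codes(rseq))
            mm = np.sum(cols, axis=0)
            for p in range(len(mm)):
                results.append((chrom.chrom_id, strand, p, int(mm[p])))
    if not results:
        return []
    best = min(r[3] for r in results)
    if best > max_mm:
        return []
    return sorted(r for r in results if r[3] == best)


def oracle_gapped(
    read: str,
    genome: dict[str, GenomeModel],
    max_mm: int,
    min_gap: int,
    max_gap: int,
    min_anchor: int,
):
    """All best-score single-gap placements as (chrom, strand, blocks, mm).

    Enumerates every admissible (p, s, q) triple: prefix read[:s] at p,
    suffix read[s:] at q, gap q − (p + s) in [min_gap, max_gap], both
    anchors ≥ min_anchor and inside the chromosome.
    """
    L = len(read)
    placements = []
    for chrom in genome.values():
        G = chrom.length
        if G < L:
            continue
        garr = _codes(chrom.sequence)
        for strand, rseq in (("+", read), ("-", revcomp(read))):
            rarr = _codes(rseq)
            for s in range(min_anchor, L - min_anchor + 1):
                npre = G - s + 1
                pre = np.zeros(npre, dtype=np.int16)
                for i in range(s):
                    pre += garr[i : i + npre] != rarr[i]
                m = L - s
                nsuf = G - m + 1
                suf = np.zeros(nsuf, dtype=np.int16)
                for i in range(m):
                    suf += garr[i : i + nsuf] != rarr[s + i]
                cand_p = np.nonzero(pre <= max_mm)[0]
                cand_q = np.nonzero(suf <= max_mm)[0]
                if len(cand_p) == 0 or len(cand_q) == 0:
                    continue
                gaps = cand_q[None, :] - (cand_p[:, None] + s)
                tot = pre[cand_p][:, None] + suf[cand_q][None, :]
                ok = (gaps >= min_gap) & (gaps <= max_gap) & (tot <= max_mm)
                for ip, iq in zip(*np.nonzero(ok)):
                    p, q = int(cand_p[ip]), int(cand_q[iq])
                    blocks = ((p + 1, p + s), (q + 1, q + L - s))
                    placements.append(
                        (chrom.chrom_id, strand, blocks, int(tot[ip, iq]))
                    )
    if not placements:
        return []
    best = min(pl[3] for pl in placements)
    return sorted(pl for pl in placements if pl[3] == best)


def oracle_map_read(
    read: str,
    genome: dict[str, GenomeModel],
    max_mm_ungapped: int = 4,
    max_mm_gapped: int = 3,
    min_gap: int = 10,
    max_gap: int = 20000,
    min_anchor: int = 12,
    max_locations: int = 2,
):
    """Full two-step policy: returns (step, accepted placements as block sets).

    ``step`` is "step1", "step2" or "unmapped"; placements are kept only when
    their count is ≤ ``max_locations`` (else the read is rejected and an
    empty list is returned with the step that produced the multi-mapping).
    """
    hits = oracle_ungapped(read, genome, max_mm_ungapped)
    if hits:
        placements = [
            (c, st, ((p + 1, p + len(read)),), mm) for c, st, p, mm in hits
        ]
        step = "step1"
    else:
        placements = oracle_gapped(
            read, genome, max_mm_gapped, min_gap, max_gap, min_anchor
        )
        step = "step2" if placements else "unmapped"
    if len(placements) > max_locations:
        return step, []
    return step, placements
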