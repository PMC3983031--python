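"""Shared fixtures: a hand-crafted two-exon gene with known protein output,
its minus-strand mirror, and a small error-free simulated study."""

from __future__ import annotations

from dataclasses import replace

import pytest

from cryptosplice.io_formats import GeneModel, GenomeModel, revcomp
from cryptosplice.junction_discovery import JunctionEvent
from cryptosplice.synthetic_data import (
    SimConfig,
    build_toy_genome,
    simulate_reads,
)

# A fully hand-specified gene ("TOY1"): 9 nt 5' UTR, 8 codons in exon 1, a
# 60 nt intron ending TAAGTAG (canonical TAG acceptor preceded by an AAG and
# a TAA that become in-frame/frameshift stops under small acceptor shifts),
# then 5 codons (incl. stop) and a 12 nt 3' UTR that stops in every frame.
UTR5 = "TTTTTTTTT"
EXON1_CDS = "ATGGTTTGTACTGATTCAGAACTT"        # MVCTDSEL
INTRON = "GTATGT" + "C" * 20 + "TACTAAC" + "C" * 20 + "TAAGTAG"
EXON2_CDS = "AAGTGCCATTGGTAA"                 # KCHW*
UTR3 = "TTAATTAATTAA"
EXON1 = UTR5 + EXON1_CDS                      # 33 nt
EXON2 = EXON2_CDS + UTR3                      # 27 nt
SPACER1 = ("ACGT" * 13)[:50]
SPACER2 = ("GGCCA" * 8)[:40]
CHROM_SEQ = SPACER1 + EXON1 + INTRON + EXON2 + SPACER2  # 210 nt

CANONICAL_PROTEIN = "MVCTDSELKCHW"
CANONICAL_MRNA = EXON1 + EXON2                # 60 nt
CDS_START, CDS_STOP = 10, 48
PLUS_EXONS = [(51, 83), (144, 170)]
PLUS_INTRON = (84, 143)
CHROM_LEN = len(CHROM_SEQ)


def flip(iv: tuple[int, int], length: int = CHROM_LEN) -> tuple[int, int]:
    """Mirror a 1-based interval onto the reverse-complemented chromosome."""
    return (length - iv[1] + 1, length - iv[0] + 1)


@pytest.fixture(scope="session")
def toy() -> dict:
    genome = {
        "chrP": GenomeModel("chrP", CHROM_SEQ),
        "chrM": GenomeModel("chrM", revcomp(CHROM_SEQ)),
    }
    gene_plus = GeneModel("TOY1", "chrP", "+", PLUS_EXONS, CDS_START, CDS_STOP)
    gene_minus = GeneModel(
        "TOY1M", "chrM", "-", sorted(flip(iv) for iv in PLUS_EXONS),
        CDS_START, CDS_STOP,
    )
    # Same gene body but with a stop-free G-run 3' UTR, so removing the stop
    # codon leaves no downstream stop at all.
    chrom2 = SPACER1 + EXON1 + INTRON + EXON2_CDS + "G" * 12 + SPACER2
    genome["chrG"] = GenomeModel("chrG", chrom2)
    gene_grun = GeneModel("TOY2", "chrG", "+", PLUS_EXONS, CDS_START, CDS_STOP)
    intronless = GeneModel("FLAT1", "chrP", "+", [(180, 205)])
    return {
        "genome": genome,
        "genes": {
            "TOY1": gene_plus,
            "TOY1M": gene_minus,
            "TOY2": gene_grun,
            "FLAT1": intronless,
        },
    }


def make_event(
    iv: tuple[int, int],
    chrom: str = "chrP",
    strand: str = "+",
    gene_id: str | None = "TOY1",
    status: str = "alternative",
    **kwargs,
) -> JunctionEvent:
    return JunctionEvent(
        chrom_id=chrom,
        strand=strand,
        intron_start=iv[0],
        intron_end=iv[1],
        gene_id=gene_id,
        status=status,
        **kwargs,
    )


@pytest.fixture(scope="session")
def small_sim():
    """Error-free four-genotype simulation over 10 toy genes."""
    config = SimConfig(n_genes=10, library_size=4000, error_rate=0.0, seed=42)
    scenario = build_toy_genome(config)
    result = simulate_reads(scenario)
    return scenario, result
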