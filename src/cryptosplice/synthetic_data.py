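"""Toy genome and RNA-seq library simulator with an explicit NMD-decay model.

The generator builds a small genome of two-exon intron-containing genes with
canonical yeast splice signals (GTATGT donor, TACTAAC branchpoint,
polypyrimidine tract, TAG acceptor) and plants configurable alternative
donor/acceptor sites — degenerate motifs such as the GTTTGT alternative donor
— at fixed offsets from the canonical sites.  75-nt single-end read libraries
are then simulated for an NMD-competent genotype (WT) and NMD-deficient
genotypes (upf1/upf2/upf3 deletions) under a steady-state decay model: every
NMD-target isoform (PTC-bearing splice products and, by default, unspliced
pre-mRNA) keeps only a fraction ``r`` (the retention factor) of its pre-decay
abundance in the NMD-competent genotype, after which per-gene proportions are
renormalized.  NMD-deficient genotypes sample the pre-decay proportions
unchanged.

Everything is deterministic for a given seed, and full ground truth (per-read
origin, per-isoform proportions, planted-event registry) is retained so the
downstream pipeline can be validated against it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .io_formats import (
    GeneModel,
    GenomeModel,
    Interval,
    revcomp,
    write_annotation,
    write_fastq,
    write_genome,
    write_alignments,
)
from .spliced_alignment import SplicedAlignment

_BASES = "ACGT"
_STOPS = {"TAA", "TAG", "TGA"}
_SENSE_CODONS = [
    a + b + c
    for a in _BASES
    for b in _BASES
    for c in _BASES
    if a + b + c not in _STOPS
]

CANONICAL_DONOR = "GTATGT"
BRANCHPOINT = "TACTAAC"
CANONICAL_ACCEPTOR = "TAG"
DEFAULT_ALT_DONOR = "GTTTGT"


class ConfigError(ValueError):
    """The simulation configuration is internally inconsistent."""


@dataclass(frozen=True)
class AltEventSpec:
    """One planted alternative splice site.

    ``kind`` is ``alt5`` (donor moves) or ``alt3`` (acceptor moves); ``offset``
    is the shift in nt along transcript orientation, positive = downstream.
    An ``alt5`` with positive offset or an ``alt3`` with negative offset puts
    the alternative site inside the intron (intron retention in the product)
    and ``motif`` is planted there; sites falling in exonic sequence keep
    whatever (random) sequence is present, mimicking cryptic exonic sites.
    """

    kind: str
    offset: int
    motif: str | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("alt5", "alt3"):
            raise ConfigError(f"unknown event kind {self.kind!r}")
        if self.offset == 0:
            raise ConfigError("offset 0 would replicate the canonical site")


#: Default per-gene event geometries, cycled across genes.  They echo the
#: validated event classes: small downstream acceptor shifts causing
#: frameshifts, an upstream in-frame acceptor that retains the canonical TAG,
#: an intronic degenerate donor, and an in-frame exonic donor deletion.
DEFAULT_GEOMETRIES: tuple[tuple[AltEventSpec, ...], ...] = (
    (AltEventSpec("alt3", 7),),
    (AltEventSpec("alt3", -6, "AAG"),),
    (AltEventSpec("alt5", 16, DEFAULT_ALT_DONOR),),
    (AltEventSpec("alt5", -30),),
    (AltEventSpec("alt3", 17), AltEventSpec("alt5", 9, DEFAULT_ALT_DONOR)),
)

DEFAULT_GENOTYPES: tuple[tuple[str, bool], ...] = (
    ("WT", True),
    ("upf1", False),
    ("upf2", False),
    ("upf3", False),
)


@dataclass
class SimConfig:
    """Study design: genome shape, isoform mix, decay, and library parameters.

    ``p_canonical`` + ``p_alt_total`` + ``p_unspliced`` must sum to 1; the
    alternative share is split equally among a gene's planted events.
    ``nmd_retention`` is the fraction of each NMD-target isoform surviving in
    an NMD-competent genotype.
    """

    n_genes: int = 20
    exon_len_range: tuple[int, int] = (150, 400)
    intron_len_range: tuple[int, int] = (90, 200)
    utr5_len_range: tuple[int, int] = (20, 50)
    utr3_len_range: tuple[int, int] = (45, 90)
    spacer_len_range: tuple[int, int] = (200, 400)
    geometries: tuple[tuple[AltEventSpec, ...], ...] = DEFAULT_GEOMETRIES
    p_canonical: float = 0.65
    p_alt_total: float = 0.20
    p_unspliced: float = 0.15
    nmd_retention: float = 0.5
    unspliced_is_nmd_target: bool = True
    expression_log_mu: float = 0.0
    expression_log_sigma: float = 1.0
    read_len: int = 75
    error_rate: float = 0.001
    library_size: int = 50_000
    genotypes: tuple[tuple[str, bool], ...] = DEFAULT_GENOTYPES
    chrom_id: str = "chrI"
    seed: int = 0

    def __post_init__(self) -> None:
        total = self.p_canonical + self.p_alt_total + self.p_unspliced
        if abs(total - 1.0) > 1e-9:
            raise ConfigError(f"isoform proportions sum to {total}, not 1")
        if not 0 < self.nmd_retention <= 1:
            raise ConfigError("nmd_retention must be in (0, 1]")
        if self.library_size <= 0:
            raise ConfigError("library_size must be positive")
        if self.n_genes <= 0:
            raise ConfigError("n_genes must be positive")
        if not 0 <= self.error_rate < 1:
            raise ConfigError("error_rate must be in [0, 1)")


@dataclass
class IsoformModel:
    """One transcript isoform of a toy gene, in local gene coordinates.

    Local coordinates are 1-based along the gene in transcript orientation
    (position 1 is the transcript 5' end); ``kept_local`` are the intervals
    retained in the mRNA, ascending, and ``junction_local`` the excised
    interval of the event (None for the unspliced isoform).
    """

    isoform_id: str
    gene_id: str
    kind: str                      # canonical | alt | unspliced
    mrna: str
    kept_local: list[Interval]
    junction_local: Interval | None
    pre_decay: float
    nmd_target: bool
    is_ptc: bool = False
    junction_genomic: Interval | None = None

    @property
    def length(self) -> int:
        return len(self.mrna)

    @property
    def junction_tx_pos(self) -> int | None:
        """Transcript position of the last base before the splice, if any."""
        if self.junction_local is None:
            return None
        return self.kept_local[0][1] - self.kept_local[0][0] + 1


@dataclass
class GeneScenario:
    """A placed toy gene: local structure plus its genomic embedding."""

    gene_id: str
    strand: str
    genomic_offset: int          # gene occupies genomic [offset+1, offset+local_len]
    local_len: int
    isoforms: list[IsoformModel]
    theta: float = 0.0           # relative expression weight (normalized)

    def local_to_genomic(self, iv: Interval) -> Interval:
        a, b = iv
        if self.strand == "+":
            return (self.genomic_offset + a, self.genomic_offset + b)
        return (
            self.genomic_offset + self.local_len - b + 1,
            self.genomic_offset + self.local_len - a + 1,
        )


@dataclass
class SimScenario:
    """Toy genome, gene models, planted-event registry and expression weights."""

    config: SimConfig
    genome: dict[str, GenomeModel]
    genes: dict[str, GeneModel]
    gene_scenarios: dict[str, GeneScenario]
    registry: pd.DataFrame

    @property
    def read_len(self) -> int:
        return self.config.read_len


# ---------------------------------------------------------------------------
# Gene construction
# ---------------------------------------------------------------------------

def _random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(map(_BASES.__getitem__, rng.integers(0, 4, n)))


def _random_cds(rng: np.random.Generator, n_codons: int) -> str:
    idx = rng.integers(0, len(_SENSE_CODONS), n_codons)
    return "".join(_SENSE_CODONS[i] for i in idx)


def _build_intron(rng: np.random.Generator, length: int) -> str:
    if length < 50:
        raise ConfigError(f"intron length {length} < 50 cannot hold splice signals")
    seq = list(_random_dna(rng, length))
    seq[0:6] = CANONICAL_DONOR
    seq[length - 37 : length - 30] = BRANCHPOINT
    # T-rich polypyrimidine tract upstream of the acceptor
    seq[length - 13 : length - 4] = "".join(
        map("TC".__getitem__, (rng.random(9) < 0.3).astype(int))
    )
    seq[length - 3 : length] = CANONICAL_ACCEPTOR
    return "".join(seq)


def _event_interval_local(
    e1: int, intron_len: int, spec: AltEventSpec
) -> Interval:
    """Excised local interval of an event, given exon1 length and intron length."""
    s, e = e1 + 1, e1 + intron_len
    if spec.kind == "alt5":
        return (s + spec.offset, e)
    return (s, e + spec.offset)


def _first_stop(mrna: str, cds_start: int) -> int | None:
    for i in range(cds_start - 1, len(mrna) - 2, 3):
        if mrna[i : i + 3] in _STOPS:
            return i + 1
    return None


def _wobble_free(seq: str, iv: Interval) -> bool:
    """True when the excised interval cannot slide by one nt at equal score.

    A junction is ambiguous to any aligner when the first excised base equals
    the first base after the excision (right shift) or the last excised base
    equals the base before it (left shift); the generator rejects such genes
    so that simulated junctions have a unique gapped placement.
    """
    s, e = iv  # 1-based on seq
    right = e < len(seq) and seq[s - 1] == seq[e]
    left = s > 1 and seq[s - 2] == seq[e - 1]
    return not (right or left)


def _try_build_gene(
    rng: np.random.Generator,
    config: SimConfig,
    gene_id: str,
    events: Sequence[AltEventSpec],
) -> dict | None:
    e1 = int(rng.integers(*config.exon_len_range))
    e2 = int(rng.integers(*config.exon_len_range))
    intron_len = int(rng.integers(*config.intron_len_range))
    utr5 = int(rng.integers(*config.utr5_len_range))
    utr3 = int(rng.integers(*config.utr3_len_range))

    mrna_len = e1 + e2
    cds_len = mrna_len - utr5 - utr3
    cds_len -= cds_len % 3
    if cds_len < 90:
        return None
    cds_start = utr5 + 1
    cds_stop = utr5 + cds_len
    utr3 = mrna_len - cds_stop
    # The junction must sit well inside the CDS so alternative excisions hit
    # coding sequence (margin 33 nt on either side).
    if not (cds_start + 33 <= e1 <= cds_stop - 33):
        return None

    cds = "ATG" + _random_cds(rng, cds_len // 3 - 2) + "TAA"
    mrna = _random_dna(rng, utr5) + cds + _random_dna(rng, utr3)
    intron = _build_intron(rng, intron_len)

    # Validate event offsets against this gene's geometry before planting.
    for spec in events:
        if spec.kind == "alt5":
            if spec.offset <= -e1 + 5 or spec.offset >= intron_len - 45:
                raise ConfigError(
                    f"{gene_id}: alt5 offset {spec.offset} collides with exon "
                    "or intron boundaries"
                )
        else:
            if spec.offset >= e2 - 5 or spec.offset <= -(intron_len - 45):
                raise ConfigError(
                    f"{gene_id}: alt3 offset {spec.offset} collides with exon "
                    "or intron boundaries"
                )

    # Plant intron-internal alternative site motifs.
    intron_chars = list(intron)
    for spec in events:
        if spec.motif is None:
            continue
        m = spec.motif
        if spec.kind == "alt5" and spec.offset > 0:
            pos = spec.offset  # 0-based start of planted donor inside intron
            if pos + len(m) > intron_len - 44:
                raise ConfigError(f"{gene_id}: planted donor overlaps branchpoint")
            intron_chars[pos : pos + len(m)] = m
        elif spec.kind == "alt3" and spec.offset < 0:
            end = intron_len + spec.offset  # 1-based last base of alt intron
            if end - len(m) + 1 <= intron_len - 30:
                raise ConfigError(
                    f"{gene_id}: planted acceptor would overlap the branchpoint"
                )
            intron_chars[end - len(m) : end] = m
    intron = "".join(intron_chars)

    local = mrna[:e1] + intron + mrna[e1:]
    local_len = len(local)
    exons_local = [(1, e1), (e1 + intron_len + 1, local_len)]
    canonical_iv = (e1 + 1, e1 + intron_len)

    # Reject genes whose junctions could slide at equal alignment score.
    intervals = [canonical_iv] + [
        _event_interval_local(e1, intron_len, s) for s in events
    ]
    if len(set(intervals)) != len(intervals):
        return None
    for iv in intervals:
        if not (1 < iv[0] <= iv[1] < local_len):
            return None
        if not _wobble_free(local, iv):
            return None
    # Canonical CDS must be clean: first in-frame stop is the real stop.
    if _first_stop(mrna, cds_start) != cds_stop - 2:
        return None

    # Isoforms.
    n_alt = len(events)
    isoforms = [
        IsoformModel(
            isoform_id=f"{gene_id}.canonical",
            gene_id=gene_id,
            kind="canonical",
            mrna=mrna,
            kept_local=exons_local,
            junction_local=canonical_iv,
            pre_decay=config.p_canonical,
            nmd_target=False,
        )
    ]
    registry_rows = []
    for i, spec in enumerate(events, 1):
        iv = _event_interval_local(e1, intron_len, spec)
        kept = [(1, iv[0] - 1), (iv[1] + 1, local_len)]
        alt_mrna = local[: iv[0] - 1] + local[iv[1]:]
        delta = len(alt_mrna) - len(mrna)
        stop = _first_stop(alt_mrna, cds_start)
        canon_stop_mapped = cds_stop - 2 + delta
        is_ptc = stop is not None and stop < canon_stop_mapped
        iso = IsoformModel(
            isoform_id=f"{gene_id}.alt{i}",
            gene_id=gene_id,
            kind="alt",
            mrna=alt_mrna,
            kept_local=kept,
            junction_local=iv,
            pre_decay=config.p_alt_total / n_alt,
            nmd_target=is_ptc,
            is_ptc=is_ptc,
        )
        isoforms.append(iso)
        registry_rows.append(
            {
                "gene_id": gene_id,
                "event_id": iso.isoform_id,
                "kind": spec.kind,
                "offset": spec.offset,
                "motif": spec.motif or "",
                "frameshift": bool(delta % 3),
                "ptc": is_ptc,
                "nmd_target": is_ptc,
                "local_start": iv[0],
                "local_end": iv[1],
            }
        )
    isoforms.append(
        IsoformModel(
            isoform_id=f"{gene_id}.unspliced",
            gene_id=gene_id,
            kind="unspliced",
            mrna=local,
            kept_local=[(1, local_len)],
            junction_local=None,
            pre_decay=config.p_unspliced,
            nmd_target=config.unspliced_is_nmd_target,
        )
    )
    if min(iso.length for iso in isoforms) < config.read_len:
        return None
    return {
        "gene_id": gene_id,
        "local": local,
        "local_len": local_len,
        "exons_local": exons_local,
        "cds_start": cds_start,
        "cds_stop": cds_stop,
        "isoforms": isoforms,
        "registry_rows": registry_rows,
    }


def build_toy_genome(config: SimConfig) -> SimScenario:
    """Build the toy genome, gene models and planted-event registry.

    Deterministic for a given ``config.seed``: the same seed yields a
    byte-identical genome.  Genes alternate between the + and − strands and
    are separated by random intergenic spacers.  Per-gene expression weights
    (log-normal) are drawn here so that closed-form expectations and the read
    simulator share one set of weights.
    """
    rng = np.random.default_rng(config.seed)
    pieces: list[str] = []
    pos = 0
    genes: dict[str, GeneModel] = {}
    scenarios: dict[str, GeneScenario] = {}
    registry_rows: list[dict] = []

    for gi in range(config.n_genes):
        gene_id = f"g{gi + 1:03d}"
        events = config.geometries[gi % len(config.geometries)]
        built = None
        for _ in range(200):
            built = _try_build_gene(rng, config, gene_id, events)
            if built is not None:
                break
        if built is None:
            raise ConfigError(
                f"could not build gene {gene_id} under the configured geometry"
            )
        spacer = _random_dna(rng, int(rng.integers(*config.spacer_len_range)))
        pieces.append(spacer)
        pos += len(spacer)
        strand = "+" if gi % 2 == 0 else "-"
        local = built["local"]
        pieces.append(local if strand == "+" else revcomp(local))
        scenario = GeneScenario(
            gene_id=gene_id,
            strand=strand,
            genomic_offset=pos,
            local_len=built["local_len"],
            isoforms=built["isoforms"],
        )
        pos += built["local_len"]
        exons_genomic = sorted(
            scenario.local_to_genomic(iv) for iv in built["exons_local"]
        )
        genes[gene_id] = GeneModel(
            gene_id=gene_id,
            chrom_id=config.chrom_id,
            strand=strand,
            exons=exons_genomic,
            cds_start=built["cds_start"],
            cds_stop=built["cds_stop"],
        )
        for iso in built["isoforms"]:
            if iso.junction_local is not None:
                iso.junction_genomic = scenario.local_to_genomic(iso.junction_local)
        for row in built["registry_rows"]:
            iv = scenario.local_to_genomic((row.pop("local_start"), row.pop("local_end")))
            row["chrom"] = config.chrom_id
            row["strand"] = strand
            row["intron_start"], row["intron_end"] = iv
            registry_rows.append(row)
        scenarios[gene_id] = scenario
    pieces.append(_random_dna(rng, int(rng.integers(*config.spacer_len_range))))

    theta = rng.lognormal(
        config.expression_log_mu, config.expression_log_sigma, config.n_genes
    )
    theta /= theta.sum()
    for w, scenario in zip(theta, scenarios.values()):
        scenario.theta = float(w)

    genome = {
        config.chrom_id: GenomeModel(config.chrom_id, "".join(pieces))
    }
    registry = pd.DataFrame(registry_rows)
    return SimScenario(
        config=config,
        genome=genome,
        genes=genes,
        gene_scenarios=scenarios,
        registry=registry,
    )


# ---------------------------------------------------------------------------
# Decay model
# ---------------------------------------------------------------------------

def isoform_abundances(
    isoforms: Sequence[IsoformModel],
    nmd_active: bool,
    retention: float,
) -> np.ndarray:
    """Post-decay isoform proportions for one gene in one genotype.

    With NMD active, each NMD-target isoform's pre-decay proportion is
    multiplied by the retention factor and the gene's proportions are
    renormalized; with NMD inactive the pre-decay proportions are returned
    unchanged.
    """
    if not 0 < retention <= 1:
        raise ConfigError("retention must be in (0, 1]")
    p = np.array([iso.pre_decay for iso in isoforms], dtype=float)
    if nmd_active:
        target = np.array([iso.nmd_target for iso in isoforms])
        p = np.where(target, p * retention, p)
    return p / p.sum()


def post_decay_proportions(scenario: SimScenario) -> pd.DataFrame:
    """Per gene × genotype × isoform post-decay proportions (ground truth)."""
    rows = []
    r = scenario.config.nmd_retention
    for gene_id, gs in scenario.gene_scenarios.items():
        for genotype, nmd_active in scenario.config.genotypes:
            props = isoform_abundances(gs.isoforms, nmd_active, r)
            for iso, p in zip(gs.isoforms, props):
                rows.append(
                    {
                        "gene_id": gene_id,
                        "genotype": genotype,
                        "isoform_id": iso.isoform_id,
                        "kind": iso.kind,
                        "proportion": p,
                    }
                )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Closed-form expectations
# ---------------------------------------------------------------------------

def spanning_start_count(junction_tx_pos: int, mrna_len: int, read_len: int) -> int:
    """Number of read start positions whose read spans the junction.

    The junction sits between transcript positions ``junction_tx_pos`` and
    ``junction_tx_pos + 1``; a read of length L starting at s covers it iff
    s ≤ j and s + L − 1 ≥ j + 1.  Fully interior junctions give L − 1 starts.
    """
    lo = max(1, junction_tx_pos - read_len + 2)
    hi = min(junction_tx_pos, mrna_len - read_len + 1)
    return max(0, hi - lo + 1)


def expected_event_share(
    scenario: SimScenario,
    nmd_active: bool,
    retention: float,
    subset: str = "ptc",
) -> float:
    """Expected fraction of a library's reads that span events in ``subset``.

    ``subset`` is ``"ptc"`` (NMD-target alternative events), ``"alt"`` (all
    alternative events) or ``"canonical"``.  Exact closed form under the
    sampling model: gene ∝ expression weight, isoform ∝ post-decay
    proportions, start uniform over valid positions.
    """
    L = scenario.config.read_len
    share = 0.0
    for gs in scenario.gene_scenarios.values():
        props = isoform_abundances(gs.isoforms, nmd_active, retention)
        for iso, p in zip(gs.isoforms, props):
            if iso.junction_local is None:
                continue
            if subset == "ptc" and not (iso.kind == "alt" and iso.nmd_target):
                continue
            if subset == "alt" and iso.kind != "alt":
                continue
            if subset == "canonical" and iso.kind != "canonical":
                continue
            j = iso.kept_local[0][1] - iso.kept_local[0][0] + 1
            frac = spanning_start_count(j, iso.length, L) / (iso.length - L + 1)
            share += gs.theta * p * frac
    return share


def expected_aggregate_fold(
    scenario: SimScenario, retention: float, subset: str = "ptc"
) -> float:
    """Closed-form expected depth-adjusted fold, NMD-deficient over NMD+."""
    num = expected_event_share(scenario, nmd_active=False, retention=retention,
                               subset=subset)
    den = expected_event_share(scenario, nmd_active=True, retention=retention,
                               subset=subset)
    return num / den


def solve_retention_for_fold(
    scenario: SimScenario, target_fold: float = 1.7, subset: str = "ptc"
) -> float:
    """Retention factor r at which the expected aggregate fold equals target.

    The fold is 1 at r = 1 and increases monotonically as r decreases, so a
    root exists for any target above 1 that the isoform mix can reach.
    """
    f = lambda r: expected_aggregate_fold(scenario, r, subset) - target_fold
    lo = 1e-6
    if f(lo) < 0:
        raise ConfigError(
            f"target fold {target_fold} unreachable under this isoform mix"
        )
    return float(brentq(f, lo, 1.0, xtol=1e-12))


# ---------------------------------------------------------------------------
# Read simulation
# ---------------------------------------------------------------------------

@dataclass
class SimulatedLibrary:
    """One genotype's simulated library plus its per-read ground truth."""

    genotype: str
    nmd_active: bool
    iso_index: np.ndarray          # per-read index into scenario isoform list
    start: np.ndarray              # per-read 1-based mRNA start position
    n_errors: np.ndarray           # per-read number of substitution errors
    sequences: list[str] | None    # read sequences, None if not materialized

    @property
    def n_reads(self) -> int:
        return len(self.iso_index)


@dataclass
class SimResult:
    """All genotype libraries, with lazy truth-alignment generation."""

    scenario: SimScenario
    libraries: dict[str, SimulatedLibrary]
    isoforms: list[IsoformModel]   # flat isoform list the libraries index into
    gene_of_isoform: list[GeneScenario]

    def read_ids(self, genotype: str) -> list[str]:
        lib = self.libraries[genotype]
        return [f"{genotype}_{i:07d}" for i in range(lib.n_reads)]

    def reads(self, genotype: str) -> Iterator[tuple[str, str]]:
        lib = self.libraries[genotype]
        if lib.sequences is None:
            raise ValueError("library was simulated without sequences")
        for i, seq in enumerate(lib.sequences):
            yield f"{genotype}_{i:07d}", seq

    def truth_alignments(self, genotype: str) -> Iterator[SplicedAlignment]:
        """Error-free genomic alignments of every read, with N gaps where the
        read spans its isoform's junction."""
        lib = self.libraries[genotype]
        L = self.scenario.config.read_len
        chrom = self.scenario.config.chrom_id
        for i in range(lib.n_reads):
            iso = self.isoforms[lib.iso_index[i]]
            gs = self.gene_of_isoform[lib.iso_index[i]]
            t0 = int(lib.start[i])
            blocks_local = _map_read_to_local(iso, t0, L)
            blocks = sorted(gs.local_to_genomic(iv) for iv in blocks_local)
            read_blocks = _read_blocks_for(blocks)
            seq = None
            if lib.sequences is not None:
                s = lib.sequences[i]
                seq = s if gs.strand == "+" else revcomp(s)
            yield SplicedAlignment(
                read_id=f"{genotype}_{i:07d}",
                chrom_id=chrom,
                strand=gs.strand,
                blocks=blocks,
                read_blocks=read_blocks,
                mismatches=int(lib.n_errors[i]),
                n_best_locations=1,
                step="gapped" if len(blocks) > 1 else "ungapped",
                sequence=seq,
            )

    def truth_frame(self, genotype: str) -> pd.DataFrame:
        """Per-read truth table: gene, isoform, start, junction if spanned."""
        lib = self.libraries[genotype]
        L = self.scenario.config.read_len
        rows = {
            "read_id": self.read_ids(genotype),
            "gene_id": [self.isoforms[k].gene_id for k in lib.iso_index],
            "isoform_id": [self.isoforms[k].isoform_id for k in lib.iso_index],
            "start": lib.start,
            "n_errors": lib.n_errors,
        }
        spans = []
        for k, t0 in zip(lib.iso_index, lib.start):
            iso = self.isoforms[k]
            j = (
                iso.kept_local[0][1] - iso.kept_local[0][0] + 1
                if iso.junction_local is not None
                else None
            )
            spans.append(
                j is not None and j - L + 1 < t0 <= j
            )
        rows["spans_junction"] = spans
        return pd.DataFrame(rows)


def _map_read_to_local(iso: IsoformModel, t0: int, L: int) -> list[Interval]:
    """Local gene intervals covered by a read at mRNA position ``t0``."""
    out = []
    t_end = t0 + L - 1
    offset = 0
    for s, e in iso.kept_local:
        n = e - s + 1
        a = max(t0, offset + 1)
        b = min(t_end, offset + n)
        if a <= b:
            out.append((s + (a - offset) - 1, s + (b - offset) - 1))
        offset += n
    return out


def _read_blocks_for(blocks: list[Interval]) -> list[Interval]:
    out = []
    pos = 1
    for s, e in blocks:
        out.append((pos, pos + (e - s)))
        pos += e - s + 1
    return out


def simulate_reads(
    scenario: SimScenario,
    with_sequences: bool = True,
) -> SimResult:
    """Simulate one library per genotype under the decay model.

    Per read: gene ∝ expression weight, isoform ∝ post-decay proportions for
    the genotype, start uniform over valid mRNA positions, i.i.d. substitution
    errors at ``error_rate`` (only when ``with_sequences``).  Deterministic
    per seed; each genotype uses an independent substream.
    """
    config = scenario.config
    L = config.read_len
    isoforms: list[IsoformModel] = []
    gene_of: list[GeneScenario] = []
    for gs in scenario.gene_scenarios.values():
        for iso in gs.isoforms:
            isoforms.append(iso)
            gene_of.append(gs)

    libraries: dict[str, SimulatedLibrary] = {}
    for g_idx, (genotype, nmd_active) in enumerate(config.genotypes):
        rng = np.random.default_rng([config.seed, 7919 + g_idx])
        probs = np.concatenate(
            [
                gs.theta
                * isoform_abundances(gs.isoforms, nmd_active, config.nmd_retention)
                for gs in scenario.gene_scenarios.values()
            ]
        )
        counts = rng.multinomial(config.library_size, probs)
        iso_index = np.repeat(np.arange(len(isoforms)), counts).astype(np.int32)
        start = np.empty(config.library_size, dtype=np.int32)
        pos = 0
        for k, c in enumerate(counts):
            if c == 0:
                continue
            m = isoforms[k].length
            start[pos : pos + c] = rng.integers(1, m - L + 2, size=c)
            pos += c
        # Shuffle so read order does not leak isoform identity.
        perm = rng.permutation(config.library_size)
        iso_index, start = iso_index[perm], start[perm]

        n_errors = np.zeros(config.library_size, dtype=np.int16)
        sequences: list[str] | None = None
        if with_sequences:
            n_errors = rng.binomial(L, config.error_rate, size=config.library_size).astype(
                np.int16
            )
            sequences = []
            for i in range(config.library_size):
                iso = isoforms[iso_index[i]]
                t0 = int(start[i])
                seq = iso.mrna[t0 - 1 : t0 + L - 1]
                k = int(n_errors[i])
                if k:
                    seq_list = list(seq)
                    pos_err = rng.choice(L, size=k, replace=False)
                    for p in pos_err:
                        orig = seq_list[p]
                        choices = [b for b in _BASES if b != orig]
                        seq_list[p] = choices[int(rng.integers(0, 3))]
                    seq = "".join(seq_list)
                sequences.append(seq)
        libraries[genotype] = SimulatedLibrary(
            genotype=genotype,
            nmd_active=nmd_active,
            iso_index=iso_index,
            start=start,
            n_errors=n_errors,
            sequences=sequences,
        )
    return SimResult(
        scenario=scenario,
        libraries=libraries,
        isoforms=isoforms,
        gene_of_isoform=gene_of,
    )


# ---------------------------------------------------------------------------
# Output bundle
# ---------------------------------------------------------------------------

def simulate_to_dir(
    config: SimConfig, outdir: str | Path, with_sequences: bool = True
) -> SimResult:
    """Run the full simulation and write the standard output bundle.

    Writes genome.fa, genes.gff3, registry.tsv, proportions.tsv and, per
    genotype, reads_<genotype>.fastq, truth_<genotype>.sam and
    truth_<genotype>.tsv.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    scenario = build_toy_genome(config)
    result = simulate_reads(scenario, with_sequences=with_sequences)
    write_genome(scenario.genome, outdir / "genome.fa")
    write_annotation(scenario.genes, outdir / "genes.gff3")
    scenario.registry.to_csv(outdir / "registry.tsv", sep="\t", index=False)
    post_decay_proportions(scenario).to_csv(
        outdir / "proportions.tsv", sep="\t", index=False
    )
    for genotype, _ in config.genotypes:
        if with_sequences:
            write_fastq(result.reads(genotype), outdir / f"reads_{genotype}.fastq")
        write_alignments(
            result.truth_alignments(genotype),
            outdir / f"truth_{genotype}.sam",
            scenario.genome,
        )
        result.truth_frame(genotype).to_csv(
            outdir / f"truth_{genotype}.tsv", sep="\t", index=False
        )
    return result
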