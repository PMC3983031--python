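"""Junction collapsing, gene assignment, site sequences and strain overlaps."""

import random
from itertools import combinations

import pytest

from conftest import PLUS_INTRON, flip, make_event

from cryptosplice.junction_discovery import (
    JunctionEvent,
    classify_events,
    extract_junctions,
    site_sequences,
    strain_overlap,
)
from cryptosplice.spliced_alignment import SplicedAlignment


def _gapped(chrom, b1, b2, n_best=1, read_id="r"):
    return SplicedAlignment(
        read_id=read_id, chrom_id=chrom, strand="+", blocks=[b1, b2],
        read_blocks=[(1, b1[1] - b1[0] + 1),
                     (b1[1] - b1[0] + 2, b1[1] - b1[0] + 1 + b2[1] - b2[0] + 1)],
        mismatches=0, n_best_locations=n_best, step="gapped",
    )


def _ungapped(chrom, b):
    return SplicedAlignment(
        read_id="r", chrom_id=chrom, strand="+", blocks=[b],
        read_blocks=[(1, b[1] - b[0] + 1)], mismatches=0,
    )


def test_extract_junctions_block_arithmetic():
    (j,) = extract_junctions({"s1": [_gapped("chr1", (101, 130), (331, 375))]})
    assert (j.intron_start, j.intron_end) == (131, 330)
    assert j.counts == {"s1": 1}


def test_extract_junctions_sums_per_sample_and_tracks_ambiguous():
    alns = {
        "s1": [_gapped("chr1", (101, 130), (331, 375)) for _ in range(3)],
        "s2": [_gapped("chr1", (101, 130), (331, 375), n_best=2)
               for _ in range(3)],
    }
    (j,) = extract_junctions(alns)
    assert j.counts == {"s1": 3, "s2": 3}
    assert j.ambiguous_counts == {"s2": 3}
    # ungapped alignments contribute no junctions
    assert extract_junctions({"s1": [_ungapped("chr1", (1, 75))]}) == []


def test_min_support_drops_singletons():
    alns = {
        "s1": [
            _gapped("chr1", (101, 130), (331, 375)),
            _gapped("chr1", (101, 130), (331, 375)),
            _gapped("chr1", (501, 530), (731, 775)),
        ]
    }
    events = extract_junctions(alns, min_support=2)
    assert len(events) == 1
    assert events[0].intron_start == 131


def test_classify_annotated_alternative_and_outside(toy):
    genes, genome = toy["genes"], toy["genome"]
    events = [
        make_event(PLUS_INTRON, gene_id=None, status="x"),
        make_event((84, 160), gene_id=None, status="x"),   # inside TOY1 span
        make_event((185, 199), gene_id=None, status="x"),  # intronless gene span
    ]
    out = classify_events(events, genes, genome)
    by_key = {j.key[2]: j for j in out}
    assert by_key[84].status in ("annotated", "alternative")
    annotated = next(j for j in out if (j.intron_start, j.intron_end) == PLUS_INTRON)
    assert annotated.status == "annotated" and annotated.gene_id == "TOY1"
    alt = next(j for j in out if j.intron_end == 160)
    assert alt.status == "alternative" and alt.gene_id == "TOY1"
    outside = next(j for j in out if j.intron_start == 185)
    assert outside.status == "outside_icg" and outside.gene_id is None


def test_classify_is_idempotent_and_order_independent(toy):
    genes, genome = toy["genes"], toy["genome"]
    events = [
        make_event(PLUS_INTRON, gene_id=None, status="x"),
        make_event((84, 160), gene_id=None, status="x"),
    ]
    once = classify_events(events, genes, genome)
    twice = classify_events(once, genes, genome)
    assert [(j.key, j.status, j.gene_id) for j in once] == [
        (j.key, j.status, j.gene_id) for j in twice
    ]
    shuffled = classify_events(list(reversed(events)), genes, genome)
    assert sorted(j.key for j in shuffled) == sorted(j.key for j in once)


def test_minus_strand_junction_inherits_gene_strand(toy):
    genes, genome = toy["genes"], toy["genome"]
    iv = flip(PLUS_INTRON)
    (j,) = classify_events(
        [make_event(iv, chrom="chrM", gene_id=None, status="x")], genes, genome
    )
    assert j.status == "annotated" and j.gene_id == "TOY1M" and j.strand == "-"


def test_site_sequences_plus_and_minus(toy):
    genome = toy["genome"]
    plus = make_event(PLUS_INTRON, status="annotated")
    d, a, trunc = site_sequences(plus, genome)
    assert d == "GTATGT" and a == "CTAAGTAG" and not trunc
    minus = make_event(flip(PLUS_INTRON), chrom="chrM", strand="-",
                       status="annotated")
    dm, am, truncm = site_sequences(minus, genome)
    assert (dm, am) == (d, a) and not truncm


def test_site_sequences_short_intron_truncated(toy):
    j = make_event((84, 93), status="alternative")  # 10 nt intron
    d, a, trunc = site_sequences(j, toy["genome"])
    assert trunc and d == "GTATGT" and len(a) == 8


def test_strain_overlap_small_example():
    regions = strain_overlap({"A": ["e1", "e2"], "B": ["e2", "e3"], "C": ["e3"]})
    assert regions[frozenset({"A"})] == 1
    assert regions[frozenset({"A", "B"})] == 1
    assert regions[frozenset({"B", "C"})] == 1
    assert regions[frozenset({"A", "B", "C"})] == 0
    assert sum(regions.values()) == 3


def test_strain_overlap_identical_sets_all_shared():
    regions = strain_overlap({"A": ["e1", "e2"], "B": ["e1", "e2"]})
    assert regions[frozenset({"A", "B"})] == 2
    assert regions[frozenset({"A"})] == regions[frozenset({"B"})] == 0


def test_strain_overlap_matches_brute_force_tabulation():
    rng = random.Random(5)
    universe = [f"e{i}" for i in range(40)]
    sets = {s: set(rng.sample(universe, 20)) for s in ("a", "b", "c", "d")}
    regions = strain_overlap(sets)
    for r in range(1, 5):
        for combo in combinations(sets, r):
            members = set(combo)
            expected = sum(
                1
                for e in universe
                if {s for s in sets if e in sets[s]} == members
            )
            assert regions[frozenset(combo)] == expected


def test_simulated_truth_junctions_recovered_exactly(small_sim):
    """With error-free reads, collapsing the truth alignments reproduces the
    planted registry exactly: every junction is a planted or annotated one."""
    scenario, result = small_sim
    streams = {g: result.truth_alignments(g) for g, _ in scenario.config.genotypes}
    junctions = classify_events(
        extract_junctions(streams), scenario.genes, scenario.genome
    )
    planted = {
        (r.chrom, r.intron_start, r.intron_end)
        for r in scenario.registry.itertuples()
    }
    annotated = {
        (g.chrom_id, *iv) for g in scenario.genes.values() for iv in g.introns
    }
    seen = {(j.chrom_id, j.intron_start, j.intron_end) for j in junctions}
    assert seen <= planted | annotated
    assert all(j.status != "outside_icg" for j in junctions)
    # per-sample counts equal the truth tables' spanning-read tallies
    for genotype, _ in scenario.config.genotypes:
        tf = result.truth_frame(genotype)
        spanning = tf[tf.spans_junction]
        by_iso = spanning.groupby("isoform_id").size()
        iso_junction = {
            iso.isoform_id: (scenario.config.chrom_id, *iso.junction_genomic)
            for gs in scenario.gene_scenarios.values()
            for iso in gs.isoforms
            if iso.junction_genomic is not None
        }
        expected: dict = {}
        for iso_id, n in by_iso.items():
            expected[iso_junction[iso_id]] = expected.get(iso_junction[iso_id], 0) + n
        got = {
            (j.chrom_id, j.intron_start, j.intron_end): j.counts.get(genotype, 0)
            for j in junctions
            if j.counts.get(genotype, 0)
        }
        assert got == expected
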