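"""Toy genome generator and decay-model read simulator."""

import math

import numpy as np
import pytest

from cryptosplice.io_formats import write_genome
from cryptosplice.synthetic_data import (
    AltEventSpec,
    ConfigError,
    IsoformModel,
    SimConfig,
    build_toy_genome,
    expected_aggregate_fold,
    expected_event_share,
    isoform_abundances,
    post_decay_proportions,
    simulate_reads,
    solve_retention_for_fold,
    spanning_start_count,
)

CANONICAL_SIGNALS = ("GTATGT", "TACTAAC")


def _iso(p, target):
    return IsoformModel(
        isoform_id="x", gene_id="g", kind="alt", mrna="A" * 100,
        kept_local=[(1, 100)], junction_local=None, pre_decay=p,
        nmd_target=target,
    )


# -- decay arithmetic --------------------------------------------------------

def test_retention_one_means_no_decay():
    isoforms = [_iso(0.5, False), _iso(0.5, True)]
    assert np.allclose(
        isoform_abundances(isoforms, nmd_active=True, retention=1.0),
        isoform_abundances(isoforms, nmd_active=False, retention=1.0),
    )


def test_half_half_with_r_fifth_renormalizes():
    isoforms = [_iso(0.5, False), _iso(0.5, True)]
    got = isoform_abundances(isoforms, nmd_active=True, retention=0.2)
    assert np.allclose(got, [0.5 / 0.6, 0.1 / 0.6])
    assert np.allclose(got, [0.8333, 0.1667], atol=1e-4)


def test_three_isoform_decay_example():
    isoforms = [_iso(0.6, False), _iso(0.2, True), _iso(0.2, True)]
    got = isoform_abundances(isoforms, nmd_active=True, retention=0.5)
    assert np.allclose(got, [0.75, 0.125, 0.125])


def test_nmd_deficient_returns_pre_decay_unchanged():
    isoforms = [_iso(0.6, False), _iso(0.4, True)]
    got = isoform_abundances(isoforms, nmd_active=False, retention=0.1)
    assert np.allclose(got, [0.6, 0.4])


# -- genome construction -----------------------------------------------------

def test_same_seed_gives_byte_identical_genome(tmp_path):
    config = SimConfig(n_genes=5, seed=123)
    a, b = build_toy_genome(config), build_toy_genome(config)
    pa, pb = tmp_path / "a.fa", tmp_path / "b.fa"
    write_genome(a.genome, pa)
    write_genome(b.genome, pb)
    assert pa.read_bytes() == pb.read_bytes()
    assert not a.registry.empty
    assert a.registry.equals(b.registry)


def test_planted_sites_and_signals(small_sim):
    scenario, _ = small_sim
    chrom = scenario.genome[scenario.config.chrom_id]
    for gene in scenario.genes.values():
        (intron,) = gene.introns
        s, e = intron
        if gene.strand == "+":
            donor = chrom.fetch(s, s + 5)
            acceptor = chrom.fetch(e - 2, e)
            body = chrom.fetch(s, e)
        else:
            from cryptosplice.io_formats import revcomp

            donor = revcomp(chrom.fetch(e - 5, e))
            acceptor = revcomp(chrom.fetch(s, s + 2))
            body = revcomp(chrom.fetch(s, e))
        assert donor == "GTATGT"
        assert acceptor == "TAG"
        assert "TACTAAC" in body
    # registry PTC flags: frameshifted events that stop early are targets
    assert set(scenario.registry.columns) >= {
        "gene_id", "kind", "offset", "frameshift", "ptc", "nmd_target",
        "intron_start", "intron_end",
    }


def test_zero_alt_events_config():
    config = SimConfig(
        n_genes=3, geometries=((),), p_canonical=0.85, p_alt_total=0.0,
        p_unspliced=0.15, seed=9,
    )
    scenario = build_toy_genome(config)
    assert scenario.registry.empty
    for gs in scenario.gene_scenarios.values():
        assert [iso.kind for iso in gs.isoforms] == ["canonical", "unspliced"]


@pytest.mark.parametrize(
    "kwargs",
    [
        dict(p_canonical=0.7, p_alt_total=0.2, p_unspliced=0.2),
        dict(nmd_retention=0.0),
        dict(nmd_retention=1.5),
        dict(library_size=0),
        dict(error_rate=1.0),
    ],
)
def test_invalid_configs_rejected(kwargs):
    with pytest.raises(ConfigError):
        SimConfig(**kwargs)


def test_colliding_offset_rejected():
    config = SimConfig(
        n_genes=1, geometries=((AltEventSpec("alt3", 500),),), seed=0
    )
    with pytest.raises(ConfigError, match="collides"):
        build_toy_genome(config)


# -- read sampling -----------------------------------------------------------

def test_proportions_sum_to_one_everywhere(small_sim):
    scenario, _ = small_sim
    frame = post_decay_proportions(scenario)
    sums = frame.groupby(["gene_id", "genotype"])["proportion"].sum()
    assert np.allclose(sums, 1.0)


def test_error_free_reads_match_isoform_sequence(small_sim):
    scenario, result = small_sim
    lib = result.libraries["WT"]
    for i in range(0, lib.n_reads, 97):
        iso = result.isoforms[lib.iso_index[i]]
        t0 = int(lib.start[i])
        assert lib.sequences[i] == iso.mrna[t0 - 1 : t0 + 74]


def test_junction_spanning_fraction_within_three_sigma():
    """Among canonical-isoform reads the junction-spanning fraction matches
    the exact enumeration (L−1 interior start positions) within 3σ."""
    config = SimConfig(
        n_genes=1, geometries=((),), p_canonical=0.9, p_alt_total=0.0,
        p_unspliced=0.1, library_size=30_000, error_rate=0.0, seed=5,
        genotypes=(("WT", True),),
    )
    scenario = build_toy_genome(config)
    result = simulate_reads(scenario, with_sequences=False)
    tf = result.truth_frame("WT")
    canon = tf[tf.isoform_id.str.endswith("canonical")]
    iso = next(
        i for i in result.isoforms if i.isoform_id.endswith("canonical")
    )
    L = config.read_len
    j = iso.junction_tx_pos
    f = spanning_start_count(j, iso.length, L) / (iso.length - L + 1)
    n = len(canon)
    obs = canon.spans_junction.mean()
    sigma = math.sqrt(f * (1 - f) / n)
    assert abs(obs - f) < 3 * sigma


def test_decay_model_read_counts_match_closed_form(small_sim):
    """Observed NMD-target junction reads in each genotype sit within 3σ of
    the closed-form expectation, so the deficient/competent ratio matches the
    decay model's prediction."""
    scenario, result = small_sim
    r = scenario.config.nmd_retention
    for genotype, nmd_active in scenario.config.genotypes:
        share = expected_event_share(scenario, nmd_active, r, subset="ptc")
        tf = result.truth_frame(genotype)
        ptc_isoforms = {
            iso.isoform_id
            for iso in result.isoforms
            if iso.kind == "alt" and iso.nmd_target
        }
        obs = int(
            (tf.spans_junction & tf.isoform_id.isin(ptc_isoforms)).sum()
        )
        n = len(tf)
        sigma = math.sqrt(n * share * (1 - share))
        assert abs(obs - n * share) < 3 * sigma, genotype


def test_solved_retention_hits_target_fold():
    config = SimConfig(n_genes=12, seed=31)
    scenario = build_toy_genome(config)
    r = solve_retention_for_fold(scenario, target_fold=1.7, subset="ptc")
    assert 0 < r < 1
    assert expected_aggregate_fold(scenario, r, subset="ptc") == pytest.approx(1.7)
    assert expected_aggregate_fold(scenario, 1.0, subset="ptc") == pytest.approx(1.0)


def test_truth_alignments_consistent_with_registry(small_sim):
    scenario, result = small_sim
    planted = {
        (r.intron_start, r.intron_end) for r in scenario.registry.itertuples()
    }
    annotated = {iv for g in scenario.genes.values() for iv in g.introns}
    for aln in result.truth_alignments("upf2"):
        if aln.has_gap:
            assert aln.gap_interval in planted | annotated
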