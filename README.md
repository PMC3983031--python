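# cryptosplice

Discovery and quantification of **non-productive alternative splicing** in
budding yeast from short-read RNA-seq, with classification of splice products
as substrates of **nonsense-mediated mRNA decay (NMD)**.

*Saccharomyces cerevisiae* has ~300 intron-containing genes (ICGs), and many
of them splice not only at their annotated sites but also at nearby cryptic
5′ and 3′ splice sites. Most of these alternative events insert a premature
termination codon (PTC) — either directly, by retaining intronic sequence
that contains an in-frame stop, or by shifting the reading frame — so the
resulting transcripts are destroyed by NMD and are essentially invisible in
wild-type cells. They surface only when NMD is inactivated (*upf1Δ*,
*upf2Δ*, *upf3Δ*). This package implements the computational side of that
experiment for users who want to detect such events, classify their protein
consequences, and test their enrichment upon NMD inactivation — plus a fully
ground-truthed simulator to validate every stage.

## What it computes

- **Two-step read mapping** (toy scale, exhaustive): 75-nt single-end reads
  are first placed ungapped with ≤ 4 mismatches; only reads that fail are
  re-aligned with one gap of 10–20000 nt (the intron) and ≤ 3 mismatches,
  with ≥ 12 nt anchors. A read is kept iff its best score occurs at ≤ 2
  genomic locations. For real data, externally produced SAM is ingested
  instead.
- **Junction discovery**: gapped alignments collapse into junctions; a
  junction is *annotated* iff it exactly matches an annotated intron,
  *alternative* if it lies inside an ICG without matching, and labeled
  `outside_icg` otherwise.
- **PTC classification**: each alternative event is substituted for the one
  annotated intron it overlaps in the otherwise-canonical transcript; the
  product is translated from the annotated start. A first in-frame stop
  strictly upstream of the canonical stop's mapped position is a PTC;
  `is_frameshift ⇔ Δℓ mod 3 ≠ 0` where Δℓ is the excision-length change.
  Protein consequences are reported as substitutions, Δn deletions,
  insertions or truncations.
- **Enrichment statistics**: counts are depth-normalized by total mapped
  reads; for each unit the mutant/WT fold is tested with a Poisson upper
  tail, p = P(X ≥ k), X ~ Poisson(λ), λ = depth-scaled WT count. RPKM,
  per-gene unspliced (intronic + exon–intron boundary) counts, and
  abundance-stratified medians round out the comparisons.
- **Splice-site consensus**: position-frequency matrices and per-position
  information content IC_j = 2 + Σ_b f_bj log₂ f_bj bits for canonical vs.
  alternative 5′/3′ sites.
- **Simulator**: a toy genome with canonical signals (GUAUGU donor,
  UACUAAC branchpoint, YAG acceptor) and planted degenerate alternative
  sites (e.g. the GUUUGU class of cryptic donors). Isoform mixes decay under
  a single retention factor *r*: in NMD-competent cells every NMD-target
  isoform keeps a fraction *r* of its pre-decay abundance, then per-gene
  proportions renormalize; NMD-deficient genotypes sample pre-decay
  proportions unchanged. Closed-form expectations for event read shares and
  aggregate folds are provided, including a solver that picks *r* to hit a
  target fold.

## Worked example

Simulate a 20-ICG study in four genotypes with the retention factor solved
so the expected depth-adjusted enrichment of PTC-generating events is
1.7-fold, then run the discovery pipeline and measure it:

```python
from dataclasses import replace
from cryptosplice.synthetic_data import (SimConfig, build_toy_genome,
    simulate_reads, solve_retention_for_fold)
from cryptosplice.junction_discovery import extract_junctions, classify_events
from cryptosplice.ptc_classification import build_splice_product, call_ptc
from cryptosplice.quantification_stats import event_count_matrix, enrichment_table

config = SimConfig(n_genes=20, library_size=50_000, seed=1)
scenario = build_toy_genome(config)
r = solve_retention_for_fold(scenario, target_fold=1.7, subset="ptc")
scenario.config = replace(config, nmd_retention=r)
print(f"retention factor r = {r:.3f}")

result = simulate_reads(scenario, with_sequences=False)
streams = {g: result.truth_alignments(g) for g, _ in config.genotypes}
junctions = classify_events(extract_junctions(streams),
                            scenario.genes, scenario.genome)
for j in junctions:
    if j.status == "alternative":
        gene = scenario.genes[j.gene_id]
        j.is_ptc = call_ptc(build_splice_product(gene, j, scenario.genome),
                            gene).is_ptc

samples = [g for g, _ in config.genotypes]
totals = {g: result.libraries[g].n_reads for g in samples}
counts = event_count_matrix(junctions, samples, status="alternative",
                            ptc_only=True)
_, agg = enrichment_table(counts, totals, wt="WT")
for row in agg.itertuples():
    print(f"{row.sample_id}: PTC-event fold = {row.fold:.2f}  "
          f"(p = {row.pvalue:.2e})")
```

Output:

```
retention factor r = 0.484
upf1: PTC-event fold = 1.64  (p = 7.65e-57)
upf2: PTC-event fold = 1.64  (p = 1.05e-57)
upf3: PTC-event fold = 1.75  (p = 1.32e-75)
```

With only ~48% of each PTC isoform surviving decay in wild-type, the three
NMD-deficient libraries show the expected ≈1.7-fold excess of PTC-generating
junction reads, and the Poisson tail under the wild-type rate rejects
equality decisively.

The same pipeline is available from the shell:

```bash
cryptosplice simulate --seed 1 --outdir sim/
cryptosplice align --genome sim/genome.fa --reads sim/reads_WT.fastq --out WT.sam
cryptosplice junctions --sam WT=WT.sam --sam upf1=upf1.sam \
    --gff sim/genes.gff3 --genome sim/genome.fa --out-prefix junctions
cryptosplice classify --events junctions.tsv --gff sim/genes.gff3 \
    --genome sim/genome.fa --out classified.tsv
cryptosplice stats --events classified.tsv \
    --totals '{"WT": 50000, "upf1": 50000}' --wt WT
cryptosplice logo --events junctions.tsv --genome sim/genome.fa --out pfm.tsv
```

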