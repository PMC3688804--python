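# uceflow

**Ultraconserved-element target-enrichment phylogenomics, end to end.**

Sequence capture of ultraconserved elements (UCEs) and their variable
flanking regions is a workhorse strategy for collecting hundreds of
orthologous nuclear loci across deep evolutionary timescales — in fishes,
birds, mammals and beyond. `uceflow` implements the informatic arc of such
a study as a tested, reusable toolkit for phylogeneticists:

1. **Discovery** — scan pairwise genome alignments for perfectly conserved
   runs strictly longer than 80 bp, buffer them to 180 bp with flanking
   sequence, validate each buffered locus by realignment against every
   genome in the comparison set (exactly one match with span ≥ 120 bp and
   identity ≥ 80%), and keep only loci separated by more than 10 kbp.
2. **Probe design** — tile 120-bp capture probes at 4× density across each
   locus (offsets `round(i·(L−p)/(d−1))`), with composition QC.
3. **Contig matching** — align per-taxon assembled contigs to the probe set
   with a seeded gapped local aligner, then enforce one-to-one orthology by
   removing *non-reciprocal* duplicates (a contig matching several loci)
   and *reciprocal* duplicates (a locus matched by several contigs),
   recording everything in a relational match store. Genome-enabled taxa
   can be harvested directly from assemblies as outgroups.
4. **Matrix assembly** — select loci by taxon-count / required-taxon
   criteria, align each locus (MAFFT via a command hook, or the builtin
   progressive aligner), trim ragged alignment edges, drop excessively
   trimmed taxa, and concatenate into an incomplete supermatrix
   (relaxed PHYLIP, NEXUS with sets block, RAxML-style partition file).
5. **Model selection** — per-locus AICc over JC69/K80/HKY85/GTR (± Γ₄),
   AICc = −2 lnL + 2K + 2K(K+1)/(n−K−1), with Felsenstein-pruning
   likelihoods on a neighbor-joining guide tree; loci sharing a best model
   are grouped into partitions, loci too short to fit any candidate are
   set aside.
6. **Species tree** — STAR: each rooted gene tree contributes rank-based
   distances (root rank = n−1, decreasing by one per edge; d(a,b) =
   2·rank(MRCA)), averaged over the gene trees covering each pair, with
   neighbor joining on the averaged matrix. Node support comes from a
   two-stage multilocus bootstrap (resample loci with replacement, then
   sites within each drawn locus), and nodes below 50% support collapse.
7. **Enrichment statistics** — per-taxon on-target fractions
   (UCE contigs / assembled contigs; reads in UCE contigs / trimmed reads)
   and cross-taxon aggregates with 95% normal CIs, plus matrix bookkeeping.

A deterministic simulation module generates every input the pipeline
consumes — genome pairs with planted conserved elements, per-taxon contig
sets with engineered duplicates, multispecies-coalescent gene trees, and
model-based sequence evolution — so the entire toolkit is testable offline.

## Worked example

```python
>>> from uceflow import (SimSpec, simulate_genome_set, scan_conserved,
...                      buffer_element, validate_across_genomes,
...                      spacing_filter, SeededLocalMatcher, tile_loci)
>>> spec = SimSpec(rng_seed=101, genome_length=160_000, n_elements=5,
...                min_element_gap=15_000, background_divergence=0.15)
>>> sim = simulate_genome_set(spec, 3)
>>> elements = scan_conserved(sim["blocks"][0], 80)
>>> ga = sim["genomes"]["genome_a"]["chr1"]
>>> buffered = [buffer_element(e, ga, 180) for e in elements]
>>> loci = spacing_filter(validate_across_genomes(
...     buffered, sim["genomes"], SeededLocalMatcher()), 10_000)
>>> sum(l.status == "validated" for l in loci)
5
>>> probes = tile_loci({l.id: l.element.buffered_seq for l in loci})
>>> len(probes), sorted({p.offset for p in probes})
(20, [0, 20, 40, 60])
```

Five planted conserved elements are recovered as five validated loci, and
4× tiling yields four staggered 120-bp probes per 180-bp locus — the same
geometry that puts 2,000 probes on 500 loci in a full design.

The enrichment-statistics layer reproduces the familiar study summary from
the packaged per-taxon table:

```python
>>> from uceflow import load_table1_fixture, aggregate, format_aggregate
>>> from uceflow.enrichment import table_rows
>>> agg = format_aggregate(aggregate(table_rows(load_table1_fixture())))
>>> agg["contigs_assembled"]["mean"], agg["uce_contigs"]["mean"]
(665.0, 332.0)
>>> agg["contigs_on_target"]["mean"], agg["reads_on_target"]["mean"]
(0.55, 0.32)
```

On average 665 contigs assemble per library, 332 of them match UCE loci;
55% of contigs and 32% of reads are on-target.

There is also a CLI, `uceflow`, with subcommands `discover`,
`design-probes`, `match`, `matrix`, `align`, `trim`, `concat`,
`model-select`, `partition`, `star`, `stats` and `simulate`.

## Layout

```
src/uceflow/
  config.py      pipeline thresholds (all published operating points)
  io.py          FASTA / MAF / BED / TSV readers and writers; packaged table
  discovery.py   conserved-element scan, buffering, validation, spacing
  probes.py      probe tiling and QC
  matching.py    seeded local aligner, duplicate filters, match store
  matrix.py      locus selection, alignment, edge trimming, concatenation
  models.py      NJ, pruning likelihood, AICc model selection, partitions
  startree.py    STAR distances, species tree, multilocus bootstrap
  enrichment.py  on-target statistics and aggregates
  simulate.py    deterministic generators for every pipeline input
  cli.py         the `uceflow` command
```

See `docs/methods.md` for the underlying models, parameter defaults, and
design decisions.
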