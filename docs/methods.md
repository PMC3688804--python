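# Methods

This note documents the models, algorithms, parameter defaults and design
decisions behind `uceflow`, and states what the synthetic fixtures do and
do not establish about behavior on real data.

## Coordinates, characters, conventions

All coordinates are 0-based half-open internally and in BED output; FASTA
headers that carry coordinates report 1-based inclusive. The gap character
is `-` inside locus alignments and `?` for missing taxa in supermatrices.
Ambiguity codes are IUPAC; `N` never counts as a match anywhere: it breaks
conserved runs in discovery, disqualifies probes in QC, is excluded from
k-mer seeds, and is treated as missing data in likelihoods and distances.

## Conserved-element discovery

A conserved core is a maximal run of alignment columns that are gap-free,
unambiguous, and identical between the two rows, with run length strictly
greater than `min_conserved_len` (default 80 bp — an 80-bp run fails; the
threshold is read literally as "greater than"). The scan is symmetric in
the two rows and reports reference coordinates.

Cores shorter than `buffer_len` (180 bp) are extended with flanking
sequence from the buffering genome, split as evenly as possible; an odd
leftover base goes to the 3′ side (an arbitrary but fixed choice). Cores
that cannot be fully buffered — within half a buffer of a sequence end —
are dropped rather than padded, so every probe-design target has uniform
length and real sequence.

Validation realigns each buffered locus against every genome in the
comparison set with the seeded local aligner. A locus is kept only when
*every* genome yields exactly one match with span ≥ `min_match_len`
(120 bp) and identity ≥ `min_identity` (0.80); two or more qualifying
matches anywhere mark the locus a duplicate. Finally a greedy left-to-right
sweep per genome (ordered by start; ties broken by longer core, then id)
drops any locus whose edge-to-edge gap to the previously retained one is
≤ `min_spacing` (10 kbp). Retained loci therefore satisfy the spacing
constraint in every genome, and the sweep is deterministic and idempotent.
Which of two close loci to keep is not dictated by the biology; the greedy
first-come rule is a documented convention.

## Probe tiling

`density` probes of `probe_len` (120 bp) are placed at offsets
`round(i·(L−p)/(density−1))`, `i = 0..density−1`, duplicate offsets
collapsed. For the default 180-bp locus at 4× this gives offsets
0/20/40/60, so the central third of the locus is covered by all four
probes. The per-locus probe count is the only geometry consistent with a
2,000-probe set over 500 loci at 4× tiling. QC rejects probes containing
any `N` and probes with more than 25% soft-masked (lowercase) sequence;
both thresholds are toolkit defaults, configurable.

## Local matching (LASTZ stand-in)

The seeded aligner indexes the target's 20-mers, clusters seed hits closer
than one query length into candidate windows, and runs an exact
Smith–Waterman-style local alignment (via Bio.Align.PairwiseAligner) of
the query against each window, on both strands. Scoring defaults: match
+1, mismatch −1, gap open −4, gap extend −1 (the opening gap character
scores −4, each further one −1). Identity is identities over alignment
columns (gaps included); span is alignment columns. Overlapping hits merge
keeping the best score, so one genomic site yields one hit while a tandem
duplication yields two. A query sharing no 20-mer with the target never
matches — by construction the heuristic can miss weak similarity that full
DP would find, but on test pairs with a planted seed it equals the
exhaustive optimum. The original study used LASTZ; its scoring parameters
are not recoverable, so these defaults are the toolkit's own, overridable.

## Duplicate removal

Matching one taxon's contigs to the probe set (any probe of a locus
counts for that locus) enforces one-to-one orthology in two stages:
contigs matching ≥ 2 loci are removed first (non-reciprocal duplicates),
leaving their loci available to other contigs; loci then matched by ≥ 2
surviving contigs are removed entirely (reciprocal duplicates). The
result is independent of contig input order. Kept sequences are
orientation-normalized to the probe strand. Contig-level acceptance
thresholds are not published for the original pipeline; the defaults
mirror the discovery thresholds (span ≥ 120 bp, identity ≥ 0.80). Genome
harvesting applies the same rules to probe hits merged into genomic sites
and slices the matched span ± 500 bp (configurable; flagged when clipped
at a sequence end).

## Alignment and trimming

Per-locus alignment is delegated to an external command template (MAFFT
by default) or to the builtin progressive aligner: UPGMA guide tree on
6-mer profile distances, then profile–profile global alignment with
affine gaps (Gotoh), sum-of-pairs column scoring. On two sequences the
builtin path equals the exact affine Needleman–Wunsch optimum. The
builtin aligner exists so the full pipeline runs with no external binary;
it is not a MAFFT re-implementation and makes no accuracy claims beyond
the tested properties.

Edge trimming scans inward from each edge until `window` (20) consecutive
columns each have occupancy ≥ 0.5 and column identity ≥ 0.65 (identity =
modal-residue fraction among non-gap residues; 1.0 when ≤ 1 residue).
Taxa left with fewer residues than 0.25 × the trimmed length are dropped,
and all-gap columns purged. The published workflow trims edges and drops
"excessively trimmed" taxa without stating thresholds; these four numbers
are documented stand-ins, all configurable, chosen to reproduce the
behavior class (ragged edges removed, sparse taxa dropped). Trimming is
idempotent and never increases any row's residue count. A locus trimmed
to nothing (or below two taxa) raises an empty-alignment signal and is
dropped with a log entry.

Concatenation fills missing taxa with `?`, emits relaxed PHYLIP, NEXUS
(data + sets blocks) and RAxML-style partition files, and records locus
ranges so the supermatrix splits back into its loci column-for-column.

## Substitution models and AICc

Candidates are JC69, K80, HKY85 and GTR, each ± 4-category discrete-gamma
rate variation — 8 models. (+I variants are deliberately omitted: the
proportion-invariant and gamma-shape parameters are notoriously
confounded, and the 8-model set spans the same nesting chain.) Base
frequencies for HKY85/GTR are empirical counts, counted as free
parameters in K (the MrAIC convention): K = substitution parameters
(JC 0, K80 1, HKY85 4, GTR 8, +1 for Γ) + (2T−3) branch lengths; n is
alignment columns. AICc = −2 lnL + 2K + 2K(K+1)/(n−K−1). When no
candidate satisfies n − K − 1 > 0 the locus is reported `too_short` and
excluded from partitioning — the behavior class that removed two short
loci from the original 491.

Likelihoods use Felsenstein pruning over site patterns (gaps/ambiguities
contribute partial likelihood 1), with transition matrices from the
eigendecomposition of the π-symmetrized rate matrix, normalized to one
expected substitution per unit time. Γ₄ uses equal-probability categories
with mean category rates. The guide tree is neighbor joining on
Jukes–Cantor distances (saturated pairs capped just below p = 0.75) and
its topology stays fixed during fitting — the goal is model choice, not
tree search. Branch lengths are optimized by bounded per-branch Brent
search (bounds 1e-8..10, tolerance 3e-4) and substitution parameters by
Nelder–Mead in log space; +Γ variants warm-start from the corresponding
plain model's fit. These tolerances give lnL stable to well under the
AICc differences that separate neighboring models in the candidate set.

Loci sharing a best model form one partition, named deterministically
from the model (`p_GTR_G` etc.). Downstream concatenated ML/Bayesian
inference (RAxML, MrBayes) is out of scope: the toolkit writes their
inputs.

## STAR species trees and the multilocus bootstrap

For each rooted gene tree with n leaves, the root has rank n−1 and ranks
decrease by one per edge toward the leaves; the distance between two taxa
is twice the rank of their MRCA. Matrix entries average over the gene
trees containing both taxa, so loci may cover different taxon subsets; a
pair covered by no tree is a hard error (imputation would silently bias
the matrix). The species tree is neighbor joining on this matrix, rooted
at a user-declared outgroup. With unanimous gene trees STAR returns the
common topology; under the multispecies coalescent the rank distances are
consistent estimates of relative divergence order.

Support comes from the two-stage nonparametric bootstrap: each replicate
draws L loci with replacement, resamples columns with replacement within
each drawn locus, re-estimates every gene tree, and re-runs STAR.
The internal gene-tree estimator is neighbor joining on the locus's
best-model pairwise ML distances (closed form for JC; otherwise a
two-taxon pruning-likelihood optimization) — the original study used
PhyML, an external ML engine, so this estimator is a documented
substitution with the same interface. Whether the original bootstrap
re-selected models per replicate is unstated; the toolkit reuses each
locus's original best model. Replicates that leave some taxon pair
uncovered are redrawn with bounded retries. Support is the fraction of
replicates containing each bipartition; nodes below the collapse
threshold (default 0.50) become polytomies.

## Enrichment statistics

Per taxon: contigs on target = UCE contigs / assembled contigs; reads on
target = reads in UCE contigs / trimmed reads. Aggregates report mean,
95% CI half-width (1.96·s/√n with sample standard deviation), min and
max per column. All arithmetic is full precision; rounding (half away
from zero; integers for counts and coverage, two decimals for fractions)
happens only at the reporting layer — this reproduces every published
aggregate of the 17-taxon table exactly. The packaged table's "average
coverage" column is used as printed: the original read-length accounting
behind it is not recoverable from published information. The published
overall means of ~2.82 M reads and 457 bp per contig are *not*
reproducible from the 17 printed rows (they presumably reflect an
additional unprinted library) and are therefore not targets of any check
here.

## Synthetic fixtures: what they show and what they do not

The generators are fully seed-deterministic, and each simulation stage
draws from an independent random stream (genome, extra genomes, contigs),
so no fixture can accidentally replay another's draws.

* **Genome pairs** plant identical elements into i.i.d.-substitution
  backgrounds (default 15% divergence, no indels). Because coordinates
  are preserved, the true alignment is known without running an aligner,
  and the base flanking each core is forced to mismatch so planted core
  coordinates are exact. Consequence: discovery tests exercise the scan,
  buffering, validation and spacing logic — not whole-genome alignment,
  indel handling, or repeat structure.
* **Contig sets** embed mutated locus copies (taxon-specific rates,
  default 1–4%) in random flanks on random strands, plus background
  contigs and engineered duplicate copies. Read simulation and assembly
  are deliberately skipped — assembly is out of scope — so these tests
  say nothing about assembler artifacts (chimeras, collapsed repeats)
  beyond the duplicate classes modeled.
* **MSC gene trees** sample one lineage per species tip and exponential
  coalescence within species-tree branches (coalescent units; the
  species tree must be ultrametric). The 3-taxon gene-tree probability
  1 − (2/3)e^(−T) is verified against simulation within Monte Carlo
  error, which calibrates the generator independently of STAR.
* **Sequence evolution** samples states down the tree under the named
  model, with per-site Γ rates drawn once and shared across branches.

Passing the recovery suites therefore demonstrates correctness of the
implemented algorithms under their stated models — not robustness to
alignment error, indels, assembly artifacts, or model misspecification in
real capture data.

## Problem sizes in the test and acceptance suites

The statistical-recovery suites use 5–6 planted elements in 150–160 kb
genomes, 4 taxa × ~20 contigs for duplicate filtering, 50 seeded
2,000-site six-taxon replicates per generating model for AICc recovery,
20 trials × 200 gene trees for STAR recovery, and 2,000 gene trees for
the MSC calibration — sizes chosen so each suite finishes in minutes on a
single core while leaving the Monte Carlo margins (≥ 90%, ≥ 95%, 3 s.e.)
comfortably testable. The acceptance script uses 25 replicates per model
for the AICc summary at the same per-replicate sizes.

## Known limitations

* The local matcher's 20-mer seeding can miss homologs diverged beyond
  ~15–20% or hit regions shorter than the seed; LASTZ's transition seeds
  are more sensitive.
* The builtin progressive aligner has no iterative refinement; for
  production alignments use the MAFFT hook.
* Branch lengths from the NJ + per-branch optimization are adequate for
  model selection, not a substitute for full ML tree inference.
* STAR here uses NJ on rank distances; pseudo-likelihood methods
  (MP-EST, ASTRAL) and distributed execution are out of scope.
* The multilocus bootstrap re-estimates gene trees with the internal NJ
  estimator, which underestimates gene-tree uncertainty relative to the
  ML estimators used in the original workflow.
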