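"""Deterministic generators for every input the pipeline consumes.

The generators emulate the workflow's real inputs at the points where the
pipeline picks them up: genome pairs with planted, perfectly conserved
elements standing in for the stickleback-medaka comparison; per-taxon
contig sets standing in for de-novo assemblies of enriched reads; and
multispecies-coalescent gene trees with model-based sequence evolution for
the species-tree and model-selection machinery.  Read simulation and
assembly are deliberately skipped — contigs are drawn directly — so
assembler behavior is outside what these fixtures can exercise.

Background divergence is i.i.d. substitution only (no indels), which keeps
the true pairwise alignment trivially known; the base flanking each planted
element is forced to differ so the conserved core's coordinates are exact
rather than extended by chance flank matches.  Every generator is fully
determined by its seed and emits a machine-readable truth record.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import AlignmentBlock, FastaRecord
from .matching import revcomp
from .models import gamma_category_rates, rate_matrix
from .trees import Node

_NUC = np.array(list("ACGT"))


class SimulationError(ValueError):
    pass


def _stream(seed: int, key: int) -> np.random.Generator:
    """Independent generator per simulation stage.

    The genome, extra-genome and contig generators must never share a raw
    random stream: a shared stream would let a "background" contig replay
    the very draws that produced a planted element, creating spurious
    sequence identity between supposedly unrelated fixtures.
    """
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(key,)))


@dataclass
class SimSpec:
    rng_seed: int = 0
    genome_length: int = 200_000
    n_elements: int = 5
    element_len_range: tuple[int, int] = (120, 200)
    min_element_gap: int = 20_000
    background_divergence: float = 0.15
    n_taxa: int = 8
    n_background_contigs: int = 10
    duplicate_rate: float = 0.0
    locus_prob: float = 1.0
    taxon_divergence_range: tuple[float, float] = (0.01, 0.04)
    species_tree: str = ""
    sites_per_locus: int = 500

    def __post_init__(self) -> None:
        if not 0 <= self.background_divergence < 0.75:
            raise SimulationError("background divergence must be in [0, 0.75)")


def _random_genome(rng: np.random.Generator, length: int) -> np.ndarray:
    return rng.integers(0, 4, size=length, dtype=np.int8)


def _mutate(rng: np.random.Generator, seq: np.ndarray, rate: float,
            protect: np.ndarray | None = None) -> np.ndarray:
    """Substitute each position with probability ``rate`` (never to itself)."""
    out = seq.copy()
    hit = rng.random(len(seq)) < rate
    if protect is not None:
        hit &= ~protect
    idx = np.nonzero(hit)[0]
    out[idx] = (out[idx] + rng.integers(1, 4, size=len(idx))) % 4
    return out


def _to_str(arr: np.ndarray) -> str:
    return "".join(_NUC[arr])


def _place_elements(rng: np.random.Generator, spec: SimSpec
                    ) -> list[tuple[int, int]]:
    lengths = rng.integers(spec.element_len_range[0],
                           spec.element_len_range[1] + 1,
                           size=spec.n_elements)
    # margin keeps elements buffer-able and clear of sequence ends
    margin = 200
    needed = int(lengths.sum()) + (spec.n_elements - 1) * (
        spec.min_element_gap + 1) + 2 * margin
    slack = spec.genome_length - needed
    if slack < 0:
        raise SimulationError(
            f"{spec.n_elements} elements do not fit in "
            f"{spec.genome_length} bp with gap {spec.min_element_gap}")
    extra = np.sort(rng.integers(0, slack + 1, size=spec.n_elements))
    placements = []
    pos = margin
    prev_extra = 0
    for i, length in enumerate(lengths):
        pos += int(extra[i] - prev_extra)
        prev_extra = int(extra[i])
        placements.append((pos, pos + int(length)))
        pos += int(length) + spec.min_element_gap + 1
    return placements


def simulate_genome_pair(spec: SimSpec) -> dict:
    """Two genomes with identical planted elements in diverged background.

    Returns a dict with ``genome_a``/``genome_b`` ({chrom: sequence}),
    ``truth`` (list of (chrom, start, end, name) core intervals, identical
    coordinates in both genomes), and ``blocks`` (the true pairwise
    alignment as :class:`AlignmentBlock` objects).
    """
    rng = _stream(spec.rng_seed, 0)
    a = _random_genome(rng, spec.genome_length)
    placements = _place_elements(rng, spec) if spec.n_elements else []
    protect = np.zeros(spec.genome_length, dtype=bool)
    for start, end in placements:
        protect[start:end] = True
    b = _mutate(rng, a, spec.background_divergence, protect=protect)
    if spec.background_divergence > 0:
        for start, end in placements:
            # force a mismatch flanking each core so truth coordinates are exact
            for pos in (start - 1, end):
                if 0 <= pos < spec.genome_length:
                    b[pos] = (a[pos] + rng.integers(1, 4)) % 4
    seq_a, seq_b = _to_str(a), _to_str(b)
    truth = [("chr1", start, end, f"uce{i}")
             for i, (start, end) in enumerate(placements)]
    block = AlignmentBlock("chr1", 0, seq_a, "chr1", 0, seq_b, "+")
    return {"genome_a": {"chr1": seq_a}, "genome_b": {"chr1": seq_b},
            "truth": truth, "blocks": [block]}


def simulate_genome_set(spec: SimSpec, n_genomes: int) -> dict:
    """A pair plus extra diverged genomes, elements planted verbatim in all."""
    pair = simulate_genome_pair(spec)
    rng = _stream(spec.rng_seed, 1)
    a = np.array([_NUC.tolist().index(c) for c in pair["genome_a"]["chr1"]],
                 dtype=np.int8)
    protect = np.zeros(len(a), dtype=bool)
    for _, start, end, _ in pair["truth"]:
        protect[start:end] = True
    genomes = {"genome_a": pair["genome_a"], "genome_b": pair["genome_b"]}
    for g in range(2, n_genomes):
        mutated = _mutate(rng, a, spec.background_divergence, protect=protect)
        genomes[f"genome_{chr(ord('a') + g)}"] = {"chr1": _to_str(mutated)}
    return {"genomes": genomes, "truth": pair["truth"],
            "blocks": pair["blocks"]}


def simulate_contigs(spec: SimSpec, loci: dict[str, str],
                     taxa: list[str] | None = None) -> dict:
    """Per-taxon contig sets containing mutated locus copies plus noise.

    Each taxon carries each locus with probability ``spec.locus_prob``,
    mutated at a taxon-specific substitution rate and embedded in random
    flanks, on a random strand.  Background contigs match nothing;
    engineered duplicates (rate ``spec.duplicate_rate``) plant a second
    copy of a locus, which the duplicate filter must remove.  Returns
    ``contigs`` ({taxon: [FastaRecord]}), ``truth`` ({taxon: {locus:
    contig_id}} restricted to loci the filter should keep) and
    ``duplicated`` ({taxon: [locus ids]}).
    """
    rng = _stream(spec.rng_seed, 2)
    if taxa is None:
        taxa = [f"taxon{i}" for i in range(spec.n_taxa)]
    contigs: dict[str, list[FastaRecord]] = {}
    truth: dict[str, dict[str, str]] = {}
    duplicated: dict[str, list[str]] = {}
    for taxon in taxa:
        rate = rng.uniform(*spec.taxon_divergence_range)
        records: list[FastaRecord] = []
        tmap: dict[str, str] = {}
        dups: list[str] = []
        counter = 0
        for locus_id in sorted(loci):
            if rng.random() > spec.locus_prob:
                continue
            n_copies = 2 if rng.random() < spec.duplicate_rate else 1
            for copy in range(n_copies):
                seq = np.array([_NUC.tolist().index(c)
                                for c in loci[locus_id].upper()], dtype=np.int8)
                mutated = _to_str(_mutate(rng, seq, rate))
                left = _to_str(_random_genome(rng, int(rng.integers(50, 150))))
                right = _to_str(_random_genome(rng, int(rng.integers(50, 150))))
                contig = left + mutated + right
                if rng.random() < 0.5:
                    contig = revcomp(contig)
                contig_id = f"{taxon}_c{counter}"
                counter += 1
                records.append(FastaRecord(contig_id, contig))
            if n_copies == 1:
                tmap[locus_id] = records[-1].id
            else:
                dups.append(locus_id)
        for _ in range(spec.n_background_contigs):
            records.append(FastaRecord(
                f"{taxon}_c{counter}",
                _to_str(_random_genome(rng, int(rng.integers(200, 500))))))
            counter += 1
        contigs[taxon] = records
        truth[taxon] = tmap
        duplicated[taxon] = dups
    return {"contigs": contigs, "truth": truth, "duplicated": duplicated}


# ---------------------------------------------------------------------------
# Multispecies coalescent


def _node_heights(tree: Node) -> dict[int, float]:
    """Heights above the tips; errors if the tree is not ultrametric."""
    heights: dict[int, float] = {}

    def walk(node: Node) -> float:
        if node.is_leaf:
            heights[id(node)] = 0.0
            return 0.0
        child_heights = [walk(c) + c.length for c in node.children]
        if max(child_heights) - min(child_heights) > 1e-6:
            raise SimulationError(
                "species tree is not ultrametric in coalescent units")
        h = float(np.mean(child_heights))
        heights[id(node)] = h
        return h

    walk(tree)
    return heights


def simulate_msc_gene_trees(species_tree: Node, n_trees: int,
                            seed: int) -> list[Node]:
    """Sample gene trees under the multispecies coalescent.

    Branch lengths of ``species_tree`` are in coalescent units; one lineage
    enters per species tip.  Within each branch, lineage pairs coalesce at
    rate k(k-1)/2; remaining lineages coalesce above the root.
    """
    heights = _node_heights(species_tree)
    rng = np.random.default_rng(seed)
    trees: list[Node] = []
    for _ in range(n_trees):
        trees.append(_one_msc_tree(species_tree, heights, rng))
    return trees


def _one_msc_tree(sp: Node, heights: dict[int, float],
                  rng: np.random.Generator) -> Node:
    # each lineage is tracked as (gene-tree node, height of its creation)
    def walk(species_node: Node, limit: float) -> list[tuple[Node, float]]:
        h = heights[id(species_node)]
        if species_node.is_leaf:
            incoming = [(Node(name=species_node.name), 0.0)]
        else:
            incoming = []
            for child in species_node.children:
                incoming.extend(walk(child, h))
        return _coalesce_interval(incoming, h, limit, rng)

    survivors = walk(sp, np.inf)
    (root, _) = survivors[0]
    return root


def _coalesce_interval(lineages: list[tuple[Node, float]], start: float,
                       limit: float, rng: np.random.Generator
                       ) -> list[tuple[Node, float]]:
    lineages = list(lineages)
    t = start
    while len(lineages) > 1:
        k = len(lineages)
        wait = rng.exponential(1.0 / (k * (k - 1) / 2.0))
        if t + wait > limit:
            break
        t += wait
        i, j = sorted(rng.choice(k, size=2, replace=False))
        node_j, h_j = lineages.pop(j)
        node_i, h_i = lineages.pop(i)
        node_i.length = t - h_i
        node_j.length = t - h_j
        lineages.append((Node(children=[node_i, node_j]), t))
    return lineages


# ---------------------------------------------------------------------------
# Sequence evolution on a tree


def simulate_sequences(tree: Node, model: str, n_sites: int, seed: int,
                       params: dict | None = None) -> dict[str, str]:
    """Evolve sequences down ``tree`` under a reversible model.

    With ``+G`` in the model name, per-site rates are drawn once from the
    4-category discrete gamma (shape ``params['alpha']``) and shared across
    the whole tree.
    """
    params = params or {}
    rng = np.random.default_rng(seed)
    Q, freqs = rate_matrix(model, params)
    if "+G" in model:
        cats = gamma_category_rates(float(params.get("alpha", 0.5)))
        site_rates = cats[rng.integers(0, len(cats), size=n_sites)]
    else:
        site_rates = np.ones(n_sites)

    from scipy.linalg import expm

    out: dict[str, str] = {}
    root_states = rng.choice(4, size=n_sites, p=freqs)

    def walk(node: Node, states: np.ndarray) -> None:
        if node is not tree:
            new_states = states.copy()
            for rate in np.unique(site_rates):
                mask = site_rates == rate
                P = expm(Q * node.length * rate)
                P = np.clip(P, 0, None)
                P /= P.sum(axis=1, keepdims=True)
                cum = np.cumsum(P, axis=1)
                u = rng.random(int(mask.sum()))
                rows = cum[states[mask]]
                new_states[mask] = (u[:, None] > rows).sum(axis=1)
            states = new_states
        if node.is_leaf:
            out[node.name] = _to_str(states.astype(np.int8))
        for child in node.children:
            walk(child, states)

    walk(tree, root_states)
    return out
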