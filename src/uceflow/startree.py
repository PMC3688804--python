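"""STAR species-tree estimation and the two-stage multilocus bootstrap.

STAR converts each rooted gene tree into rank-based pairwise distances —
the root of a tree with n leaves has rank n-1, ranks decrease by one per
edge toward the leaves, and the distance between two taxa is twice the rank
of their most recent common ancestor — averages the distances over the gene
trees covering each pair, and estimates the species tree by neighbor
joining.  Gene trees may cover different taxon subsets (averaging then runs
over covering trees only); a pair covered by no tree is a hard error.

Node support comes from a two-stage nonparametric bootstrap: each replicate
resamples loci with replacement, then resamples alignment columns within
each drawn locus, re-estimates every gene tree, and re-runs STAR.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .models import model_distance_matrix
from .trees import Node, nj_tree, root_at_outgroup


class CoverageError(ValueError):
    pass


@dataclass
class SpeciesTreeResult:
    tree: Node
    n_gene_trees: int
    bootstrap_reps: int = 0
    collapse_threshold: float = 0.0
    supports: dict[frozenset, float] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# STAR distances


def _pair_ranks(tree: Node) -> dict[tuple[str, str], int]:
    """MRCA rank for every leaf pair of one rooted gene tree."""
    n_leaves = len(tree.leaves())
    out: dict[tuple[str, str], int] = {}

    def walk(node: Node, depth: int) -> list[str]:
        if node.is_leaf:
            return [node.name]
        rank = (n_leaves - 1) - depth
        child_sets = [walk(c, depth + 1) for c in node.children]
        for i in range(len(child_sets)):
            for j in range(i + 1, len(child_sets)):
                for a in child_sets[i]:
                    for b in child_sets[j]:
                        key = (a, b) if a < b else (b, a)
                        out[key] = rank
        return [leaf for s in child_sets for leaf in s]

    walk(tree, 0)
    return out


def star_distance_matrix(gene_trees: list[Node]
                         ) -> tuple[list[str], np.ndarray]:
    """Average rank distance (2 x MRCA rank) over covering gene trees."""
    if not gene_trees:
        raise ValueError("need at least one gene tree")
    sums: dict[tuple[str, str], float] = {}
    counts: dict[tuple[str, str], int] = {}
    taxa: set[str] = set()
    for tree in gene_trees:
        taxa.update(tree.leaf_names())
        for pair, rank in _pair_ranks(tree).items():
            sums[pair] = sums.get(pair, 0.0) + 2.0 * rank
            counts[pair] = counts.get(pair, 0) + 1
    names = sorted(taxa)
    n = len(names)
    dist = np.zeros((n, n))
    uncovered: list[tuple[str, str]] = []
    for i in range(n):
        for j in range(i + 1, n):
            pair = (names[i], names[j])
            if pair not in counts:
                uncovered.append(pair)
                continue
            dist[i, j] = dist[j, i] = sums[pair] / counts[pair]
    if uncovered:
        raise CoverageError(
            f"taxon pairs covered by no gene tree: {uncovered}")
    return names, dist


def star_tree(gene_trees: list[Node], outgroup: str | None = None
              ) -> SpeciesTreeResult:
    """Neighbor joining on the STAR matrix, rooted at ``outgroup`` if given."""
    names, dist = star_distance_matrix(gene_trees)
    if len(names) < 3:
        raise ValueError("species tree needs >= 3 taxa")
    tree = nj_tree(names, dist)
    if outgroup is not None:
        tree = root_at_outgroup(tree, outgroup)
    return SpeciesTreeResult(tree=tree, n_gene_trees=len(gene_trees))


# ---------------------------------------------------------------------------
# Gene-tree estimation (internal stand-in for external ML estimators)


def estimate_gene_tree(aln: dict[str, str], model: str = "JC69",
                       params: dict | None = None) -> Node:
    """NJ gene tree on best-model pairwise distances."""
    names, dist = model_distance_matrix(aln, model, params)
    if len(names) < 3:
        raise ValueError("gene tree needs >= 3 taxa")
    return nj_tree(names, dist)


# ---------------------------------------------------------------------------
# Multilocus bootstrap


def _resample_columns(aln: dict[str, str], rng: np.random.Generator
                      ) -> dict[str, str]:
    length = len(next(iter(aln.values())))
    cols = rng.integers(0, length, size=length)
    return {t: "".join(s[c] for c in cols) for t, s in aln.items()}


def multilocus_bootstrap(loci_alignments: dict[str, dict[str, str]],
                         reps: int, seed: int,
                         models: dict[str, str] | None = None,
                         outgroup: str | None = None,
                         resample: bool = True,
                         max_retries: int = 20) -> list[Node]:
    """Two-stage bootstrap: loci with replacement, then sites within loci.

    Each replicate re-estimates every drawn gene tree (NJ on the locus's
    best-model distances; models default to JC69) and summarizes with STAR.
    ``resample=False`` is the degenerate identity mode: the original loci
    and columns are used as-is.  Replicates whose resampled data leave some
    taxon pair uncovered are redrawn, up to ``max_retries`` times.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    locus_ids = sorted(loci_alignments)
    models = models or {}
    rng = np.random.default_rng(seed)
    trees: list[Node] = []
    for _ in range(reps):
        for attempt in range(max_retries + 1):
            if resample:
                drawn = [locus_ids[i] for i in
                         rng.integers(0, len(locus_ids), size=len(locus_ids))]
            else:
                drawn = locus_ids
            gene_trees = []
            ok = True
            for locus_id in drawn:
                aln = loci_alignments[locus_id]
                if resample:
                    aln = _resample_columns(aln, rng)
                try:
                    gene_trees.append(
                        estimate_gene_tree(aln, models.get(locus_id, "JC69")))
                except ValueError:
                    ok = False
                    break
            if not ok:
                continue
            try:
                result = star_tree(gene_trees, outgroup=outgroup)
            except CoverageError:
                continue
            trees.append(result.tree)
            break
        else:
            raise CoverageError(
                f"could not draw a covered replicate in {max_retries} tries")
    return trees


# ---------------------------------------------------------------------------
# Support mapping and collapsing


def _splits(tree: Node) -> dict[frozenset, Node]:
    """Non-trivial unrooted splits, keyed by the side without the anchor leaf."""
    all_leaves = frozenset(tree.leaf_names())
    anchor = min(all_leaves)
    out: dict[frozenset, Node] = {}

    def walk(node: Node) -> frozenset:
        if node.is_leaf:
            return frozenset([node.name])
        below = frozenset().union(*(walk(c) for c in node.children))
        if 1 < len(below) < len(all_leaves) - 1:
            side = below if anchor not in below else all_leaves - below
            out[side] = node
        return below

    walk(tree)
    return out


def map_support_and_collapse(main: SpeciesTreeResult,
                             replicate_trees: list[Node],
                             threshold: float = 0.50) -> SpeciesTreeResult:
    """Bipartition-frequency supports; collapse nodes below ``threshold``.

    Every replicate must cover exactly the main tree's leaf set.
    """
    tree = main.tree.copy()
    leaf_set = frozenset(tree.leaf_names())
    for rep in replicate_trees:
        if frozenset(rep.leaf_names()) != leaf_set:
            raise ValueError("replicate tree leaf set differs from main tree")
    rep_splits = [set(_splits(rep)) for rep in replicate_trees]
    node_splits = _splits(tree)
    supports: dict[frozenset, float] = {}
    for side, node in node_splits.items():
        if replicate_trees:
            support = sum(side in s for s in rep_splits) / len(replicate_trees)
        else:
            support = 1.0
        node.support = support
        supports[side] = support
    _collapse_below(tree, threshold)
    return SpeciesTreeResult(tree=tree, n_gene_trees=main.n_gene_trees,
                             bootstrap_reps=len(replicate_trees),
                             collapse_threshold=threshold, supports=supports)


def _collapse_below(tree: Node, threshold: float) -> None:
    def walk(node: Node) -> None:
        new_children: list[Node] = []
        for child in node.children:
            walk(child)
            if (not child.is_leaf and child.support is not None
                    and child.support < threshold):
                new_children.extend(child.children)
            else:
                new_children.append(child)
        node.children = new_children

    walk(tree)


def support_table(result: SpeciesTreeResult) -> list[dict]:
    rows = []
    for side in sorted(result.supports, key=lambda s: (len(s), sorted(s))):
        rows.append({"bipartition": "|".join(sorted(side)),
                     "support": f"{result.supports[side]:.4f}"})
    return rows
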