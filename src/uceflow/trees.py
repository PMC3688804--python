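"""Lightweight rooted/unrooted trees and neighbor joining.

The in-package :class:`Node` carries exactly what likelihood evaluation and
distance-based estimation need (children, branch length, optional name and
support); conversion to and from dendropy covers everything else (newick
I/O, bipartitions, rerooting).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np


@dataclass
class Node:
    name: str | None = None
    length: float = 0.0
    children: list["Node"] = field(default_factory=list)
    support: float | None = None

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def postorder(self):
        for child in self.children:
            yield from child.postorder()
        yield self

    def leaves(self) -> list["Node"]:
        return [n for n in self.postorder() if n.is_leaf]

    def leaf_names(self) -> list[str]:
        return [n.name for n in self.leaves()]

    def copy(self) -> "Node":
        return Node(self.name, self.length,
                    [c.copy() for c in self.children], self.support)

    def to_newick(self, with_support: bool = False) -> str:
        return _newick(self, with_support) + ";"


def _newick(node: Node, with_support: bool) -> str:
    if node.is_leaf:
        return f"{node.name}:{node.length:.6g}"
    inner = ",".join(_newick(c, with_support) for c in node.children)
    label = ""
    if with_support and node.support is not None:
        label = f"{node.support:.3f}"
    elif node.name:
        label = node.name
    return f"({inner}){label}:{node.length:.6g}"


def from_newick(text: str) -> Node:
    tree = dendropy.Tree.get(data=text, schema="newick")
    return from_dendropy(tree)


def from_dendropy(tree: "dendropy.Tree") -> Node:
    def build(dnode) -> Node:
        name = dnode.taxon.label if dnode.taxon else (dnode.label or None)
        length = dnode.edge.length if dnode.edge.length is not None else 0.0
        return Node(name, float(length), [build(c) for c in dnode.child_nodes()])
    return build(tree.seed_node)


def to_dendropy(node: Node, taxon_namespace=None) -> "dendropy.Tree":
    tree = dendropy.Tree.get(data=node.to_newick(), schema="newick",
                             taxon_namespace=taxon_namespace)
    return tree


# ---------------------------------------------------------------------------
# Neighbor joining


class TreeError(ValueError):
    pass


def nj_tree(names: list[str], dist: np.ndarray) -> Node:
    """Standard neighbor joining with deterministic tie-breaking.

    Requires a symmetric non-negative matrix over >= 3 taxa.  Negative
    estimated branch lengths are clamped to zero.  The returned tree is
    unrooted, represented with a trifurcating root.  Ties in the Q
    criterion are broken by the lexicographically smallest joined pair.
    """
    dist = np.asarray(dist, dtype=float)
    n = len(names)
    if n < 3:
        raise TreeError("neighbor joining needs at least 3 taxa")
    if dist.shape != (n, n):
        raise TreeError("distance matrix shape does not match taxa")
    if (dist < 0).any():
        raise TreeError("negative distance entry")
    if not np.allclose(dist, dist.T, atol=1e-9):
        raise TreeError("distance matrix is not symmetric")

    nodes: dict[int, Node] = {i: Node(name=names[i]) for i in range(n)}
    labels: dict[int, str] = {i: names[i] for i in range(n)}
    d = {(i, j): dist[i, j] for i in range(n) for j in range(n) if i != j}
    active = list(range(n))
    next_id = n

    while len(active) > 3:
        m = len(active)
        r = {i: sum(d[(i, j)] for j in active if j != i) for i in active}
        best: tuple[float, str, str, int, int] | None = None
        for ai, i in enumerate(active):
            for j in active[ai + 1:]:
                q = (m - 2) * d[(i, j)] - r[i] - r[j]
                pair_key = tuple(sorted((labels[i], labels[j])))
                cand = (q, pair_key[0], pair_key[1], i, j)
                if best is None or cand[:3] < best[:3]:
                    best = cand
        _, _, _, i, j = best
        vi = 0.5 * d[(i, j)] + (r[i] - r[j]) / (2 * (m - 2))
        vj = d[(i, j)] - vi
        node_i, node_j = nodes.pop(i), nodes.pop(j)
        node_i.length = max(0.0, vi)
        node_j.length = max(0.0, vj)
        parent = Node(children=[node_i, node_j])
        nodes[next_id] = parent
        labels[next_id] = min(labels[i], labels[j])
        for k in active:
            if k in (i, j):
                continue
            dk = 0.5 * (d[(i, k)] + d[(j, k)] - d[(i, j)])
            d[(next_id, k)] = d[(k, next_id)] = max(0.0, dk)
        active = [k for k in active if k not in (i, j)] + [next_id]
        next_id += 1

    i, j, k = active
    li = 0.5 * (d[(i, j)] + d[(i, k)] - d[(j, k)])
    lj = 0.5 * (d[(i, j)] + d[(j, k)] - d[(i, k)])
    lk = 0.5 * (d[(i, k)] + d[(j, k)] - d[(i, j)])
    for idx, length in ((i, li), (j, lj), (k, lk)):
        nodes[idx].length = max(0.0, length)
    children = [nodes[idx] for idx in sorted(
        (i, j, k), key=lambda x: labels[x])]
    return Node(children=children)


def root_at_outgroup(tree: Node, outgroup: str) -> Node:
    """Root an unrooted tree on the edge leading to ``outgroup``."""
    d = to_dendropy(tree)
    og = d.find_node_with_taxon_label(outgroup)
    if og is None:
        raise TreeError(f"outgroup {outgroup!r} not in tree")
    half = (og.edge.length or 0.0) / 2.0
    d.reroot_at_edge(og.edge, length1=half, length2=half,
                     update_bipartitions=False)
    return from_dendropy(d)


def rooted_topology_key(node: Node) -> frozenset:
    """Rooted-topology fingerprint: the set of internal-node clades."""
    clades: set[frozenset] = set()

    def collect(n: Node) -> frozenset:
        if n.is_leaf:
            return frozenset([n.name])
        below = frozenset().union(*(collect(c) for c in n.children))
        clades.add(below)
        return below

    collect(node)
    return frozenset(clades)


def topology_key(node: Node) -> frozenset:
    """Unrooted-topology fingerprint: the set of non-trivial bipartitions."""
    all_leaves = frozenset(node.leaf_names())
    splits: set[frozenset] = set()

    def collect(n: Node) -> frozenset:
        if n.is_leaf:
            return frozenset([n.name])
        below = frozenset().union(*(collect(c) for c in n.children))
        if 1 < len(below) < len(all_leaves) - 1:
            splits.add(frozenset([below, all_leaves - below]))
        return below

    collect(node)
    return frozenset(splits)
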