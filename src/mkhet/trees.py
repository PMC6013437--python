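"""Tree utilities on top of dendropy: validation, pruning, indexed traversal.

The package uses :class:`dendropy.Tree` as its tree container (rooted, branch
lengths in Ma, polytomies allowed).  Computational code does not walk dendropy
node objects directly; it builds a :class:`TreeIndex` once — flat postorder
arrays of parents, children and edge lengths — and operates on that.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import dendropy
import numpy as np


class TreeValidationError(ValueError):
    pass


def normalize_label(label: str) -> str:
    """Canonical taxon label: underscores and spaces are interchangeable."""
    return label.replace("_", " ").strip()


def leaf_labels(tree: dendropy.Tree) -> list[str]:
    return [lf.taxon.label for lf in tree.leaf_node_iter()]


def validate_tree(tree: dendropy.Tree, require_lengths: bool = True) -> None:
    """Check rootedness conventions, non-negative lengths, unique tip labels."""
    labels = [normalize_label(l) for l in leaf_labels(tree)]
    seen: set[str] = set()
    dups = {l for l in labels if l in seen or seen.add(l)}
    if dups:
        raise TreeValidationError(f"duplicate tip labels: {sorted(dups)}")
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        el = node.edge.length
        if el is None:
            if require_lengths:
                raise TreeValidationError(
                    f"edge above {describe_node(node)!r} has no length; branch lengths in Ma are required"
                )
        elif el < 0:
            raise TreeValidationError(f"negative edge length {el} above {describe_node(node)!r}")


def describe_node(node: dendropy.Node) -> str:
    if node.taxon is not None:
        return node.taxon.label
    if node.label:
        return node.label
    return f"<internal node {id(node):x}>"


def node_by_label(tree: dendropy.Tree, label: str) -> dendropy.Node:
    """Find the internal node carrying ``label`` (clade anchor)."""
    for node in tree.preorder_node_iter():
        if node.label == label or (node.taxon is not None and node.taxon.label == label):
            return node
    raise KeyError(f"no node labelled {label!r} in tree")


def mrca(tree: dendropy.Tree, tip_labels: Iterable[str]) -> dendropy.Node:
    """Most recent common ancestor of the named tips (label-normalized)."""
    wanted = {normalize_label(l) for l in tip_labels}
    taxa = [
        lf.taxon
        for lf in tree.leaf_node_iter()
        if normalize_label(lf.taxon.label) in wanted
    ]
    found = {normalize_label(t.label) for t in taxa}
    if found != wanted:
        raise KeyError(f"tips not in tree: {sorted(wanted - found)}")
    node = tree.mrca(taxa=taxa)
    if node is None:
        raise KeyError(f"no MRCA found for {sorted(wanted)}")
    return node


def prune_to_taxa(tree: dendropy.Tree, taxa: Iterable[str]) -> dendropy.Tree:
    """Induced subtree on ``taxa``, rooted at their MRCA.

    Degree-2 nodes created by the pruning are suppressed with their edge
    lengths summed, so patristic distances among retained tips are preserved.
    """
    wanted = {normalize_label(t) for t in taxa}
    if len(wanted) < 2:
        raise ValueError("pruning requires at least 2 taxa")
    have = {normalize_label(l) for l in leaf_labels(tree)}
    unknown = wanted - have
    if unknown:
        raise KeyError(f"taxa not in tree: {sorted(unknown)}")
    sub = tree.clone(depth=1)
    keep = [
        lf.taxon
        for lf in sub.leaf_node_iter()
        if normalize_label(lf.taxon.label) in wanted
    ]
    sub.retain_taxa(keep, suppress_unifurcations=True)
    # Re-root at the MRCA: strip any remaining chain of single-child nodes
    # above it, accumulating nothing (lengths above the MRCA are irrelevant).
    root = sub.seed_node
    while len(root.child_nodes()) == 1:
        root = root.child_nodes()[0]
    if root is not sub.seed_node:
        root.parent_node = None
        sub.seed_node = root
    root.edge.length = None
    sub.update_bipartitions(suppress_unifurcations=True)
    return sub


def node_ages(tree: dendropy.Tree) -> dict[dendropy.Node, float]:
    """Age (Ma above the tips) of every node of an ultrametric tree."""
    ages: dict[dendropy.Node, float] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            ages[node] = 0.0
        else:
            ages[node] = max(
                ages[c] + (c.edge.length or 0.0) for c in node.child_nodes()
            )
    return ages


def is_ultrametric(tree: dendropy.Tree, tol: float = 1e-6) -> bool:
    depths: list[float] = []
    for lf in tree.leaf_node_iter():
        d = 0.0
        node = lf
        while node.parent_node is not None:
            d += node.edge.length or 0.0
            node = node.parent_node
        depths.append(d)
    return max(depths) - min(depths) <= tol


class TreeIndex:
    """Flat, postorder-indexed view of a rooted tree for fast traversals.

    Attributes
    ----------
    nodes:
        dendropy nodes in postorder (children always precede parents; the
        root is last).
    parent:
        parent index per node (-1 for the root).
    children:
        list of child index lists per node.
    edge_length:
        length of the edge above each node (nan for the root).
    tip_index:
        {normalized tip label: node index}.
    """

    def __init__(self, tree: dendropy.Tree, require_lengths: bool = True):
        validate_tree(tree, require_lengths=require_lengths)
        self.tree = tree
        self.nodes: list[dendropy.Node] = list(tree.postorder_node_iter())
        self.n = len(self.nodes)
        pos = {id(nd): i for i, nd in enumerate(self.nodes)}
        self.parent = np.full(self.n, -1, dtype=np.int64)
        self.children: list[list[int]] = [[] for _ in range(self.n)]
        self.edge_length = np.full(self.n, np.nan)
        self.is_tip = np.zeros(self.n, dtype=bool)
        self.tip_index: dict[str, int] = {}
        for i, nd in enumerate(self.nodes):
            if nd.parent_node is not None:
                p = pos[id(nd.parent_node)]
                self.parent[i] = p
                self.children[p].append(i)
                if nd.edge.length is not None:
                    self.edge_length[i] = nd.edge.length
            if nd.is_leaf():
                self.is_tip[i] = True
                self.tip_index[normalize_label(nd.taxon.label)] = i
        self.root = self.n - 1

    def tip_codes(self, column: dict[str, int], default: int | None = None) -> np.ndarray:
        """Map a {taxon: cell code} column onto tip indices.

        Every tip must be covered unless ``default`` (e.g. MISSING) is given.
        """
        from .characters import MISSING  # local import to avoid cycle

        norm = {normalize_label(k): v for k, v in column.items()}
        codes = np.full(self.n, -1, dtype=np.int8)
        absent = []
        for label, i in self.tip_index.items():
            if label in norm:
                codes[i] = norm[label]
            elif default is not None:
                codes[i] = default
            else:
                absent.append(label)
        if absent:
            raise KeyError(f"tips without a character cell: {sorted(absent)[:10]}")
        return codes

    def descendant_tip_labels(self) -> list[set[str]]:
        """Per node, the set of normalized labels of descendant tips."""
        out: list[set[str]] = [set() for _ in range(self.n)]
        for i in range(self.n):
            if self.is_tip[i]:
                out[i] = {normalize_label(self.nodes[i].taxon.label)}
            else:
                for c in self.children[i]:
                    out[i] |= out[c]
        return out


def validate_matrix_against_tree(matrix, tree: dendropy.Tree) -> None:
    """Check that matrix taxa and tree tips coincide (up to _/space)."""
    tips = {normalize_label(l) for l in leaf_labels(tree)}
    taxa = {normalize_label(t) for t in matrix.taxa}
    extra = sorted(taxa - tips)
    lacking = sorted(tips - taxa)
    if extra or lacking:
        raise TreeValidationError(
            f"matrix/tree taxon mismatch: {len(extra)} matrix taxa absent from tree "
            f"(e.g. {extra[:5]}), {len(lacking)} tips absent from matrix (e.g. {lacking[:5]})"
        )
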