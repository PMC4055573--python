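"""Rooted binary trees and topology combinatorics.

Trees are the common currency of the package: parental species trees carry
branch lengths in *coalescent units* (two lineages in one population coalesce
at rate 1 per unit), gene genealogies carry lengths in *expected substitutions
per site*.  Every :class:`RootedTree` is tagged with its unit so that the two
scales cannot be mixed silently.

The module provides newick I/O (delegated to dendropy), enumeration of all
rooted binary topologies on a label set, canonical topology keys (used for
deterministic state ordering in the HMM), congruence testing of a gene
genealogy against a parental tree, and the rooted-to-unrooted reduction used
to share branch-length parameters between states whose genealogies differ
only in root placement.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator

import dendropy

COALESCENT = "coalescent"
SUBSTITUTIONS = "substitutions"
_UNITS = (COALESCENT, SUBSTITUTIONS)


class TreeError(ValueError):
    """Base class for tree construction/validation errors."""


class NewickError(TreeError):
    """Malformed newick input."""


class NonBinaryError(TreeError):
    """A tree that is not strictly bifurcating where one is required."""


class TopologySizeError(TreeError):
    """Label set outside the supported enumeration range."""


class AlleleMappingError(TreeError):
    """An allele without a species assignment (or vice versa)."""


class UnitError(TreeError):
    """Branch lengths supplied on the wrong scale."""


class Node:
    """A tree node; ``length`` is the length of the edge to its parent."""

    __slots__ = ("label", "length", "children", "tag")

    def __init__(self, label=None, length=0.0, children=None, tag=None):
        self.label = label
        self.length = float(length)
        self.children = list(children) if children is not None else []
        self.tag = tag

    def is_leaf(self) -> bool:
        return not self.children

    def copy(self) -> "Node":
        return Node(self.label, self.length,
                    [c.copy() for c in self.children], self.tag)

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"Node({self.label!r}, {self.length})"


def _postorder(node: Node) -> Iterator[Node]:
    for child in node.children:
        yield from _postorder(child)
    yield node


def _preorder(node: Node) -> Iterator[Node]:
    yield node
    for child in node.children:
        yield from _preorder(child)


@dataclass
class RootedTree:
    """A rooted tree with branch lengths and a unit tag."""

    root: Node
    unit: str

    def __post_init__(self):
        if self.unit not in _UNITS:
            raise UnitError(f"unit must be one of {_UNITS}, got {self.unit!r}")
        labels = self.leaf_labels()
        if len(labels) != len(set(labels)):
            raise TreeError("leaf labels are not unique")
        for node in self.postorder():
            if node.length < 0:
                raise TreeError(f"negative branch length {node.length} "
                                f"above node {node.label!r}")
            if node.is_leaf() and node.label is None:
                raise TreeError("leaf without a label")

    # -- traversal -----------------------------------------------------
    def postorder(self) -> Iterator[Node]:
        return _postorder(self.root)

    def preorder(self) -> Iterator[Node]:
        return _preorder(self.root)

    def leaves(self) -> list[Node]:
        return [n for n in self.postorder() if n.is_leaf()]

    def leaf_labels(self) -> list[str]:
        return [n.label for n in self.leaves()]

    @property
    def n_leaves(self) -> int:
        return len(self.leaves())

    def is_binary(self) -> bool:
        return all(len(n.children) in (0, 2) for n in self.postorder())

    def copy(self) -> "RootedTree":
        return RootedTree(self.root.copy(), self.unit)

    # -- serialisation -------------------------------------------------
    def newick(self, lengths: bool = True) -> str:
        def fmt(node: Node) -> str:
            if node.is_leaf():
                core = node.label
            else:
                core = "(" + ",".join(fmt(c) for c in node.children) + ")"
                if node.label:
                    core += node.label
            if lengths:
                core += f":{node.length!r}"
            return core

        # the root itself carries no meaningful edge; omit its length
        root = self.root
        if root.is_leaf():
            return f"{root.label};"
        return "(" + ",".join(fmt(c) for c in root.children) + ");"

    def topology_key(self) -> str:
        """Canonical, length-free newick string identifying the topology."""
        def key(node: Node) -> str:
            if node.is_leaf():
                return node.label
            return "(" + ",".join(sorted(key(c) for c in node.children)) + ")"
        return key(self.root)

    def canonicalize(self) -> "RootedTree":
        """Return a copy with children sorted into canonical order."""
        tree = self.copy()

        def key(node: Node) -> str:
            if node.is_leaf():
                return node.label
            pairs = sorted((key(c), c) for c in node.children)
            node.children = [c for _, c in pairs]
            return "(" + ",".join(k for k, _ in pairs) + ")"

        key(tree.root)
        return tree

    # -- time geometry (used for coalescent-unit trees) ----------------
    def node_times(self) -> dict[int, float]:
        """Map ``id(node)`` to its time before present (leaves at 0).

        Assumes an ultrametric tree; for slightly inconsistent child depths
        the maximum is taken.
        """
        times: dict[int, float] = {}

        def walk(node: Node) -> float:
            if node.is_leaf():
                times[id(node)] = 0.0
                return 0.0
            t = max(walk(c) + c.length for c in node.children)
            times[id(node)] = t
            return t

        walk(self.root)
        return times


# ----------------------------------------------------------------------
# newick I/O
# ----------------------------------------------------------------------

def parse_newick(text: str, unit_tag: str) -> RootedTree:
    """Parse a rooted binary newick string; missing lengths default to 0.

    Raises :class:`NewickError` (with the offending position when dendropy
    reports one) for malformed input and :class:`NonBinaryError` for
    multifurcations.
    """
    try:
        dtree = dendropy.Tree.get(
            data=text, schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises several parse-error classes
        line = getattr(exc, "line_num", None)
        col = getattr(exc, "col_num", None)
        pos = f" (line {line}, column {col})" if line is not None else ""
        raise NewickError(f"malformed newick{pos}: {exc}") from exc

    def convert(dnode) -> Node:
        label = None
        if dnode.taxon is not None:
            label = dnode.taxon.label
        elif dnode.label:
            label = dnode.label
        length = dnode.edge.length if dnode.edge.length is not None else 0.0
        children = [convert(c) for c in dnode.child_nodes()]
        if children and label is not None:
            label = None  # internal labels are not used
        return Node(label=label, length=length, children=children)

    root = convert(dtree.seed_node)
    tree = RootedTree(root, unit_tag)
    if not tree.is_binary():
        raise NonBinaryError("non-binary tree: every internal node must "
                             "have exactly two children")
    return tree


def write_newick(tree: RootedTree, lengths: bool = True) -> str:
    return tree.newick(lengths=lengths)


# ----------------------------------------------------------------------
# enumeration
# ----------------------------------------------------------------------

def double_factorial(n: int) -> int:
    out = 1
    while n > 1:
        out *= n
        n -= 2
    return out


def enumerate_rooted_topologies(labels: Iterable[str],
                                unit: str = SUBSTITUTIONS
                                ) -> list[RootedTree]:
    """All distinct rooted binary topologies on ``labels``.

    Trees are returned in deterministic canonical order (sorted by
    canonical topology key); all branch lengths are zero.  The count is
    (2n-3)!! for n leaves; n is restricted to 2..8 to guard against
    combinatorial blow-up.
    """
    labels = sorted(set(labels))
    n = len(labels)
    if not 2 <= n <= 8:
        raise TopologySizeError(f"need between 2 and 8 labels, got {n}")

    roots = [Node(children=[Node(labels[0]), Node(labels[1])])]
    for lab in labels[2:]:
        grown: list[Node] = []
        for root in roots:
            grown.extend(_attach_everywhere(root, lab))
        roots = grown

    trees = [RootedTree(r, unit).canonicalize() for r in roots]
    trees.sort(key=lambda t: t.topology_key())
    assert len(trees) == double_factorial(2 * n - 3)
    return trees


def _attach_everywhere(root: Node, label: str) -> list[Node]:
    """New trees obtained by attaching a leaf on every edge, incl. above
    the root.  A tree with k leaves has 2k-1 attachment points, which is
    what makes the enumeration count (2n-3)!!."""

    def copy_attach(node: Node, target: Node) -> Node:
        if node is target:
            inner = Node(node.label, 0.0, [c.copy() for c in node.children])
            return Node(children=[inner, Node(label)])
        return Node(node.label, node.length,
                    [copy_attach(c, target) for c in node.children])

    out = [Node(children=[root.copy(), Node(label)])]
    for target in _postorder(root):
        if target is not root:
            out.append(copy_attach(root, target))
    return out


# ----------------------------------------------------------------------
# congruence
# ----------------------------------------------------------------------

def restrict(tree: RootedTree, keep: set[str]) -> RootedTree:
    """Restrict a tree to a subset of its leaves, suppressing unary nodes."""

    def prune(node: Node) -> Node | None:
        if node.is_leaf():
            return node.copy() if node.label in keep else None
        kept = [p for p in (prune(c) for c in node.children) if p is not None]
        if not kept:
            return None
        if len(kept) == 1:
            child = kept[0]
            child.length += node.length
            return child
        return Node(node.label, node.length, kept)

    root = prune(tree.root)
    if root is None:
        raise TreeError("restriction removed every leaf")
    return RootedTree(root, tree.unit)


def is_congruent(gene_tree: RootedTree, parental: RootedTree,
                 allele_map: dict[str, str]) -> bool:
    """Does the gene-tree topology match the parental species topology?

    Each species' alleles must be monophyletic, and the species tree induced
    by contracting those clades must equal the parental topology (restricted
    to the species actually sampled).  Any arrangement of alleles *within* a
    species counts as congruent.
    """
    for leaf in gene_tree.leaf_labels():
        if leaf not in allele_map:
            raise AlleleMappingError(f"allele {leaf!r} has no species "
                                     "assignment")
    species_present = {allele_map[l] for l in gene_tree.leaf_labels()}

    def contract(node: Node) -> tuple[str, frozenset[str]]:
        if node.is_leaf():
            sp = allele_map[node.label]
            return sp, frozenset([sp])
        parts = [contract(c) for c in node.children]
        union = frozenset().union(*(s for _, s in parts))
        if len(union) == 1:
            return next(iter(union)), union
        return "(" + ",".join(sorted(k for k, _ in parts)) + ")", union

    induced_key, _ = contract(gene_tree.root)
    parental_key = restrict(parental, species_present).topology_key()
    return induced_key == parental_key


# ----------------------------------------------------------------------
# unrooted reduction (parameter sharing for reversible models)
# ----------------------------------------------------------------------

def unrooted_form(tree: RootedTree) -> RootedTree:
    """The unrooted version of ``tree``, deterministically re-rooted.

    The degree-2 root is suppressed (its two edges fused) and the tree is
    re-rooted at the neighbour of the lexicographically smallest leaf.  Each
    non-root node's ``tag`` is set to the frozenset of leaf labels on its
    side of the edge (the side away from the smallest leaf's neighbour),
    which serves as a stable identifier for the edge within a shared
    branch-length block.

    Two rooted topologies have equal ``topology_key()`` of their unrooted
    forms iff they differ only in root placement.
    """
    # collect undirected edges on a private copy
    src = tree.copy()
    nodes: list[Node] = list(src.postorder())
    adj: dict[int, list[tuple[Node, float]]] = {id(n): [] for n in nodes}
    parent: dict[int, Node] = {}
    for node in nodes:
        for child in node.children:
            adj[id(node)].append((child, child.length))
            adj[id(child)].append((node, child.length))
            parent[id(child)] = node

    root = src.root
    if len(root.children) == 2:
        a, b = root.children
        fused = a.length + b.length
        adj[id(a)] = [(n, l) for n, l in adj[id(a)] if n is not root]
        adj[id(b)] = [(n, l) for n, l in adj[id(b)] if n is not root]
        adj[id(a)].append((b, fused))
        adj[id(b)].append((a, fused))
        del adj[id(root)]

    leaves = sorted((n for n in nodes if n.is_leaf()), key=lambda n: n.label)
    first = leaves[0]
    anchor = adj[id(first)][0][0]

    def build(node: Node, frm: Node | None) -> Node:
        children = [build(nbr, node) for nbr, _ in adj[id(node)]
                    if nbr is not frm]
        length = 0.0
        if frm is not None:
            length = next(l for nbr, l in adj[id(node)] if nbr is frm)
        return Node(node.label, length, children)

    new_root = build(anchor, None)
    out = RootedTree(new_root, tree.unit).canonicalize()

    def tag(node: Node) -> frozenset[str]:
        if node.is_leaf():
            node.tag = frozenset([node.label])
        else:
            node.tag = frozenset().union(*(tag(c) for c in node.children))
        return node.tag

    for child in out.root.children:
        tag(child)
    out.root.tag = None
    return out


def unrooted_key(tree: RootedTree) -> str:
    return unrooted_form(tree).topology_key()


def ordered_edges(tree: RootedTree) -> list[Node]:
    """Non-root nodes (= edges) in a deterministic order keyed by their
    leaf-set tags; used to index branch-length block vectors."""
    edges = [n for n in tree.preorder() if n is not tree.root]
    for n in edges:
        if n.tag is None:
            raise TreeError("edges must be tagged with leaf sets "
                            "(see unrooted_form / tag_clades)")
    edges.sort(key=lambda n: (len(n.tag), tuple(sorted(n.tag))))
    return edges


def tag_clades(tree: RootedTree) -> RootedTree:
    """Set every node's tag to the frozenset of leaf labels below it."""
    def tag(node: Node) -> frozenset[str]:
        if node.is_leaf():
            node.tag = frozenset([node.label])
        else:
            node.tag = frozenset().union(*(tag(c) for c in node.children))
        return node.tag

    tag(tree.root)
    tree.root.tag = None
    return tree
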