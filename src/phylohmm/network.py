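"""Phylogenetic networks, parental forests, and MUL-tree conversion.

A phylogenetic network with reticulation (hybridization) edges can, in the
simple case used throughout the scan machinery, be decomposed into an
ordered set of *parental trees* — the trees the network "displays" — with
one or more classes flagged as introgressed (:class:`ParentalForest`).

For inspection of the general case the network itself can be given as an
explicit rooted DAG (:class:`PhyloNetwork`) and converted to a multi-labeled
tree (MUL-tree) by duplicating the subtree below each reticulation once per
parent edge, together with the enumeration of all allele-to-leaf mappings
subject to the species-label constraint: an allele sampled from species *s*
may map only to leaves labeled *s*.
"""
from __future__ import annotations

import itertools
from dataclasses import dataclass, field

from . import trees
from .trees import Node, RootedTree, TreeError, AlleleMappingError


@dataclass
class ParentalForest:
    """Ordered parental trees plus the allele-to-species assignment.

    ``introgressed_class_indices`` flags the classes whose parental tree
    represents introgressive descent.  A single-tree forest (no
    introgression hypothesis) is permitted as a degenerate case with an
    empty introgressed set.
    """

    parental_trees: list[RootedTree]
    allele_map: dict[str, str]
    introgressed_class_indices: frozenset[int] = field(
        default_factory=frozenset)

    def __post_init__(self):
        self.introgressed_class_indices = frozenset(
            self.introgressed_class_indices)
        if not self.parental_trees:
            raise TreeError("at least one parental tree is required")
        for t in self.parental_trees:
            if t.unit != trees.COALESCENT:
                raise trees.UnitError(
                    "parental trees must be in coalescent units")
        first = set(self.parental_trees[0].leaf_labels())
        for t in self.parental_trees[1:]:
            if set(t.leaf_labels()) != first:
                raise TreeError("parental trees must share one leaf set")
        unknown = set(self.allele_map.values()) - first
        if unknown:
            raise AlleleMappingError(
                f"alleles mapped to species {sorted(unknown)} absent from "
                "the parental trees")
        k = len(self.parental_trees)
        if k >= 2:
            idx = self.introgressed_class_indices
            if not idx or not idx < set(range(k)):
                raise TreeError(
                    "introgressed_class_indices must be a non-empty proper "
                    f"subset of range({k})")
        elif self.introgressed_class_indices:
            raise TreeError("a single-class forest has no introgressed "
                            "class")

    @property
    def n_classes(self) -> int:
        return len(self.parental_trees)

    @property
    def alleles(self) -> list[str]:
        return sorted(self.allele_map)

    def species_of(self, allele: str) -> str:
        try:
            return self.allele_map[allele]
        except KeyError:
            raise AlleleMappingError(f"allele {allele!r} has no species "
                                     "assignment") from None


# ----------------------------------------------------------------------
# explicit networks
# ----------------------------------------------------------------------

@dataclass
class PhyloNetwork:
    """A rooted phylogenetic network as an explicit edge list.

    ``edges`` maps (parent, child) -> (branch_length, inheritance_prob);
    ``inheritance_prob`` is None for tree edges and, for the two edges into
    a reticulation node, the probabilities sum to 1.  Leaf names are species
    names.
    """

    edges: dict[tuple[str, str], tuple[float, float | None]]
    root: str

    def __post_init__(self):
        self._children: dict[str, list[str]] = {}
        self._parents: dict[str, list[str]] = {}
        for (p, c), (_l, _g) in self.edges.items():
            self._children.setdefault(p, []).append(c)
            self._parents.setdefault(c, []).append(p)
        for node, parents in self._parents.items():
            if len(parents) > 2:
                raise TreeError(f"node {node!r} has {len(parents)} parents")
        if self.root in self._parents:
            raise TreeError("root must have no parents")
        # deterministic orders
        for d in (self._children, self._parents):
            for k in d:
                d[k].sort()

    @classmethod
    def from_edge_list(cls, rows, root=None) -> "PhyloNetwork":
        """Rows of (parent, child, length[, inheritance_prob])."""
        edges = {}
        children = set()
        nodes = set()
        for row in rows:
            p, c, length = row[0], row[1], float(row[2])
            g = float(row[3]) if len(row) > 3 and row[3] is not None else None
            edges[(p, c)] = (length, g)
            children.add(c)
            nodes.update((p, c))
        if root is None:
            roots = nodes - children
            if len(roots) != 1:
                raise TreeError(f"expected one root, found {sorted(roots)}")
            root = roots.pop()
        return cls(edges, root)

    def leaves(self) -> list[str]:
        return sorted(n for n in self._parents if n not in self._children)

    def reticulations(self) -> list[str]:
        return sorted(n for n, ps in self._parents.items() if len(ps) == 2)


@dataclass
class MulTree:
    """Multi-labeled tree: leaves carry species labels, possibly repeated.

    ``allele_mappings`` enumerates every function from alleles to leaf
    copies respecting the species-label constraint; leaves are identified
    by their child-index path from the root (e.g. ``"0.1"``).
    """

    tree: RootedTree
    allele_mappings: list[dict[str, str]]

    def leaf_paths(self) -> dict[str, list[str]]:
        """species label -> list of leaf paths carrying that label."""
        out: dict[str, list[str]] = {}

        def walk(node: Node, path: str):
            if node.is_leaf():
                out.setdefault(node.label, []).append(path)
            for i, c in enumerate(node.children):
                walk(c, f"{path}.{i}" if path else str(i))

        walk(self.tree.root, "")
        return out

    def mappings_table(self) -> list[tuple[str, int, str]]:
        """Rows (allele_id, mapping_index, leaf_path) for TSV export."""
        rows = []
        for i, m in enumerate(self.allele_mappings):
            for allele in sorted(m):
                rows.append((allele, i, m[allele]))
        return rows


def network_to_multree(network: PhyloNetwork,
                       samples: dict[str, list[str]]) -> MulTree:
    """Convert a network to a MUL-tree and enumerate allele mappings.

    The subtree below each reticulation is duplicated once per parent edge;
    branch lengths are carried over and each copy's attachment edge keeps
    its inheritance probability as the node ``tag``.  ``samples`` maps each
    species (leaf of the network) to the alleles sampled from it.
    """

    def expand(name: str, length: float, gamma) -> Node:
        children = network._children.get(name, [])
        if not children:
            return Node(label=name, length=length, tag=gamma)
        kids = []
        for c in children:
            clen, cg = network.edges[(name, c)]
            kids.append(expand(c, clen, cg))
        if len(kids) == 1:  # suppress the reticulation node itself
            only = kids[0]
            only.length += length
            if gamma is not None:
                only.tag = gamma
            return only
        return Node(label=None, length=length, children=kids, tag=gamma)

    root = expand(network.root, 0.0, None)
    mul = RootedTree.__new__(RootedTree)  # skip unique-leaf validation
    mul.root, mul.unit = root, trees.COALESCENT

    result = MulTree(mul, [])
    paths = result.leaf_paths()
    unknown = set(samples) - set(paths)
    if unknown:
        raise AlleleMappingError(
            f"samples given for species {sorted(unknown)} not present in "
            "the network")
    alleles = [a for sp in sorted(samples) for a in samples[sp]]
    choices = [paths[sp] for sp in sorted(samples) for _ in samples[sp]]
    mappings = [dict(zip(alleles, combo))
                for combo in itertools.product(*choices)]
    result.allele_mappings = mappings
    return result
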