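"""Gene-tree topology probabilities under the multispecies coalescent.

Given a species (parental) tree with branch lengths in coalescent units and
an allele-to-species map, the probability of each rooted gene-tree topology
is computed exactly by enumerating *coalescent histories*: assignments of
gene-tree coalescence events to species-tree branches that respect both the
species-tree ancestry of the alleles involved and the gene-tree partial
order of the events.  Each history contributes a product over species-tree
branches of

    g_{uv}(t) * w / d

where ``g_{uv}(t)`` is the probability that ``u`` lineages entering the
branch leave ``v`` lineages after duration ``t`` (Tavare's formula, with the
pairwise coalescence rate equal to 1), ``d`` is the number of sequences of
``u - v`` coalescences, and ``w`` is the number of orderings of the events
assigned to the branch consistent with the gene-tree topology.

The enumeration is exact but exponential in the number of alleles; it is
limited to 6 alleles, which covers every model this package constructs.
"""
from __future__ import annotations

import itertools
import math


from . import trees
from .trees import Node, RootedTree, AlleleMappingError, UnitError, TreeError

MAX_ALLELES = 6


def tavare_gij(i: int, j: int, t: float) -> float:
    """P(i lineages reduce to j) over duration ``t`` coalescent units.

    Time is scaled so that a single pair coalesces at rate 1; ``k`` lineages
    therefore coalesce at rate k(k-1)/2.
    """
    if j > i or j < 1:
        return 0.0
    if t == math.inf:
        return 1.0 if j == 1 else 0.0
    total = 0.0
    for k in range(j, i + 1):
        term = math.exp(-k * (k - 1) * t / 2.0)
        term *= (2 * k - 1) * (-1) ** (k - j)
        term /= math.factorial(j) * math.factorial(k - j) * (j + k - 1)
        for y in range(k):
            term *= (j + y) * (i - y) / (i + y)
        total += term
    return total


def _seq_denominator(u: int, v: int) -> int:
    """Number of distinct sequences of u-v coalescences starting from u
    lineages: prod_{j=v+1}^{u} C(j, 2)."""
    out = 1
    for j in range(v + 1, u + 1):
        out *= j * (j - 1) // 2
    return out


def _linear_extensions(events: list[Node], children: dict[int, list[Node]]
                       ) -> int:
    """Number of linear orders of ``events`` consistent with the gene-tree
    partial order (an event must follow its descendant events assigned to
    the same branch).  ``events`` form a forest; the count is k! divided by
    the product of within-forest subtree sizes (hook-length formula)."""
    sizes: dict[int, int] = {}

    def size(node: Node) -> int:
        s = 1 + sum(size(c) for c in children.get(id(node), []))
        sizes[id(node)] = s
        return s

    for e in events:
        size(e)
    denom = 1
    for e in events:
        denom *= sizes[id(e)]
    return math.factorial(len(events)) // denom


def gene_tree_topology_probability(gene_topology: RootedTree,
                                   species_tree: RootedTree,
                                   allele_map: dict[str, str]) -> float:
    """Exact P(rooted gene-tree topology | species tree) under the MSC."""
    if species_tree.unit != trees.COALESCENT:
        raise UnitError("species tree must carry coalescent-unit branch "
                        f"lengths, got {species_tree.unit!r}")
    alleles = gene_topology.leaf_labels()
    if len(alleles) > MAX_ALLELES:
        raise TreeError(f"enumeration supports at most {MAX_ALLELES} "
                        f"alleles, got {len(alleles)}")
    for a in alleles:
        if a not in allele_map:
            raise AlleleMappingError(f"allele {a!r} has no species "
                                     "assignment")

    # --- species tree geometry ---------------------------------------
    sp = species_tree
    sp_nodes = list(sp.postorder())
    times = sp.node_times()
    sp_parent: dict[int, Node] = {}
    for node in sp_nodes:
        for c in node.children:
            sp_parent[id(c)] = node

    # population of node v = edge above v; root population extends to inf
    def duration(v: Node) -> float:
        if v is sp.root:
            return math.inf
        return times[id(sp_parent[id(v)])] - times[id(v)]

    sp_species: dict[int, frozenset[str]] = {}
    for node in sp_nodes:
        if node.is_leaf():
            sp_species[id(node)] = frozenset([node.label])
        else:
            sp_species[id(node)] = frozenset().union(
                *(sp_species[id(c)] for c in node.children))

    # ancestors (weak) of each species node, ordered towards the root
    def ancestors(v: Node) -> list[Node]:
        out = [v]
        while id(v) in sp_parent:
            v = sp_parent[id(v)]
            out.append(v)
        return out

    anc_ids = {id(v): {id(a) for a in ancestors(v)} for v in sp_nodes}

    # --- gene tree structure ------------------------------------------
    gt = gene_topology
    internals = [n for n in gt.postorder() if not n.is_leaf()]
    gt_children: dict[int, list[Node]] = {
        id(n): [c for c in n.children if not c.is_leaf()] for n in internals}

    gt_species: dict[int, frozenset[str]] = {}

    def collect(node: Node) -> frozenset[str]:
        if node.is_leaf():
            s = frozenset([allele_map[node.label]])
        else:
            s = frozenset().union(*(collect(c) for c in node.children))
        gt_species[id(node)] = s
        return s

    collect(gt.root)

    by_species: dict[str, int] = {}
    for a in alleles:
        by_species[allele_map[a]] = by_species.get(allele_map[a], 0) + 1
    missing = set(by_species) - set(sp_species[id(sp.root)])
    if missing:
        raise AlleleMappingError(f"species {sorted(missing)} not present in "
                                 "the species tree")

    # allowed species-tree populations for each gene coalescence: weak
    # ancestors of the MRCA population of the species involved
    def mrca_pop(species: frozenset[str]) -> Node:
        for v in sp_nodes:  # postorder => most recent first
            if species <= sp_species[id(v)]:
                return v
        raise AssertionError("unreachable: root contains all species")

    allowed: dict[int, list[Node]] = {
        id(u): ancestors(mrca_pop(gt_species[id(u)])) for u in internals}

    # --- enumerate histories ------------------------------------------
    total = 0.0
    for combo in itertools.product(*(allowed[id(u)] for u in internals)):
        assign = {id(u): v for u, v in zip(internals, combo)}
        ok = True
        for u in internals:
            for child in gt_children[id(u)]:
                # parent event must be weakly ancestral to child's branch
                if id(assign[id(u)]) not in anc_ids[id(assign[id(child)])]:
                    ok = False
                    break
            if not ok:
                break
        if not ok:
            continue
        total += _history_probability(
            assign, internals, gt_children, sp_nodes, sp_species,
            by_species, duration, sp)
    return total


def _history_probability(assign, internals, gt_children, sp_nodes,
                         sp_species, by_species, duration, sp) -> float:
    # events per population
    events: dict[int, list[Node]] = {id(v): [] for v in sp_nodes}
    for u in internals:
        events[id(assign[id(u)])].append(u)

    # lineages entering each population (postorder accumulation)
    enters: dict[int, int] = {}
    exits: dict[int, int] = {}
    prob = 1.0
    for v in sp_nodes:  # postorder: children before parents
        if v.is_leaf():
            u_in = by_species.get(v.label, 0)
        else:
            u_in = sum(exits[id(c)] for c in v.children)
        k = len(events[id(v)])
        v_out = u_in - k
        if u_in == 0:
            if k:
                return 0.0
            enters[id(v)], exits[id(v)] = 0, 0
            continue
        if v_out < 1:
            return 0.0
        if v is sp.root and v_out != 1:
            return 0.0
        enters[id(v)], exits[id(v)] = u_in, v_out
        if u_in == 1 and k == 0:
            continue
        # within-branch children restricted to events in the same branch
        local = {id(e): [c for c in gt_children[id(e)]
                         if id(c) in {id(x) for x in events[id(v)]}]
                 for e in events[id(v)]}
        w = _linear_extensions(events[id(v)], local)
        d = _seq_denominator(u_in, v_out)
        if v is sp.root:
            g = 1.0
        else:
            g = tavare_gij(u_in, v_out, duration(v))
        prob *= g * w / d
    return prob


def topology_probability_table(species_tree: RootedTree,
                               allele_map: dict[str, str],
                               topologies: list[RootedTree] | None = None,
                               ) -> dict[str, float]:
    """Map canonical topology key -> MSC probability, over all rooted
    topologies on the allele set (or a supplied list)."""
    alleles = sorted(allele_map)
    if topologies is None:
        topologies = trees.enumerate_rooted_topologies(alleles)
    table = {}
    for top in topologies:
        p = gene_tree_topology_probability(top, species_tree, allele_map)
        if math.isnan(p):
            raise ArithmeticError(
                f"NaN topology probability for {top.topology_key()}")
        table[top.topology_key()] = p
    return table


def normalize_table(table: dict[str, float]) -> dict[str, float]:
    total = sum(table.values())
    if total <= 0:
        raise ArithmeticError("topology probabilities sum to zero")
    return {k: v / total for k, v in table.items()}
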