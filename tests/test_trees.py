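import numpy as np
import pytest
from hypothesis import given, strategies as st

from phylohmm import trees as T


def random_tree(rng, labels):
    tops = T.enumerate_rooted_topologies(labels)
    tree = tops[rng.integers(len(tops))].copy()
    for node in tree.postorder():
        node.length = float(rng.uniform(0, 3))
    tree.root.length = 0.0
    return tree


class TestNewick:
    def test_basic_parse(self):
        t = T.parse_newick("((A:1,B:1):1,C:2);", T.COALESCENT)
        assert sorted(t.leaf_labels()) == ["A", "B", "C"]
        assert t.topology_key() == "((A,B),C)"
        internal = [n for n in t.postorder()
                    if not n.is_leaf() and n is not t.root][0]
        assert internal.length == 1.0

    def test_missing_lengths_default_to_zero(self):
        t = T.parse_newick("((A,B),C);", T.SUBSTITUTIONS)
        assert all(n.length == 0.0 for n in t.postorder())

    def test_non_binary_rejected(self):
        with pytest.raises(T.NonBinaryError):
            T.parse_newick("(A:1,B:1,C:1);", T.COALESCENT)

    def test_malformed_newick_reports_position(self):
        with pytest.raises(T.NewickError) as err:
            T.parse_newick("((A:1,B:1:1,C:2);", T.COALESCENT)
        assert "column" in str(err.value)

    def test_bad_unit_tag(self):
        with pytest.raises(T.UnitError):
            T.parse_newick("(A:1,B:1);", "years")

    @given(st.integers(0, 10 ** 6))
    def test_round_trip_random_trees(self, seed):
        """write_newick(parse_newick(s)) reparses to an isomorphic tree."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 7))
        tree = random_tree(rng, [f"t{i}" for i in range(n)])
        text = T.write_newick(tree)
        back = T.parse_newick(text, tree.unit)
        assert back.topology_key() == tree.topology_key()
        orig = {n.label: n.length for n in tree.leaves()}
        new = {n.label: n.length for n in back.leaves()}
        assert orig == pytest.approx(new)


class TestEnumeration:
    @pytest.mark.parametrize("n,count", [(3, 3), (4, 15), (5, 105),
                                         (6, 945)])
    def test_topology_counts_match_double_factorial(self, n, count):
        labels = [f"x{i}" for i in range(n)]
        tops = T.enumerate_rooted_topologies(labels)
        assert len(tops) == count == T.double_factorial(2 * n - 3)
        keys = [t.topology_key() for t in tops]
        assert keys == sorted(keys) and len(set(keys)) == count

    def test_order_is_deterministic(self):
        a = [t.topology_key()
             for t in T.enumerate_rooted_topologies(list("abcd"))]
        b = [t.topology_key()
             for t in T.enumerate_rooted_topologies(list("abcd"))]
        assert a == b

    @pytest.mark.parametrize("n", [1, 9])
    def test_size_guard(self, n):
        with pytest.raises(T.TopologySizeError):
            T.enumerate_rooted_topologies([f"x{i}" for i in range(n)])


class TestCongruence:
    def test_species_clades_match(self, allele_map4):
        par = T.parse_newick("(D:1,S:1);", T.COALESCENT)
        good = T.parse_newick("((d1,d2),(s1,s2));", T.SUBSTITUTIONS)
        bad = T.parse_newick("((d1,s1),(d2,s2));", T.SUBSTITUTIONS)
        assert T.is_congruent(good, par, allele_map4)
        assert not T.is_congruent(bad, par, allele_map4)

    def test_exactly_one_congruent_topology(self, allele_map4):
        """Brute force over all 15 rooted 4-allele topologies."""
        par = T.parse_newick("(D:1,S:1);", T.COALESCENT)
        tops = T.enumerate_rooted_topologies(sorted(allele_map4))
        congruent = [t for t in tops
                     if T.is_congruent(t, par, allele_map4)]
        assert len(congruent) == 1
        assert congruent[0].topology_key() == "((d1,d2),(s1,s2))"

    def test_invariant_under_within_species_relabeling(self, allele_map4):
        par = T.parse_newick("((D:1,S:1):1,O:2);", T.COALESCENT)
        amap = dict(allele_map4, o1="O")
        tops = T.enumerate_rooted_topologies(sorted(amap))
        swapped = {"d1": "d2", "d2": "d1", "s1": "s2", "s2": "s1",
                   "o1": "o1"}
        for top in tops[::7]:
            relab = top.copy()
            for leaf in relab.leaves():
                leaf.label = swapped[leaf.label]
            relab = T.RootedTree(relab.root, relab.unit)
            assert T.is_congruent(top, par, amap) == \
                T.is_congruent(relab, par, amap)

    def test_unmapped_allele_raises(self):
        par = T.parse_newick("(D:1,S:1);", T.COALESCENT)
        g = T.parse_newick("((x,y),z);", T.SUBSTITUTIONS)
        with pytest.raises(T.AlleleMappingError):
            T.is_congruent(g, par, {"x": "D", "y": "S"})


class TestUnrootedReduction:
    def test_fifteen_rooted_collapse_to_three_unrooted(self):
        tops = T.enumerate_rooted_topologies(list("abcd"))
        keys = [T.unrooted_key(t) for t in tops]
        assert len(set(keys)) == 3
        for key in set(keys):
            assert keys.count(key) == 5

    def test_all_rooted_3taxon_trees_share_one_unrooted_form(self):
        tops = T.enumerate_rooted_topologies(list("abc"))
        assert len({T.unrooted_key(t) for t in tops}) == 1

    def test_edge_count_and_bipartitions(self):
        t = T.parse_newick("((a:1,b:2):3,(c:4,d:5):6);",
                           T.SUBSTITUTIONS)
        form = T.unrooted_form(t)
        edges = T.ordered_edges(form)
        assert len(edges) == 2 * 4 - 3
        tags = {tuple(sorted(e.tag)) for e in edges}
        assert ("c", "d") in tags  # the single internal edge
        # path lengths are preserved by the re-rooting
        assert sum(e.length for e in form.postorder()) == \
            pytest.approx(1 + 2 + 4 + 5 + 3 + 6)
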