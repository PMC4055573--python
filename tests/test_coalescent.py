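import math

import pytest

from phylohmm import coalescent as C, trees as T


@pytest.fixture(scope="module")
def tops3():
    return T.enumerate_rooted_topologies(list("abc"))


AM3 = {"a": "A", "b": "B", "c": "C"}
AM4 = {"d1": "D", "d2": "D", "s1": "S", "s2": "S"}


class TestTavare:
    def test_two_lineages_closed_form(self):
        for t in (0.0, 0.1, 1.0, 5.0):
            assert C.tavare_gij(2, 1, t) == pytest.approx(1 - math.exp(-t))
            assert C.tavare_gij(2, 2, t) == pytest.approx(math.exp(-t))

    def test_identity_at_zero_and_absorption_at_infinity(self):
        for i in range(1, 6):
            for j in range(1, i + 1):
                assert C.tavare_gij(i, j, 0.0) == pytest.approx(
                    1.0 if i == j else 0.0, abs=1e-12)
        assert C.tavare_gij(5, 1, math.inf) == 1.0

    def test_rows_are_distributions(self):
        for i in range(2, 7):
            for t in (0.05, 0.5, 2.0):
                total = sum(C.tavare_gij(i, j, t) for j in range(1, i + 1))
                assert total == pytest.approx(1.0, abs=1e-12)


class TestThreeTaxa:
    def test_star_tree_limit_is_uniform(self, tops3):
        sp = T.parse_newick("((A:1,B:1):0.0,C:1);", T.COALESCENT)
        for top in tops3:
            p = C.gene_tree_topology_probability(top, sp, AM3)
            assert p == pytest.approx(1 / 3, abs=1e-12)

    @pytest.mark.parametrize("t", [0.1, 0.5, 1.0, 2.0, 5.0])
    def test_closed_form(self, tops3, t):
        """Congruent: 1 - (2/3)e^-t; each incongruent: e^-t / 3."""
        sp = T.parse_newick(f"((A:1,B:1):{t},C:{1 + t});", T.COALESCENT)
        probs = {top.topology_key():
                 C.gene_tree_topology_probability(top, sp, AM3)
                 for top in tops3}
        assert probs["((a,b),c)"] == pytest.approx(
            1 - (2 / 3) * math.exp(-t), abs=1e-9)
        for key in ("((a,c),b)", "((b,c),a)"):
            assert probs[key] == pytest.approx(math.exp(-t) / 3,
                                               abs=1e-9)

    def test_incongruent_probability_decreases_with_depth(self, tops3):
        incong = [t for t in tops3 if t.topology_key() == "((a,c),b)"][0]
        last = 1.0
        for t in (0.1, 0.5, 1.0, 2.0, 4.0):
            sp = T.parse_newick(f"((A:1,B:1):{t},C:{1 + t});",
                                T.COALESCENT)
            p = C.gene_tree_topology_probability(incong, sp, AM3)
            assert p < last
            last = p

    def test_unit_mismatch_rejected(self, tops3):
        sp = T.parse_newick("((A:1,B:1):1,C:2);", T.SUBSTITUTIONS)
        with pytest.raises(T.UnitError):
            C.gene_tree_topology_probability(tops3[0], sp, AM3)


class TestNormalization:
    @pytest.mark.parametrize("newick,amap", [
        ("(D:1.5,S:1.5);", AM4),
        ("(D:0.15,S:0.15);", AM4),
        ("((D:1.5,S:1.5):1.0,O:2.5);", AM4),
        ("((D:0.7,S:0.7):0.4,O:1.1);",
         dict(AM4, o1="O")),
    ])
    def test_probabilities_sum_to_one(self, newick, amap):
        sp = T.parse_newick(newick, T.COALESCENT)
        table = C.topology_probability_table(sp, amap)
        assert sum(table.values()) == pytest.approx(1.0, abs=1e-9)
        assert all(0.0 <= p <= 1.0 for p in table.values())

    def test_random_species_trees_normalize(self, rng):
        labels = ["u", "v", "w"]
        amap = {"u1": "u", "v1": "v", "w1": "w", "w2": "w"}
        for _ in range(5):
            tops = T.enumerate_rooted_topologies(labels, T.COALESCENT)
            sp = tops[rng.integers(len(tops))].copy()
            for node in sp.postorder():
                node.length = float(rng.uniform(0.05, 3))
            sp = T.RootedTree(sp.root, T.COALESCENT)
            table = C.topology_probability_table(sp, amap)
            assert sum(table.values()) == pytest.approx(1.0, abs=1e-9)


class TestMonteCarloOracle:
    def test_agrees_with_msprime_frequencies(self):
        """Two species, two alleles each: enumeration vs coalescent
        simulation frequencies within 3 standard errors."""
        msprime = pytest.importorskip("msprime")
        t_split = 1.0
        sp = T.parse_newick(f"(D:{t_split},S:{t_split});", T.COALESCENT)
        table = C.topology_probability_table(sp, AM4)

        demography = msprime.Demography()
        demography.add_population(name="D", initial_size=1)
        demography.add_population(name="S", initial_size=1)
        demography.add_population(name="anc", initial_size=1)
        demography.add_population_split(time=t_split,
                                        derived=["D", "S"],
                                        ancestral="anc")
        n_rep = 30_000
        names = {0: "d1", 1: "d2", 2: "s1", 3: "s2"}
        counts: dict[str, int] = {}
        reps = msprime.sim_ancestry(
            samples={"D": 2, "S": 2}, demography=demography, ploidy=1,
            num_replicates=n_rep, random_seed=7)
        for ts in reps:
            tree = ts.first()

            def key(u):
                if tree.is_leaf(u):
                    return names[u]
                return "(" + ",".join(
                    sorted(key(c) for c in tree.children(u))) + ")"

            k = key(tree.root)
            counts[k] = counts.get(k, 0) + 1

        for topo_key, prob in table.items():
            freq = counts.get(topo_key, 0) / n_rep
            se = math.sqrt(max(prob * (1 - prob), 1e-12) / n_rep)
            assert abs(freq - prob) <= max(3 * se, 2e-3), topo_key
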