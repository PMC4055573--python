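import numpy as np
import pytest

from phylohmm import simulate as SIM, trees as T


@pytest.fixture
def config():
    return SIM.SimConfig(migration_rate=0.5, length=20_000, seed=1)


class TestGenealogy:
    def test_isolation_forbids_early_cross_coalescence(self, rng):
        """With m=0, no A lineage may coalesce with a B lineage before
        the split; equivalently no (1 A + B's) clade can be younger than
        t_split_ab."""
        cfg = SIM.SimConfig(migration_rate=0.0)
        for _ in range(400):
            tree = SIM.simulate_genealogy(cfg, rng)
            for node in tree.postorder():
                if node.is_leaf():
                    continue
                labels = [l.label for l in tree.leaves()
                          if l.label in
                          {x.label for x in SIM._leaves_under(node)}]
                pops = {lab[0] for lab in labels}
                if pops == {"a", "b"}:
                    assert node.tag >= cfg.t_split_ab

    def test_pairwise_tmrca_is_one_coalescent_unit(self, rng):
        cfg = SIM.SimConfig(n_a=2, n_b=0, migration_rate=0.0)
        times = [SIM.simulate_genealogy(cfg, rng).root.tag
                 for _ in range(20_000)]
        se = np.std(times) / np.sqrt(len(times))
        assert abs(np.mean(times) - 1.0) <= 3 * se

    def test_high_migration_forces_cross_coalescence(self, rng):
        cfg = SIM.SimConfig(migration_rate=10.0, t_mig_start=0.0,
                            t_mig_end=30.0)
        hits = 0
        n = 800
        for _ in range(n):
            tree = SIM.simulate_genealogy(cfg, rng)
            times = [node.tag for node in tree.postorder()
                     if not node.is_leaf()]
            labels_under = {}
            for node in tree.postorder():
                if node.is_leaf():
                    continue
                labs = [l.label for l in SIM._leaves_under(node)]
                if {l[0] for l in labs} == {"a", "b"} and \
                        node.tag < cfg.t_split_ab:
                    hits += 1
                    break
        assert hits / n > 0.5


class TestTruthLabels:
    def test_sound_under_isolation(self, rng):
        cfg = SIM.SimConfig(migration_rate=0.0)
        assert not any(
            SIM.label_migration_lower_bound(
                SIM.simulate_genealogy(cfg, rng), cfg)
            for _ in range(2000))

    def test_hand_built_genealogy(self):
        cfg = SIM.SimConfig(migration_rate=1.0, t_mig_start=0.1,
                            t_mig_end=0.6)
        tree = T.parse_newick(
            "((a1:0.5,b1:0.5):29.5,(a2:28,(b2:1,o1:1):27):2);",
            T.COALESCENT)
        times = tree.node_times()
        for node in tree.postorder():
            node.tag = times[id(node)]
        assert SIM.label_migration_lower_bound(tree, cfg)
        late = SIM.SimConfig(migration_rate=1.0, t_mig_start=0.1,
                             t_mig_end=0.4)
        assert not SIM.label_migration_lower_bound(tree, late)

    def test_label_frequency_monotone_in_migration_rate(self, rng):
        freqs = []
        for m in (0.0, 0.5, 2.0):
            cfg = SIM.SimConfig(migration_rate=m)
            labs = [SIM.label_migration_lower_bound(
                SIM.simulate_genealogy(cfg, rng), cfg)
                for _ in range(1500)]
            freqs.append(np.mean(labs))
        assert freqs[0] == 0.0
        assert freqs[0] < freqs[1] < freqs[2]


class TestReplicates:
    def test_no_recombination_gives_one_segment(self):
        rep = SIM.simulate_replicate(
            SIM.SimConfig(recombination_rate=0.0, length=1000), seed=2)
        assert len(rep.segments) == 1
        assert (rep.segments[0].start, rep.segments[0].end) == (0, 1000)

    def test_no_mutation_gives_identical_sequences(self):
        rep = SIM.simulate_replicate(
            SIM.SimConfig(theta=0.0, length=500), seed=3)
        assert len({row.tobytes() for row in rep.alignment.codes}) == 1

    def test_segment_count_matches_poisson_mean(self):
        cfg = SIM.SimConfig(length=10_000, recombination_rate=2e-3)
        counts = [len(SIM.simulate_replicate(cfg, seed=s).segments)
                  for s in range(100)]
        expected = 1 + cfg.recombination_rate * cfg.length
        se = np.std(counts) / np.sqrt(len(counts))
        assert abs(np.mean(counts) - expected) <= 3 * se

    def test_segments_partition_sequence(self, config):
        rep = SIM.simulate_replicate(config, seed=7)
        edges = [(s.start, s.end) for s in rep.segments]
        assert edges[0][0] == 0 and edges[-1][1] == config.length
        for (a, b), (c, d) in zip(edges, edges[1:]):
            assert b == c and a < b
        for seg in rep.segments:
            assert np.all(rep.truth[seg.start:seg.end] == seg.migrant)

    def test_same_seed_is_bit_identical(self, config):
        r1 = SIM.simulate_replicate(config, seed=11)
        r2 = SIM.simulate_replicate(config, seed=11)
        assert np.array_equal(r1.alignment.codes, r2.alignment.codes)
        assert np.array_equal(r1.truth, r2.truth)

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            SIM.SimConfig(t_mig_start=0.5, t_mig_end=0.2)
        with pytest.raises(ValueError):
            SIM.SimConfig(t_mig_end=40.0)  # beyond the species split


class TestMsInterchange:
    def test_single_line_read_off(self):
        parsed = SIM.read_ms_output("[100](a:1,b:1);\n")
        assert len(parsed) == 1
        length, tree = parsed[0]
        assert length == 100
        assert sorted(tree.leaf_labels()) == ["a", "b"]

    def test_non_tree_lines_skipped(self):
        text = "ms 4 1 -T\n1234 5678\n\n//\n[10](a:1,b:1);\n"
        assert len(SIM.read_ms_output(text)) == 1

    def test_malformed_line_reports_line_number(self):
        with pytest.raises(ValueError) as err:
            SIM.read_ms_output("[10](a:1,b:1);\n[x](a:1,b:1);\n")
        assert "line 2" in str(err.value)

    def test_round_trip_reproduces_segments(self, config):
        rep = SIM.simulate_replicate(config, seed=5)
        text = SIM.write_ms_trees(rep)
        segs = SIM.segments_from_ms(text, config)
        assert len(segs) == len(rep.segments)
        assert sum(s.end - s.start for s in segs) == config.length
        for new, old in zip(segs, rep.segments):
            assert (new.start, new.end) == (old.start, old.end)
            assert new.migrant == old.migrant
            assert new.genealogy.topology_key() == \
                old.genealogy.topology_key()
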