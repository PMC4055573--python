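import itertools

import numpy as np
import pytest
from hypothesis import given, strategies as st

from phylohmm import hmm as H, substitution as S, trees as T
from phylohmm.io import SiteAlignment
from phylohmm.network import ParentalForest
from phylohmm.pipeline import seven_state_model


def exhaustive_path_sum(pi, trans, emis, pat):
    """Brute-force sum over all state paths."""
    n = pi.size
    total = 0.0
    for path in itertools.product(range(n), repeat=len(pat)):
        p = pi[path[0]] * emis[path[0], pat[0]]
        for t in range(1, len(pat)):
            p *= trans[path[t - 1], path[t]] * emis[path[t], pat[t]]
        total += p
    return np.log(total)


def exhaustive_viterbi(pi, trans, emis, pat):
    best, arg = -np.inf, None
    with np.errstate(divide="ignore"):
        lpi, lt, le = np.log(pi), np.log(trans), np.log(emis)
    for path in itertools.product(range(pi.size), repeat=len(pat)):
        s = lpi[path[0]] + le[path[0], pat[0]]
        for t in range(1, len(pat)):
            s += lt[path[t - 1], path[t]] + le[path[t], pat[t]]
        if s > best:
            best, arg = s, path
    return np.array(arg), best


class TestStateSpace:
    def test_simple_case_has_seven_states(self, model3):
        assert model3.n_states == 7

    def test_four_allele_model_has_31_states(self, model4):
        assert model4.n_states == 31
        assert model4.n_topologies == 15

    def test_degenerate_single_class(self, allele_map3, jc):
        forest = ParentalForest(
            [T.parse_newick("((A:1,B:1):1,C:2);", T.COALESCENT)],
            allele_map3)
        model = H.HmmModel(forest, jc, H.HmmParams(0.3, 0.2, 0.2))
        assert model.n_states == 1 + 3
        assert model.params.gamma == 0.0

    def test_exactly_one_congruent_state_per_class(self, model4):
        cong = model4.congruent_mask
        for c in range(model4.n_classes):
            block = cong[c * 15:(c + 1) * 15]
            assert block.sum() == 1


class TestTransitionMatrix:
    def test_hand_computed_seven_state_entries(self, allele_map3, jc):
        """Star parental trees give uniform topology probabilities; with
        gamma=0.1, s1=s2=0.2 the within-class off-diagonals are
        0.9*0.2/3 = 0.06, cross-class entries 0.1/3, and the diagonal is
        the row-stochastic remainder 0.78."""
        forest = ParentalForest(
            [T.parse_newick("((A:1,B:1):0.0,C:1);", T.COALESCENT),
             T.parse_newick("((B:1,C:1):0.0,A:1);", T.COALESCENT)],
            allele_map3, {1})
        model = H.HmmModel(forest, jc, H.HmmParams(0.1, 0.2, 0.2))
        t = model.transition_matrix()
        assert t[1, 2] == pytest.approx(0.06, abs=1e-12)
        assert t[1, 4] == pytest.approx(0.1 / 3, abs=1e-12)
        assert t[1, 1] == pytest.approx(0.78, abs=1e-12)

    @given(gamma=st.floats(1e-4, 0.9), s1=st.floats(1e-4, 0.99),
           s2=st.floats(1e-4, 0.99), seed=st.integers(0, 10 ** 6))
    def test_rows_sum_to_one(self, forest3, jc, gamma, s1, s2, seed):
        rng = np.random.default_rng(seed)
        trees_ = [t.copy() for t in forest3.parental_trees]
        for tree in trees_:
            for node in tree.postorder():
                if not node.is_leaf() and node is not tree.root:
                    node.length = float(rng.uniform(0.01, 5))
        forest = ParentalForest(trees_, forest3.allele_map, {1})
        model = H.HmmModel(forest, jc, H.HmmParams(gamma, s1, s2))
        t = model.transition_matrix()
        assert np.abs(t.sum(axis=1) - 1).max() < 1e-12
        assert np.all(t >= 0)
        assert np.all(t[:, 0] == 0)  # no transitions into the start

    def test_gamma_zero_blocks_cross_class(self, forest3, jc):
        model = H.HmmModel(forest3, jc, H.HmmParams(0.0, 0.2, 0.2))
        t = model.transition_matrix()
        assert np.all(t[1:4, 4:] == 0)
        assert np.all(t[4:, 1:4] == 0)

    def test_start_row_is_normalised_topology_probability(self, model3):
        t = model3.transition_matrix()
        raw = model3.topology_tables().reshape(-1)
        assert np.allclose(t[0, 1:], raw / raw.sum())
        assert t[0, 0] == 0


@pytest.fixture(scope="module")
def tiny(generator7):
    rng = np.random.default_rng(11)
    _path, aln = H.sample(generator7, 6, rng)
    return generator7, aln


class TestDecoding:
    def test_forward_matches_exhaustive_path_sum(self, tiny):
        model, aln = tiny
        pi, trans, emis, pat = H._prepare(model, aln)
        ll = H.log_likelihood(model, aln)
        assert ll == pytest.approx(
            exhaustive_path_sum(pi, trans, emis, pat), abs=1e-10)

    def test_forward_equals_backward(self, tiny):
        model, aln = tiny
        dec = H.forward_backward(model, aln)
        assert dec.log_likelihood == pytest.approx(
            dec.log_likelihood_backward, abs=1e-8)

    def test_posterior_rows_sum_to_one(self, generator7):
        rng = np.random.default_rng(3)
        _path, aln = H.sample(generator7, 300, rng)
        dec = H.forward_backward(generator7, aln)
        assert np.abs(dec.posterior.sum(axis=1) - 1).max() < 1e-8

    def test_single_column_closed_form(self, generator7):
        rng = np.random.default_rng(5)
        _path, aln = H.sample(generator7, 1, rng)
        pi, _trans, emis, pat = H._prepare(generator7, aln)
        expected = np.log((pi * emis[:, pat[0]]).sum())
        assert H.log_likelihood(generator7, aln) == pytest.approx(
            expected, abs=1e-12)

    def test_viterbi_matches_exhaustive_argmax(self, tiny):
        model, aln = tiny
        pi, trans, emis, pat = H._prepare(model, aln)
        path, score = H.viterbi_with_score(model, aln)
        _bpath, bscore = exhaustive_viterbi(pi, trans, emis, pat)
        assert score == pytest.approx(bscore, abs=1e-10)

    def test_path_score_invariant_under_reversal(self, generator7):
        """With symmetric emissions and a reversible chain a reversed
        alignment admits a path of identical score (the reversed
        path)."""
        rng = np.random.default_rng(9)
        _path, aln = H.sample(generator7, 40, rng)
        rev = SiteAlignment(aln.labels, aln.codes[:, ::-1].copy())
        _p1, s1 = H.viterbi_with_score(generator7, aln)
        _p2, s2 = H.viterbi_with_score(generator7, rev)
        assert s1 == pytest.approx(s2, abs=1e-8)

    def test_all_missing_alignment_has_zero_loglik(self, model3):
        aln = SiteAlignment(model3.alleles,
                            np.full((3, 50), S.N_CODE, dtype=np.uint8))
        assert H.log_likelihood(model3, aln) == pytest.approx(
            0.0, abs=1e-9)


class TestIntrogressionPosterior:
    def test_complement_identity(self, generator7):
        rng = np.random.default_rng(21)
        _path, aln = H.sample(generator7, 200, rng)
        dec = H.forward_backward(generator7, aln)
        track = H.introgression_posterior(dec, generator7)
        other = dec.posterior[:, ~generator7.introgressed_mask].sum(
            axis=1)
        assert np.abs(track - (1 - other)).max() < 1e-10
        assert np.all((track >= 0) & (track <= 1))

    def test_gamma_zero_data_from_class_one(self):
        """gamma ~ 0 and class-1 data: the posterior assigns (almost) no
        mass to introgressed states and Viterbi never enters class 2."""
        truth = seven_state_model(gamma=1e-6, s1=0.1, s2=0.3)
        rng = np.random.default_rng(2)
        path, aln = H.sample(truth, 2000, rng)
        # force a class-1-only sample (reject class-2 visits)
        while np.any(truth.introgressed_mask[path - 1]):
            path, aln = H.sample(truth, 2000, rng)
        dec = H.forward_backward(truth, aln)
        track = H.introgression_posterior(dec, truth)
        assert track.mean() < 0.01
        vpath = H.viterbi(truth, aln)
        assert not np.any(truth.introgressed_mask[vpath - 1])


class TestSerialization:
    def test_round_trip_is_bit_exact(self, tmp_path, generator7):
        rng = np.random.default_rng(13)
        _path, aln = H.sample(generator7, 120, rng)
        ll = H.log_likelihood(generator7, aln)
        path = tmp_path / "model.json"
        generator7.save(path)
        back = H.HmmModel.load(path)
        assert H.log_likelihood(back, aln) == ll
        assert back.share == generator7.share
        assert [s.key for s in back.states] == \
            [s.key for s in generator7.states]

    def test_mismatched_block_rejected(self, generator7):
        data = generator7.to_json()
        data["blocks"]["((zz,yy),xx)"] = [0.1, 0.1, 0.1, 0.1]
        with pytest.raises(H.ModelError):
            H.HmmModel.from_json(data)
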