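"""DEC likelihood machinery against dense brute-force oracles."""

import numpy as np
import pytest

from paleorange.dec import (
    DECModel,
    DECParams,
    TipRangeObservation,
    build_rate_matrix,
    cladogenesis_distribution,
    dec_log_likelihood,
    tip_likelihood_vector,
)
from paleorange.trees import DatedTree

from _oracles import DecOracle, clado_outcomes_bruteforce
from conftest import make_geo


def obs(label, mask, ambiguous=False):
    return TipRangeObservation(label, mask, ambiguous)


class TestRateMatrix:
    def test_two_area_rates(self, geo2):
        q = build_rate_matrix(geo2, 0, DECParams(0.1, 0.05)).toarray()
        si = geo2.state_index
        A, B, AB = si[0b01], si[0b10], si[0b11]
        assert q[A, AB] == pytest.approx(0.1)
        assert q[AB, A] == pytest.approx(0.05)
        assert q[A, 0] == pytest.approx(0.05)  # extirpation of the last area
        assert np.allclose(q.sum(axis=1), 0)

    def test_adjacency_gates_dispersal(self):
        geo = make_geo([np.eye(2, dtype=int)], [50.0, 0.0], 2)
        q = build_rate_matrix(geo, 0, DECParams(0.1, 0.05)).toarray()
        # with A and B unconnected the two-area range is not even a state
        assert geo.global_state_space == [0, 0b01, 0b10]
        assert q[geo.state_index[0b01], geo.state_index[0b10]] == 0

    def test_chain_counts_adjacent_sources(self, geo3_chain):
        q = build_rate_matrix(geo3_chain, 0, DECParams(0.1, 0.05)).toarray()
        si = geo3_chain.state_index
        assert 0b101 not in si  # disconnected {A,C} not in the space
        # only B is adjacent to C, so {A,B} -> {A,B,C} runs at d, not 2d
        assert q[si[0b011], si[0b111]] == pytest.approx(0.1)
        # both A and C are adjacent to B: {A,C} absent, but {B}->{A,B} at d
        assert q[si[0b010], si[0b011]] == pytest.approx(0.1)

    def test_rows_sum_zero_null_absorbing(self, geo3_strat):
        for k in range(2):
            q = build_rate_matrix(geo3_strat, k, DECParams(0.07, 0.03)).toarray()
            assert np.allclose(q.sum(axis=1), 0, atol=1e-12)
            assert np.all(q[0] == 0)
            offdiag = q - np.diag(np.diag(q))
            assert np.all(offdiag >= 0)

    def test_disallowed_slice_rows_zero(self, geo3_strat):
        # {B,C} is connected only in the older slice
        q_recent = build_rate_matrix(geo3_strat, 1, DECParams(0.1, 0.05)).toarray()
        i = geo3_strat.state_index[0b110]
        assert np.all(q_recent[i] == 0)

    def test_bad_slice_index(self, geo2):
        with pytest.raises(IndexError):
            build_rate_matrix(geo2, 5, DECParams(0.1, 0.1))


class TestCladogenesis:
    def test_singleton_identity(self):
        assert cladogenesis_distribution(0b1) == [(0b1, 0b1, 1.0)]

    def test_two_area_six_outcomes(self):
        got = cladogenesis_distribution(0b11)
        assert len(got) == 6
        assert all(w == pytest.approx(1 / 6) for _, _, w in got)
        assert set((l, r) for l, r, _ in got) == {
            (0b01, 0b11), (0b11, 0b01), (0b10, 0b11),
            (0b11, 0b10), (0b01, 0b10), (0b10, 0b01),
        }

    def test_three_area_twelve_outcomes(self):
        got = cladogenesis_distribution(0b111)
        assert len(got) == 12
        assert sum(w for _, _, w in got) == pytest.approx(1.0)

    @pytest.mark.parametrize("size", [1, 2, 3, 4, 5])
    def test_matches_bruteforce_enumeration(self, size):
        parent = (1 << size) - 1
        got = {(l, r): w for l, r, w in cladogenesis_distribution(parent)}
        assert got == pytest.approx(clado_outcomes_bruteforce(parent))

    def test_null_parent_rejected(self):
        with pytest.raises(ValueError):
            cladogenesis_distribution(0)


class TestTipVector:
    def test_ambiguous_supersets(self, geo2):
        v = tip_likelihood_vector(obs("f", 0b01, ambiguous=True), geo2)
        si = geo2.state_index
        assert v[si[0b01]] == 1 and v[si[0b11]] == 1
        assert v[si[0b10]] == 0 and v[0] == 0

    def test_exact_single_state(self, geo2):
        v = tip_likelihood_vector(obs("t", 0b01), geo2)
        assert v.sum() == 1 and v[geo2.state_index[0b01]] == 1

    def test_ambiguous_pair_three_areas(self, geo3_complete):
        v = tip_likelihood_vector(obs("f", 0b011, ambiguous=True), geo3_complete)
        hits = {geo3_complete.global_state_space[i] for i in np.nonzero(v)[0]}
        assert hits == {0b011, 0b111}

    def test_out_of_range_area(self, geo2):
        with pytest.raises(ValueError, match="outside"):
            tip_likelihood_vector(obs("t", 0b100), geo2)


# -- likelihood vs oracle ----------------------------------------------------

TREES = {
    "two": "(A:1,B:1);",
    "two_fossil": "(A:3,F:1.5);",
    "three": "((A:1,B:1):1,C:2);",
    "four": "((A:1,B:1):1,(C:1.5,D:1.5):0.5);",
    "four_fossil": "((A:2,F:0.8):1,(C:1.5,D:1.5):1.5);",
    "four_deep": "((A:10,F:4):20,(C:15,D:15):15);",
}


def case(tree_key, observations, d, e, geo_name):
    return pytest.param(tree_key, observations, d, e, geo_name,
                        id=f"{tree_key}-{geo_name}-d{d}-e{e}")


LIK_CASES = [
    case("two", {"A": (0b01, False), "B": (0b10, False)}, 0.1, 0.05, "geo2"),
    case("two", {"A": (0b01, False), "B": (0b01, False)}, 0.3, 0.2, "geo2"),
    case("two_fossil", {"A": (0b01, False), "F": (0b10, True)}, 0.1, 0.05, "geo2"),
    case("three", {"A": (0b001, False), "B": (0b010, False), "C": (0b100, False)},
         0.1, 0.05, "geo3_chain"),
    case("three", {"A": (0b011, False), "B": (0b010, False), "C": (0b110, False)},
         0.2, 0.1, "geo3_complete"),
    case("four", {"A": (0b001, False), "B": (0b011, False),
                  "C": (0b100, False), "D": (0b100, False)}, 0.15, 0.02,
         "geo3_chain"),
    case("four_fossil", {"A": (0b001, False), "F": (0b010, True),
                         "C": (0b100, False), "D": (0b110, False)}, 0.1, 0.08,
         "geo3_complete"),
    case("four_deep", {"A": (0b001, False), "F": (0b010, True),
                       "C": (0b100, False), "D": (0b010, False)}, 0.05, 0.01,
         "geo3_strat"),
]


class TestLikelihoodOracle:
    @pytest.mark.parametrize("tree_key,observations,d,e,geo_name", LIK_CASES)
    def test_matches_dense_bruteforce(self, tree_key, observations, d, e,
                                      geo_name, request):
        geo = request.getfixturevalue(geo_name)
        tree = DatedTree.from_newick(TREES[tree_key])
        obs_list = [obs(k, m, a) for k, (m, a) in observations.items()]
        got = dec_log_likelihood(tree, obs_list, geo, DECParams(d, e))
        want = DecOracle(geo, d, e).loglik(tree, {o.label: o for o in obs_list})
        assert got == pytest.approx(want, abs=1e-8)

    def test_no_events_probability_one(self, geo2):
        tree = DatedTree.from_newick("(A:1,B:1);")
        obs_list = [obs("A", 0b01), obs("B", 0b01)]
        lnl = dec_log_likelihood(tree, obs_list, geo2, DECParams(0.0, 0.0))
        assert lnl == pytest.approx(0.0, abs=1e-12)

    def test_stratification_noop(self):
        """Four identical slices give the same likelihood as one."""
        adj = [[1, 1, 0], [1, 1, 1], [0, 1, 1]]
        geo_one = make_geo([adj], [50.0, 0.0], 3)
        geo_four = make_geo([adj] * 4, [50.0, 30.0, 20.0, 5.0, 0.0], 3)
        tree = DatedTree.from_newick("((A:8,B:8):27,(C:25,F:12):10);")
        obs_list = [obs("A", 0b001), obs("B", 0b010), obs("C", 0b100),
                    obs("F", 0b010, ambiguous=True)]
        p = DECParams(0.07, 0.02)
        l1 = dec_log_likelihood(tree, obs_list, geo_one, p)
        l4 = dec_log_likelihood(tree, obs_list, geo_four, p)
        assert l1 == pytest.approx(l4, abs=1e-10)

    def test_tip_order_and_child_swap_invariance(self, geo3_complete):
        p = DECParams(0.1, 0.05)
        t1 = DatedTree.from_newick("((A:1,B:1):1,C:2);")
        t2 = DatedTree.from_newick("(C:2,(B:1,A:1):1);")
        obs_list = [obs("A", 0b001), obs("B", 0b010), obs("C", 0b100)]
        l1 = dec_log_likelihood(t1, obs_list, geo3_complete, p)
        l2 = dec_log_likelihood(t2, list(reversed(obs_list)), geo3_complete, p)
        assert l1 == pytest.approx(l2, abs=1e-12)

    def test_ambiguity_never_lowers_likelihood(self, geo3_complete):
        p = DECParams(0.1, 0.05)
        tree = DatedTree.from_newick("((A:1,F:0.5):1,C:2);")
        exact = [obs("A", 0b001), obs("F", 0b010), obs("C", 0b100)]
        fuzzy = [obs("A", 0b001), obs("F", 0b010, ambiguous=True), obs("C", 0b100)]
        l_exact = dec_log_likelihood(tree, exact, geo3_complete, p)
        l_fuzzy = dec_log_likelihood(tree, fuzzy, geo3_complete, p)
        assert l_fuzzy >= l_exact - 1e-12

    def test_missing_observation_rejected(self, geo2):
        tree = DatedTree.from_newick("(A:1,B:1);")
        with pytest.raises(ValueError, match="without range"):
            DECModel(tree, [obs("A", 0b01)], geo2)

    def test_root_older_than_tiling_rejected(self, geo2):
        tree = DatedTree.from_newick("(A:60,B:60);")
        with pytest.raises(ValueError, match="slice tiling"):
            DECModel(tree, [obs("A", 0b01), obs("B", 0b10)], geo2)


class TestAncestralRanges:
    def test_no_event_root_certain(self, geo2):
        tree = DatedTree.from_newick("(A:1,B:1);")
        model = DECModel(tree, [obs("A", 0b01), obs("B", 0b01)], geo2)
        from paleorange.dec import DECResults

        res = DECResults(model, DECParams(0.0, 0.0), 0.0, {"converged": True})
        table = res.ancestral_ranges()
        best, p = table.ranked[tree.root.index][0]
        assert best == 0b01 and p == pytest.approx(1.0)

    @pytest.mark.parametrize("geo_name,d,e", [
        ("geo3_complete", 0.1, 0.05),
        ("geo3_chain", 0.2, 0.02),
        ("geo3_strat", 0.08, 0.04),
    ])
    def test_marginals_match_joint_enumeration(self, geo_name, d, e, request):
        geo = request.getfixturevalue(geo_name)
        tree = DatedTree.from_newick("((A:6,B:6):14,C:20);")
        obs_map = {"A": obs("A", 0b001), "B": obs("B", 0b010),
                   "C": obs("C", 0b100)}
        model = DECModel(tree, obs_map, geo)
        from paleorange.dec import DECResults

        params = DECParams(d, e)
        res = DECResults(model, params, model.loglike(params),
                         {"converged": True})
        table = res.ancestral_ranges()
        want = DecOracle(geo, d, e).joint_marginals(tree, obs_map)
        space = geo.global_state_space
        for node in tree.postorder():
            got = np.zeros(len(space))
            for mask, p in table.ranked[node.index]:
                got[space.index(mask)] = p
            assert got == pytest.approx(want[node.index], abs=1e-8)

    def test_probabilities_normalized_and_sorted(self, geo3_complete):
        tree = DatedTree.from_newick("((A:1,B:1):1,C:2);")
        model = DECModel(
            tree, [obs("A", 0b001), obs("B", 0b011), obs("C", 0b100)],
            geo3_complete)
        from paleorange.dec import DECResults

        params = DECParams(0.1, 0.05)
        res = DECResults(model, params, model.loglike(params),
                         {"converged": True})
        table = res.ancestral_ranges()
        for i, entries in table.ranked.items():
            probs = [p for _, p in entries]
            assert sum(probs) == pytest.approx(1.0, abs=1e-9)
            assert probs == sorted(probs, reverse=True)
            assert len(table.equally_likely[i]) >= 1


class TestFit:
    def test_no_signal_rates_at_floor(self, geo2):
        tree = DatedTree.from_newick("((A:1,B:1):1,(C:1,D:1):1);")
        obs_list = [obs(x, 0b01) for x in "ABCD"]
        res = DECModel(tree, obs_list, geo2).fit()
        assert res.llf == pytest.approx(0.0, abs=1e-4)
        assert res.params.d < 1e-4 and res.params.e < 1e-4

    def test_summary_mentions_estimates(self, geo2):
        tree = DatedTree.from_newick("(A:1,B:1);")
        res = DECModel(tree, [obs("A", 0b01), obs("B", 0b10)], geo2).fit()
        text = res.summary()
        assert "log-likelihood" in text and "d (disp.)" in text
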