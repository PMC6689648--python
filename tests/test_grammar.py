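"""Grammar core: combinatorics, taxonomy, charts vs enumeration oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from songgrammar import grammar as G
from songgrammar.grammar import TopologyClass

from conftest import random_weight_table


def brute_force_log_total(table, l):
    """Independent oracle: sum tree weights over every fully labeled parse
    of every topology, via per-node Python loops in linear space."""
    lls = np.exp(table.leaf_log_score)
    K, S = table.n_nonterminals, table.n_terminals

    def tree_sums(node):
        # value[z] = total weight of the subtree rooted at a z-labeled node
        if isinstance(node, int):
            return [table.emit_choice_w[z]
                    * sum(table.emit_w[z, s] * lls[node, s] for s in range(S))
                    for z in range(K)]
        vl, vr = tree_sums(node[0]), tree_sums(node[1])
        return [table.branch_choice_w[z]
                * sum(table.branch_w[z, y1, y2] * vl[y1] * vr[y2]
                      for y1 in range(K) for y2 in range(K))
                for z in range(K)]

    total = 0.0
    for topo in G.enumerate_topologies(l):
        v = tree_sums(topo)
        total += sum(table.root_w[z] * v[z] for z in range(K))
    with np.errstate(divide="ignore"):
        return np.log(total)


def brute_force_max_log_weight(table, l):
    """Independent Viterbi oracle: per-topology max over labelings via
    explicit Python loops in linear space."""
    lls = np.exp(table.leaf_log_score)
    K, S = table.n_nonterminals, table.n_terminals

    def tree_max(node):
        if isinstance(node, int):
            return [table.emit_choice_w[z]
                    * max(table.emit_w[z, s] * lls[node, s] for s in range(S))
                    for z in range(K)]
        vl, vr = tree_max(node[0]), tree_max(node[1])
        return [table.branch_choice_w[z]
                * max(table.branch_w[z, y1, y2] * vl[y1] * vr[y2]
                      for y1 in range(K) for y2 in range(K))
                for z in range(K)]

    best = max(max(table.root_w[z] * v[z] for z in range(K))
               for v in (tree_max(t) for t in G.enumerate_topologies(l)))
    with np.errstate(divide="ignore"):
        return np.log(best)


# ---------------------------------------------------------------------------
# counting & enumeration
# ---------------------------------------------------------------------------

class TestCountParses:
    def test_base_cases(self):
        assert G.count_parses(1) == 1
        assert G.count_parses(2) == 1

    def test_l4_is_5(self):
        assert G.count_parses(4) == 5

    def test_l10_matches_catalan_recurrence(self):
        # independent oracle: C_n = sum C_i C_{n-1-i}
        c = [1]
        for n in range(1, 10):
            c.append(sum(c[i] * c[n - 1 - i] for i in range(n)))
        assert G.count_parses(10) == c[9] == 4862

    def test_matches_enumeration_up_to_10(self):
        for l in range(1, 11):
            assert len(G.enumerate_topologies(l)) == G.count_parses(l)

    def test_invalid_length(self):
        with pytest.raises(ValueError):
            G.count_parses(0)


class TestEnumerateTopologies:
    def test_l2_single_tree(self):
        assert G.enumerate_topologies(2) == [(0, 1)]

    def test_l3_two_trees(self):
        assert len(G.enumerate_topologies(3)) == 2

    def test_l5_distinct(self):
        trees = G.enumerate_topologies(5)
        assert len(trees) == 14 == len(set(trees))

    def test_guard(self):
        with pytest.raises(ValueError):
            G.enumerate_topologies(13)


class TestClassifyTopology:
    def test_left_chain(self):
        assert G.classify_topology((((0, 1), 2), 3)) == TopologyClass.LEFT

    def test_balanced_is_nonregular(self):
        assert G.classify_topology(((0, 1), (2, 3))) == TopologyClass.NONREGULAR

    def test_short_strings(self):
        assert G.classify_topology((0, 1)) == TopologyClass.BOTH_REGULAR
        assert G.classify_topology(0) == TopologyClass.BOTH_REGULAR

    @pytest.mark.parametrize("side", [TopologyClass.LEFT, TopologyClass.RIGHT])
    @pytest.mark.parametrize("l", [3, 4, 5, 7])
    def test_regular_tree_composition(self, l, side):
        assert G.classify_topology(G.regular_tree(l, side)) == side

    @pytest.mark.parametrize("l", [4, 5, 6, 7])
    def test_nonregular_count_is_catalan_minus_2(self, l):
        classes = [G.classify_topology(t) for t in G.enumerate_topologies(l)]
        assert classes.count(TopologyClass.LEFT) == 1
        assert classes.count(TopologyClass.RIGHT) == 1
        assert classes.count(TopologyClass.NONREGULAR) == G.count_parses(l) - 2


class TestRegularTree:
    def test_right_l4(self):
        assert G.regular_tree(4, TopologyClass.RIGHT) == (0, (1, (2, 3)))

    def test_left_l4(self):
        assert G.regular_tree(4, TopologyClass.LEFT) == (((0, 1), 2), 3)

    def test_single_leaf(self):
        assert G.regular_tree(1, TopologyClass.LEFT) == 0


# ---------------------------------------------------------------------------
# charts vs oracles
# ---------------------------------------------------------------------------

class TestInside:
    def test_unit_weights_give_catalan(self):
        for l in (1, 2, 3, 4, 6):
            t = G.RuleWeightTable(np.ones(1), np.ones(1), np.ones(1),
                                  np.ones((1, 1, 1)), np.ones((1, 1)))
            t = t.with_leaf_scores(np.ones((l, 1)))
            assert G.inside_log_normalizer(t) == pytest.approx(
                np.log(G.count_parses(l)), abs=1e-12)

    def test_l1_closed_form(self, rng):
        t = random_weight_table(rng, K=3, S=2, l=1)
        expected = np.log(sum(
            t.root_w[z] * t.emit_choice_w[z]
            * sum(t.emit_w[z, s] * np.exp(t.leaf_log_score[0, s]) for s in range(2))
            for z in range(3)))
        assert G.inside_log_normalizer(t) == pytest.approx(expected, rel=1e-12)

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        l = int(rng.integers(1, 7))
        t = random_weight_table(rng, K=2, S=2, l=l)
        assert G.inside_log_normalizer(t) == pytest.approx(
            brute_force_log_total(t, l), rel=1e-9)

    def test_zero_weights_give_neg_inf(self):
        t = G.RuleWeightTable(np.zeros(1), np.ones(1), np.zeros(1),
                              np.ones((1, 1, 1)), np.ones((1, 1)))
        assert G.inside_log_normalizer(t, l=2) == -np.inf

    def test_monotone_in_weights(self, rng):
        t = random_weight_table(rng, K=2, S=2, l=4)
        base = G.inside_log_normalizer(t)
        t.branch_w[0, 1, 1] *= 2.0
        assert G.inside_log_normalizer(t) >= base


class TestParsePosterior:
    def test_uniform_l4_each_topology_one_fifth(self, rng):
        t = G.RuleWeightTable(np.ones(1), np.ones(1), np.ones(1),
                              np.ones((1, 1, 1)), np.ones((1, 1)))
        t = t.with_leaf_scores(np.ones((4, 1)))
        for topo in G.enumerate_topologies(4):
            tree = _label_topology(topo)
            assert G.parse_posterior(t, tree) == pytest.approx(0.2, abs=1e-12)

    @pytest.mark.parametrize("l", [2, 3, 4])
    def test_posteriors_sum_to_one(self, l, rng):
        t = random_weight_table(rng, K=2, S=2, l=l)
        total = sum(G.parse_posterior(t, tree)
                    for tree in G.enumerate_labeled_trees(l, 2, 2))
        assert total == pytest.approx(1.0, rel=1e-9)

    def test_only_right_rules_gives_posterior_one(self):
        from songgrammar.hmm import hmm_as_right_branching_pcfg
        t = hmm_as_right_branching_pcfg(np.array([1.0]), np.array([[1.0]]),
                                        np.array([0.5]), np.array([0.5]))
        t = t.with_leaf_scores(np.zeros((4, 1)), log=True)
        tree, _ = G.viterbi_parse(t)
        assert G.parse_posterior(t, tree) == pytest.approx(1.0, rel=1e-12)


def _label_topology(topo, label=0, terminal=0):
    if isinstance(topo, int):
        return G.ParseTree(label=label, terminal=terminal, pos=topo)
    return G.ParseTree(label=label, left=_label_topology(topo[0]),
                       right=_label_topology(topo[1]))


class TestViterbi:
    @pytest.mark.parametrize("seed", range(8))
    def test_matches_enumeration_argmax(self, seed):
        rng = np.random.default_rng(100 + seed)
        l = int(rng.integers(1, 7))
        t = random_weight_table(rng, K=2, S=2, l=l)
        tree, logw = G.viterbi_parse(t)
        assert logw == pytest.approx(brute_force_max_log_weight(t, l), rel=1e-9)
        assert G.tree_log_weight(t, tree) == pytest.approx(logw, rel=1e-12)

    def test_matches_flat_enumeration_argmax_small(self):
        rng = np.random.default_rng(7)
        t = random_weight_table(rng, K=2, S=2, l=4)
        best = max(G.tree_log_weight(t, tree)
                   for tree in G.enumerate_labeled_trees(4, 2, 2))
        _, logw = G.viterbi_parse(t)
        assert logw == pytest.approx(best, rel=1e-9)

    def test_uniform_ties_break_right(self):
        t = G.RuleWeightTable(np.ones(2), np.ones(2), np.ones(2),
                              np.ones((2, 2, 2)), np.ones((2, 2)))
        tree, _ = G.viterbi_parse(t.with_leaf_scores(np.ones((5, 2))))
        assert G.classify_topology(tree) == TopologyClass.RIGHT
        assert tree.label == 0  # label ties break to the smallest index

    def test_concentrated_weights_recover_tree(self, rng):
        t = random_weight_table(rng, K=2, S=2, l=4)
        t.branch_w[:] = 0.0
        t.branch_w[0, 1, 0] = 1.0  # only A -> B A; forces right-branching
        t.emit_w[:] = 0.0
        t.emit_w[0, 1] = 1.0
        t.emit_w[1, 0] = 1.0
        t.root_w[:] = [1.0, 0.0]
        tree, logw = G.viterbi_parse(t)
        assert np.isfinite(logw)
        assert G.classify_topology(tree) == TopologyClass.RIGHT


class TestTopologyLogInside:
    @pytest.mark.parametrize("l", [3, 4, 5])
    def test_sums_over_topologies_match_inside(self, l, rng):
        t = random_weight_table(rng, K=2, S=3, l=l)
        per_topo = [G.topology_log_inside(t, topo)
                    for topo in G.enumerate_topologies(l)]
        assert G.logsumexp(np.array(per_topo)) == pytest.approx(
            G.inside_log_normalizer(t), rel=1e-9)


# ---------------------------------------------------------------------------
# property-based checks
# ---------------------------------------------------------------------------

@settings(max_examples=40, deadline=None)
@given(seed=st.integers(0, 10_000), l=st.integers(1, 6))
def test_inside_and_viterbi_agree_with_oracles(seed, l):
    rng = np.random.default_rng(seed)
    t = random_weight_table(rng, K=2, S=2, l=l, zero_frac=0.1)
    expected_total = brute_force_log_total(t, l)
    got = G.inside_log_normalizer(t)
    if np.isfinite(expected_total):
        assert got == pytest.approx(expected_total, rel=1e-9, abs=1e-9)
    else:
        assert got == -np.inf
    expected_best = brute_force_max_log_weight(t, l)
    _, logw = G.viterbi_parse(t)
    if np.isfinite(expected_best):
        assert logw == pytest.approx(expected_best, rel=1e-9, abs=1e-9)


@settings(max_examples=20, deadline=None)
@given(l=st.integers(1, 8))
def test_serialization_round_trip(l):
    rng = np.random.default_rng(l)
    t = random_weight_table(rng, K=3, S=3, l=l)
    tree, _ = G.viterbi_parse(t)
    text = G.tree_to_string(tree)
    back = G.tree_from_string(text)
    assert back == tree
    assert G.tree_to_string(back) == text
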