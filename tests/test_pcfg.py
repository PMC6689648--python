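"""HDP-PCFG: generation, expected-log weights, CAVI updates, predictive."""

import numpy as np
import pytest
from scipy.special import digamma, gammaln

from songgrammar import pcfg
from songgrammar.data import FeatureString
from songgrammar.grammar import enumerate_labeled_trees, tree_log_weight
from songgrammar.inference import FitConfig
from songgrammar.priors import Hyperparams, niw_prior

from conftest import two_cluster_corpus


@pytest.fixture
def hyper2():
    return Hyperparams(dim=2, k_beta=2, k_gamma=2)


def make_state(corpus, hyper, seed=0):
    X = np.concatenate([s.vectors for s in corpus])
    return pcfg.init_state(corpus, hyper.resolve(X), np.random.default_rng(seed))


class TestGenerate:
    def test_same_seed_identical(self, hyper2):
        c1, t1, _ = pcfg.generate(10, hyper2, seed=42)
        c2, t2, _ = pcfg.generate(10, hyper2, seed=42)
        assert t1 == t2
        for a, b in zip(c1, c2):
            np.testing.assert_array_equal(a.vectors, b.vectors)

    def test_truncation_one_single_labels(self):
        hyper = Hyperparams(dim=2, k_beta=1, k_gamma=1)
        _, trees, _ = pcfg.generate(20, hyper, seed=0)
        for tree in trees:
            stack = [tree]
            while stack:
                node = stack.pop()
                assert node.label == 0
                if not node.is_leaf:
                    assert node.terminal is None
                    stack.extend([node.left, node.right])

    def test_emission_means_lln(self):
        # law of large numbers on the emitted vectors per terminal
        params = pcfg.PCFGParams(
            root=np.array([1.0]), branch_prob=np.array([0.5]),
            branch=np.ones((1, 1, 1)), emit=np.array([[0.5, 0.5]]),
            means=np.array([[-3.0, 0.0], [3.0, 1.0]]),
            covs=np.stack([np.eye(2)] * 2))
        hyper = Hyperparams(dim=2, k_beta=1, k_gamma=2)
        corpus, trees, _ = pcfg.generate(2000, hyper, seed=1, params=params)
        by_term = {0: [], 1: []}
        for s, tree in zip(corpus, trees):
            for i, leaf in enumerate(tree.leaves()):
                by_term[leaf.terminal].append(s.vectors[i])
        for t, mean in ((0, [-3.0, 0.0]), (1, [3.0, 1.0])):
            emp = np.mean(by_term[t], axis=0)
            n = len(by_term[t])
            assert n > 1000
            np.testing.assert_allclose(emp, mean, atol=5.0 / np.sqrt(n))


class TestExpectedLogWeights:
    def test_symmetric_dirichlet_equal_weights(self, small_corpus, hyper2):
        state = make_state(small_corpus, hyper2)
        state.dir_root = np.full(2, 1.7)
        state.dir_emit = np.full((2, 2), 0.9)
        t = pcfg.expected_log_weights(state)
        assert t.root_w[0] == pytest.approx(t.root_w[1])
        assert np.allclose(t.emit_w, t.emit_w[0, 0])

    def test_jensen_below_posterior_mean(self, small_corpus, hyper2, rng):
        state = make_state(small_corpus, hyper2)
        state.dir_root = rng.uniform(0.5, 4.0, size=2)
        state.dir_branch = rng.uniform(0.5, 4.0, size=(2, 2, 2))
        t = pcfg.expected_log_weights(state)
        mean = pcfg.mean_rule_table(state)
        assert np.all(t.root_w <= mean.root_w + 1e-12)
        assert np.all(t.branch_w <= mean.branch_w + 1e-12)
        assert np.all(t.emit_w <= mean.emit_w + 1e-12)

    def test_digamma_closed_form(self, small_corpus, hyper2):
        state = make_state(small_corpus, hyper2)
        a = np.array([2.5, 0.5])
        state.dir_root = a
        t = pcfg.expected_log_weights(state)
        expected = np.exp(digamma(a) - digamma(a.sum()))
        np.testing.assert_allclose(t.root_w, expected, rtol=1e-12)


class TestEStep:
    def test_forced_derivation_l2(self):
        hyper = Hyperparams(dim=2, k_beta=1, k_gamma=1)
        corpus = [FeatureString("x", np.zeros((2, 2)))]
        state = make_state(corpus, hyper)
        stats = pcfg.e_step(state, corpus)
        assert stats.root.sum() == pytest.approx(1.0)
        assert stats.choice[0, 0] == pytest.approx(1.0)   # one branch
        assert stats.choice[0, 1] == pytest.approx(2.0)   # two emissions
        assert stats.branch.sum() == pytest.approx(1.0)
        assert stats.emit.sum() == pytest.approx(2.0)

    def test_counts_match_enumeration_oracle(self, hyper2, rng):
        corpus = [FeatureString("x", rng.normal(size=(4, 2)))]
        state = make_state(corpus, hyper2, seed=3)
        stats = pcfg.e_step(state, corpus)
        # oracle: enumerate labeled parses, weight by exp(tree log weight)
        table = pcfg.expected_log_weights(state)
        t = table.with_leaf_scores(
            state.niw.expected_log_gaussian(corpus[0].vectors), log=True)
        K, S = 2, 2
        root = np.zeros(K)
        choice = np.zeros((K, 2))
        branch = np.zeros((K, K, K))
        emit = np.zeros((K, S))
        weights, counts = [], []
        for tree in enumerate_labeled_trees(4, K, S):
            w = tree_log_weight(t, tree)
            r = np.zeros(K); c = np.zeros((K, 2))
            b = np.zeros((K, K, K)); e = np.zeros((K, S))
            r[tree.label] += 1

            def walk(node):
                if node.is_leaf:
                    c[node.label, 1] += 1
                    e[node.label, node.terminal] += 1
                else:
                    c[node.label, 0] += 1
                    b[node.label, node.left.label, node.right.label] += 1
                    walk(node.left), walk(node.right)

            walk(tree)
            weights.append(w)
            counts.append((r, c, b, e))
        weights = np.exp(np.array(weights) - np.max(weights))
        weights /= weights.sum()
        for w, (r, c, b, e) in zip(weights, counts):
            root += w * r
            choice += w * c
            branch += w * b
            emit += w * e
        np.testing.assert_allclose(stats.root, root, atol=1e-9)
        np.testing.assert_allclose(stats.choice, choice, atol=1e-9)
        np.testing.assert_allclose(stats.branch, branch, atol=1e-9)
        np.testing.assert_allclose(stats.emit, emit, atol=1e-9)

    def test_responsibility_conservation(self, small_corpus, hyper2):
        state = make_state(small_corpus, hyper2)
        stats = pcfg.e_step(state, small_corpus)
        np.testing.assert_allclose(stats.resp.sum(axis=1), 1.0, atol=1e-9)
        total_positions = sum(len(s) for s in small_corpus)
        assert stats.emit.sum() == pytest.approx(total_positions, abs=1e-6)


class TestMStep:
    def test_zero_counts_recover_base(self, small_corpus, hyper2):
        state = make_state(small_corpus, hyper2)
        stats = pcfg.e_step(state, small_corpus)
        zero = pcfg.PCFGStats(
            root=np.zeros_like(stats.root), choice=np.zeros_like(stats.choice),
            branch=np.zeros_like(stats.branch), emit=np.zeros_like(stats.emit),
            resp=np.zeros_like(stats.resp), x=stats.x, loglik=0.0)
        new = pcfg.m_step(state, zero, update_sticks=False)
        base = state.base_counts()
        np.testing.assert_allclose(new.dir_root, base["root"])
        np.testing.assert_allclose(new.dir_branch, base["branch"])
        np.testing.assert_allclose(new.dir_emit, base["emit"])
        np.testing.assert_allclose(new.niw.mean, niw_prior(state.hyper, 2).mean)

    def test_elbo_non_decreasing_over_sweeps(self, small_corpus, hyper2):
        state = make_state(small_corpus, hyper2, seed=9)
        prev = pcfg.elbo(state, small_corpus)
        for _ in range(6):
            stats = pcfg.e_step(state, small_corpus)
            state = pcfg.m_step(state, stats)
            cur = pcfg.elbo(state, small_corpus)
            assert cur >= prev - 1e-6
            prev = cur


class TestElbo:
    def test_closed_form_degenerate_model(self):
        # 1 string, l=1, K_beta=K_gamma=1: all Dirichlets are trivial except
        # the branch/emit Beta; ELBO = E[log emit-choice] + E[log N(x)]
        # - KL(choice Beta || Beta(1,1)) - KL(NIW || prior)
        hyper = Hyperparams(dim=2, k_beta=1, k_gamma=1, niw_mean=np.zeros(2))
        x = np.array([[0.5, -0.5]])
        corpus = [FeatureString("x", x)]
        state = make_state(corpus, hyper, seed=4)
        got = pcfg.elbo(state, corpus)
        a = state.dir_choice[0]
        e_log_emit = digamma(a[1]) - digamma(a.sum())

        def beta_kl(a1, b1, a0, b0):
            return (gammaln(a1 + b1) - gammaln(a1) - gammaln(b1)
                    - gammaln(a0 + b0) + gammaln(a0) + gammaln(b0)
                    + (a1 - a0) * (digamma(a1) - digamma(a1 + b1))
                    + (b1 - b0) * (digamma(b1) - digamma(a1 + b1)))

        expected = (e_log_emit + state.niw.expected_log_gaussian(x)[0, 0]
                    - beta_kl(a[0], a[1], 1.0, 1.0)
                    - state.niw.kl_to(niw_prior(state.hyper, 1)).sum())
        assert got == pytest.approx(expected, rel=1e-9)

    def test_invariant_to_unused_component_permutation(self, hyper2):
        corpus = [FeatureString("x", np.zeros((1, 2)))]
        hyper = Hyperparams(dim=2, k_beta=1, k_gamma=3)
        state = make_state(corpus, hyper, seed=0)
        # make terminals 1 and 2 exact copies (both unused by any count)
        for arr in (state.niw.mean, state.niw.kappa, state.niw.scale, state.niw.dof):
            arr[2] = arr[1]
        state.dir_emit[:, 2] = state.dir_emit[:, 1]
        state.gamma[1] = state.gamma[2] = (state.gamma[1] + state.gamma[2]) / 2
        before = pcfg.elbo(state, corpus)
        # swap the two identical components
        for arr in (state.niw.mean, state.niw.kappa, state.niw.scale, state.niw.dof):
            arr[[1, 2]] = arr[[2, 1]]
        state.dir_emit[:, [1, 2]] = state.dir_emit[:, [2, 1]]
        assert pcfg.elbo(state, corpus) == pytest.approx(before, rel=1e-12)


class TestFit:
    def test_single_restart_huge_tol_one_sweep(self, small_corpus, hyper2):
        state, record, _ = pcfg.fit(small_corpus, hyper2,
                                    FitConfig(n_restarts=1, tol=1e12,
                                              max_iter=300, seed=0))
        assert record.n_sweeps == 1
        assert len(record.elbo_trace) == 2

    def test_best_elbo_is_max_over_restarts(self, small_corpus, hyper2):
        cfg = FitConfig(n_restarts=4, tol=1.0, max_iter=5, seed=0)
        _, best, records = pcfg.fit(small_corpus, hyper2, cfg)
        assert best.final_elbo == max(r.final_elbo for r in records)

    def test_empty_corpus_raises(self, hyper2):
        with pytest.raises(ValueError):
            pcfg.fit([], hyper2)


class TestPredictive:
    def test_l1_single_terminal_student_t(self, rng):
        hyper = Hyperparams(dim=2, k_beta=1, k_gamma=1, niw_mean=np.zeros(2))
        corpus = [FeatureString("x", rng.normal(size=(1, 2)))]
        state = make_state(corpus, hyper, seed=0)
        x = FeatureString("y", np.array([[0.2, 0.4]]))
        total, per_point = pcfg.posterior_predictive_logdensity(state, x)
        choice = state.dir_choice[0] / state.dir_choice[0].sum()
        expected = np.log(choice[1]) + state.niw.predictive_logpdf(x.vectors)[0, 0]
        assert total == pytest.approx(expected, rel=1e-12)
        assert per_point == pytest.approx(total)

    def test_per_point_divides_by_length(self, small_corpus, hyper2):
        state = make_state(small_corpus, hyper2)
        for s in small_corpus[:4]:
            total, per_point = pcfg.posterior_predictive_logdensity(state, s)
            assert per_point == pytest.approx(total / len(s))

    def test_mc_estimator_agrees(self, hyper2, rng):
        corpus = two_cluster_corpus(rng, n=8, max_len=3)
        state, _, _ = pcfg.fit(corpus, hyper2,
                               FitConfig(n_restarts=1, tol=0.5, max_iter=10, seed=0))
        s = corpus[0]
        plug, _ = pcfg.posterior_predictive_logdensity(state, s)
        mc, _, se = pcfg.posterior_predictive_logdensity_mc(state, s,
                                                            n_samples=3000, seed=1)
        assert abs(plug - mc) <= max(3 * se, 0.15)
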