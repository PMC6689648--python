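import numpy as np
import pytest

from songgrammar.data import FeatureString
from songgrammar.grammar import RuleWeightTable
from songgrammar.priors import Hyperparams


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_weight_table(rng, K=2, S=2, l=4, zero_frac=0.0):
    """A random positive weight table with attached random leaf scores."""
    def draw(shape):
        w = rng.uniform(0.1, 1.0, size=shape)
        if zero_frac:
            w[rng.uniform(size=shape) < zero_frac] = 0.0
        return w

    table = RuleWeightTable(
        root_w=draw(K), branch_choice_w=draw(K), emit_choice_w=draw(K),
        branch_w=draw((K, K, K)), emit_w=draw((K, S)))
    return table.with_leaf_scores(rng.uniform(0.2, 1.0, size=(l, S)))


def two_cluster_corpus(rng, n=20, dim=2, separation=5.0, max_len=6,
                       pattern="random"):
    """Strings of vectors from two well-separated Gaussian clusters."""
    corpus = []
    for i in range(n):
        l = int(rng.integers(1, max_len + 1))
        if pattern == "alternate":
            labels = np.arange(l) % 2
        else:
            labels = rng.integers(0, 2, size=l)
        X = np.where(labels[:, None] == 0, -separation / 2, separation / 2) \
            + rng.standard_normal((l, dim))
        corpus.append(FeatureString(f"s{i:03d}", X))
    return corpus


@pytest.fixture
def small_corpus(rng):
    return two_cluster_corpus(rng, n=12, max_len=5)


@pytest.fixture
def small_hyper():
    return Hyperparams(dim=2, k_beta=3, k_gamma=4, k_omega=4)
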