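"""HDP-PCFG with variable root and Gaussian emission conditioned on terminals.

Generative story per string: a root non-terminal is drawn from the root
distribution; each node labeled ``z`` flips a branch/emit switch, either
expanding into an ordered pair of non-terminals or emitting a terminal
``s``, which in turn emits a feature vector from a terminal-specific
Gaussian.  Stick weights ``beta`` (non-terminals) and ``gamma`` (terminals)
tie the Dirichlet-process base measures of all rule distributions.

Inference is truncated mean-field coordinate ascent: Dirichlet factors for
every rule family, Beta(1,1)-based factors for the branch/emit switches,
NIW factors for the emissions, point-mass factors for the sticks, and a
multinomial parse factor handled by inside-outside passes under
exp(E[log .]) weights.
"""

from __future__ import annotations

import copy
import logging
from dataclasses import dataclass, field

import numpy as np
from .grammar import logsumexp
from scipy.stats import multivariate_normal

from .data import FeatureString
from .grammar import ParseTree, RuleWeightTable, inside_chart
from .inference import FitConfig, RunRecord, cavi_run, multi_restart
from .priors import NIW, Hyperparams, dirichlet_expected_log, dirichlet_kl, niw_prior
from .sticks import optimize_sticks

logger = logging.getLogger(__name__)

__all__ = [
    "PCFGParams",
    "VariationalStatePCFG",
    "generate",
    "expected_log_weights",
    "e_step",
    "m_step",
    "elbo",
    "fit",
    "posterior_predictive_logdensity",
    "posterior_predictive_logdensity_mc",
    "mean_rule_table",
]

_BRANCH, _EMIT = 0, 1


# ---------------------------------------------------------------------------
# explicit parameters & generation
# ---------------------------------------------------------------------------

@dataclass
class PCFGParams:
    """A concrete PCFG with Gaussian emissions (ground truth for sampling)."""

    root: np.ndarray          # (K,) probabilities
    branch_prob: np.ndarray   # (K,) probability of branching at each label
    branch: np.ndarray        # (K, K, K) row-normalized pair distributions
    emit: np.ndarray          # (K, S) row-normalized terminal distributions
    means: np.ndarray         # (S, D)
    covs: np.ndarray          # (S, D, D)

    @property
    def n_nonterminals(self) -> int:
        return self.root.shape[0]

    @property
    def n_terminals(self) -> int:
        return self.emit.shape[1]

    def sample_tree(self, rng: np.random.Generator, max_len: int = 30,
                    max_depth: int = 60) -> ParseTree | None:
        """One parse tree from the grammar, or None if length/depth caps hit."""
        count = 0

        def expand(z: int, depth: int) -> ParseTree | None:
            nonlocal count
            if depth > max_depth or count > max_len:
                return None
            if rng.random() < self.branch_prob[z]:
                flat = rng.choice(self.n_nonterminals ** 2, p=self.branch[z].ravel())
                y1, y2 = divmod(int(flat), self.n_nonterminals)
                left = expand(y1, depth + 1)
                if left is None:
                    return None
                right = expand(y2, depth + 1)
                if right is None:
                    return None
                return ParseTree(label=z, left=left, right=right)
            s = int(rng.choice(self.n_terminals, p=self.emit[z]))
            count += 1
            return ParseTree(label=z, terminal=s, pos=-1)

        r = int(rng.choice(self.n_nonterminals, p=self.root))
        tree = expand(r, 0)
        if tree is None or len(tree) > max_len:
            return None
        return _renumber_positions(tree)

    def emit_vectors(self, tree: ParseTree, rng: np.random.Generator) -> np.ndarray:
        leaves = tree.leaves()
        X = np.empty((len(leaves), self.means.shape[1]))
        for i, leaf in enumerate(leaves):
            X[i] = rng.multivariate_normal(self.means[leaf.terminal],
                                           self.covs[leaf.terminal])
        return X


def _renumber_positions(tree: ParseTree, start: int = 0) -> ParseTree:
    if tree.is_leaf:
        return ParseTree(label=tree.label, terminal=tree.terminal, pos=start)
    left = _renumber_positions(tree.left, start)
    right = _renumber_positions(tree.right, start + len(tree.left))
    return ParseTree(label=tree.label, left=left, right=right)


def _truncated_gem(rng: np.random.Generator, k: int, alpha: float) -> np.ndarray:
    v = rng.beta(1.0, alpha, size=k - 1) if k > 1 else np.empty(0)
    w = np.empty(k)
    rest = 1.0
    for i in range(k - 1):
        w[i] = v[i] * rest
        rest *= 1.0 - v[i]
    w[k - 1] = rest
    return w


def sample_params_from_prior(hyper: Hyperparams, rng: np.random.Generator) -> PCFGParams:
    h = hyper.resolve()
    K, S = h.k_beta, h.k_gamma
    beta = _truncated_gem(rng, K, h.alpha)
    gamma = _truncated_gem(rng, S, h.alpha)
    root = rng.dirichlet(np.maximum(h.alpha * beta, 1e-8))
    branch_prob = rng.beta(1.0, 1.0, size=K)
    base_pair = np.maximum(h.alpha * np.outer(beta, beta).ravel(), 1e-8)
    branch = np.stack([rng.dirichlet(base_pair).reshape(K, K) for _ in range(K)])
    emit = np.stack([rng.dirichlet(np.maximum(h.alpha * gamma, 1e-8)) for _ in range(K)])
    means, covs = niw_prior(h, S).sample(rng)
    return PCFGParams(root=root, branch_prob=branch_prob, branch=branch,
                      emit=emit, means=means, covs=covs)


def generate(corpus_size: int, hyper: Hyperparams, seed: int | None,
             max_len: int = 30, params: PCFGParams | None = None,
             ) -> tuple[list[FeatureString], list[ParseTree], PCFGParams]:
    """Sample a corpus (and its latent parse trees) from the generative model.

    If ``params`` is given, strings are drawn from it; otherwise parameters
    are first sampled from the (truncated) prior.  Strings exceeding
    ``max_len`` are rejected and redrawn.
    """
    rng = np.random.default_rng(seed)
    if params is None:
        params = sample_params_from_prior(hyper, rng)
    corpus: list[FeatureString] = []
    trees: list[ParseTree] = []
    attempts = 0
    while len(corpus) < corpus_size:
        attempts += 1
        if attempts > 200 * corpus_size + 1000:
            raise RuntimeError("generation rejected too many over-long strings")
        tree = params.sample_tree(rng, max_len=max_len)
        if tree is None:
            continue
        X = params.emit_vectors(tree, rng)
        corpus.append(FeatureString(string_id=f"synth{len(corpus):05d}", vectors=X))
        trees.append(tree)
    return corpus, trees, params


# ---------------------------------------------------------------------------
# variational state
# ---------------------------------------------------------------------------

@dataclass
class VariationalStatePCFG:
    """All factor parameters of the truncated mean-field posterior."""

    hyper: Hyperparams
    beta: np.ndarray        # (K,) degenerate stick weights, non-terminals
    gamma: np.ndarray       # (S,) degenerate stick weights, terminals
    dir_root: np.ndarray    # (K,)
    dir_choice: np.ndarray  # (K, 2): [branch, emit]
    dir_branch: np.ndarray  # (K, K, K)
    dir_emit: np.ndarray    # (K, S)
    niw: NIW
    elbo_trace: list[float] = field(default_factory=list)
    n_sweeps: int = 0

    @property
    def k_beta(self) -> int:
        return self.dir_root.shape[0]

    @property
    def k_gamma(self) -> int:
        return self.dir_emit.shape[1]

    def base_counts(self) -> dict[str, np.ndarray]:
        """DP base counts implied by the current sticks (the prior counts)."""
        a = self.hyper.alpha
        K = self.k_beta
        return {
            "root": a * self.beta,
            "choice": np.ones((K, 2)),
            "branch": np.broadcast_to(a * np.outer(self.beta, self.beta),
                                      (K, K, K)).copy(),
            "emit": np.broadcast_to(a * self.gamma, (K, self.k_gamma)).copy(),
        }


def init_state(corpus: list[FeatureString], hyper: Hyperparams,
               rng: np.random.Generator, jitter: float = 0.05,
               mean_jitter: float = 2.0) -> VariationalStatePCFG:
    """Symmetry-broken initial state: base counts times (1 + small uniform
    jitter) and NIW means jittered around the prior mean by ``mean_jitter``
    times the per-axis sample spread.  The default spread of 2 sd covers
    the data range; tighter inits clump several components inside one data
    cluster and coordinate ascent then keeps the redundant copies."""
    X = np.concatenate([s.vectors for s in corpus])
    h = hyper.resolve(X)
    K, S = h.k_beta, h.k_gamma
    beta = np.full(K, 1.0 / K)
    gamma = np.full(S, 1.0 / S)
    prior = niw_prior(h, S)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    niw = NIW(mean=prior.mean + mean_jitter * sd * rng.standard_normal((S, h.dim)),
              kappa=prior.kappa.copy(), scale=prior.scale.copy(), dof=prior.dof.copy())
    state = VariationalStatePCFG(
        hyper=h, beta=beta, gamma=gamma,
        dir_root=np.empty(K), dir_choice=np.empty((K, 2)),
        dir_branch=np.empty((K, K, K)), dir_emit=np.empty((K, S)), niw=niw)
    base = state.base_counts()
    state.dir_root = base["root"] * (1 + jitter * rng.uniform(size=K))
    state.dir_choice = base["choice"] * (1 + jitter * rng.uniform(size=(K, 2)))
    state.dir_branch = base["branch"] * (1 + jitter * rng.uniform(size=(K, K, K)))
    state.dir_emit = base["emit"] * (1 + jitter * rng.uniform(size=(K, S)))
    return state


# ---------------------------------------------------------------------------
# expected-log weights and the E step
# ---------------------------------------------------------------------------

def expected_log_weights(state: VariationalStatePCFG) -> RuleWeightTable:
    """Rule weights exp(E_q[log phi]) from digamma differences (no leaves)."""
    choice = np.exp(dirichlet_expected_log(state.dir_choice, axis=1))
    return RuleWeightTable(
        root_w=np.exp(dirichlet_expected_log(state.dir_root)),
        branch_choice_w=choice[:, _BRANCH],
        emit_choice_w=choice[:, _EMIT],
        branch_w=np.exp(dirichlet_expected_log(
            state.dir_branch.reshape(state.k_beta, -1)
        ).reshape(state.dir_branch.shape)),
        emit_w=np.exp(dirichlet_expected_log(state.dir_emit, axis=1)),
    )


@dataclass
class PCFGStats:
    """Expected sufficient statistics accumulated over a corpus."""

    root: np.ndarray     # (K,)
    choice: np.ndarray   # (K, 2)
    branch: np.ndarray   # (K, K, K)
    emit: np.ndarray     # (K, S)
    resp: np.ndarray     # (total positions, S) terminal responsibilities
    x: np.ndarray        # (total positions, D)
    loglik: float        # sum of inside log normalizers


def _outside_chart(table: RuleWeightTable, inside: dict, l: int) -> dict:
    log_root, log_bc, _, log_branch, _ = table.logs()
    K = table.n_nonterminals
    outside = {(0, l): log_root.copy()}
    for width in range(l - 1, 0, -1):
        for i in range(l - width + 1):
            j = i + width
            acc = np.full(K, -np.inf)
            # as a left child of parent (i, j2), sibling (j, j2)
            for j2 in range(j + 1, l + 1):
                par = outside[(i, j2)] + log_bc  # (K,)
                contrib = logsumexp(
                    par[:, None, None] + log_branch
                    + inside[(j, j2)][None, None, :], axis=(0, 2))
                acc = np.logaddexp(acc, contrib)
            # as a right child of parent (i2, j), sibling (i2, i)
            for i2 in range(0, i):
                par = outside[(i2, j)] + log_bc
                contrib = logsumexp(
                    par[:, None, None] + log_branch
                    + inside[(i2, i)][None, :, None], axis=(0, 1))
                acc = np.logaddexp(acc, contrib)
            outside[(i, j)] = acc
    return outside


def _string_expectations(table: RuleWeightTable, string_id: str):
    """Inside-outside expected counts for one string (leaf scores attached)."""
    lls = table.leaf_log_score
    l = lls.shape[0]
    K, S = table.n_nonterminals, table.n_terminals
    log_root, log_bc, log_ec, log_branch, log_emit = table.logs()
    inside = inside_chart(table)
    logz = float(logsumexp(log_root + inside[(0, l)]))
    if not np.isfinite(logz):
        raise FloatingPointError(f"string {string_id!r} has -inf inside total")
    outside = _outside_chart(table, inside, l)

    root = np.exp(log_root + inside[(0, l)] - logz)
    choice = np.zeros((K, 2))
    branch = np.zeros((K, K, K))
    emit = np.zeros((K, S))
    resp = np.zeros((l, S))
    for i in range(l):
        e = np.exp(outside[(i, i + 1)][:, None] + log_ec[:, None] + log_emit
                   + lls[i][None, :] - logz)  # (K, S)
        emit += e
        choice[:, _EMIT] += e.sum(axis=1)
        resp[i] = e.sum(axis=0)
    for width in range(2, l + 1):
        for i in range(l - width + 1):
            j = i + width
            pref = outside[(i, j)] + log_bc  # (K,)
            for k in range(i + 1, j):
                t = np.exp(pref[:, None, None] + log_branch
                           + inside[(i, k)][None, :, None]
                           + inside[(k, j)][None, None, :] - logz)
                branch += t
                choice[:, _BRANCH] += t.sum(axis=(1, 2))
    return root, choice, branch, emit, resp, logz


def e_step(state: VariationalStatePCFG, corpus: list[FeatureString]) -> PCFGStats:
    """Inside-outside pass over the corpus under exp(E[log]) weights."""
    table = expected_log_weights(state)
    K, S = state.k_beta, state.k_gamma
    root = np.zeros(K)
    choice = np.zeros((K, 2))
    branch = np.zeros((K, K, K))
    emit = np.zeros((K, S))
    resps, xs = [], []
    loglik = 0.0
    for s in corpus:
        lls = state.niw.expected_log_gaussian(s.vectors)
        t = table.with_leaf_scores(lls, log=True)
        r, c, b, e, resp, logz = _string_expectations(t, s.string_id)
        root += r
        choice += c
        branch += b
        emit += e
        resps.append(resp)
        xs.append(s.vectors)
        loglik += logz
    return PCFGStats(root=root, choice=choice, branch=branch, emit=emit,
                     resp=np.concatenate(resps), x=np.concatenate(xs),
                     loglik=loglik)


# ---------------------------------------------------------------------------
# M step, sticks, ELBO
# ---------------------------------------------------------------------------

def m_step(state: VariationalStatePCFG, stats: PCFGStats,
           hyper: Hyperparams | None = None,
           update_sticks: bool = True) -> VariationalStatePCFG:
    """Conjugate updates (base counts + expected counts) then stick ascent."""
    h = (hyper or state.hyper).resolve()
    new = copy.deepcopy(state)
    base = state.base_counts()
    new.dir_root = base["root"] + stats.root
    new.dir_choice = base["choice"] + stats.choice
    new.dir_branch = base["branch"] + stats.branch
    new.dir_emit = base["emit"] + stats.emit
    new.niw = NIW.posterior(niw_prior(h, state.k_gamma), stats.resp, stats.x)
    if update_sticks:
        _update_sticks(new, stats)
    return new


def _update_sticks(state: VariationalStatePCFG, stats: PCFGStats) -> None:
    a = state.hyper.alpha
    elog_root = dirichlet_expected_log(state.dir_root)
    elog_branch = dirichlet_expected_log(
        state.dir_branch.reshape(state.k_beta, -1), axis=1
    ).reshape(state.dir_branch.shape)
    beta_usage = stats.root + stats.branch.sum(axis=(0, 2)) + stats.branch.sum(axis=(0, 1))
    state.beta = optimize_sticks(state.beta, beta_usage, a,
                                 simple_elogs=[elog_root],
                                 outer_elogs=list(elog_branch))
    elog_emit = dirichlet_expected_log(state.dir_emit, axis=1)
    gamma_usage = stats.emit.sum(axis=0)
    state.gamma = optimize_sticks(state.gamma, gamma_usage, a,
                                  simple_elogs=list(elog_emit))


def kl_penalty(state: VariationalStatePCFG) -> float:
    """KL of all parameter factors to their priors under the current sticks."""
    base = state.base_counts()
    kl = dirichlet_kl(state.dir_root, base["root"])
    for z in range(state.k_beta):
        kl += dirichlet_kl(state.dir_choice[z], base["choice"][z])
        kl += dirichlet_kl(state.dir_branch[z], base["branch"][z])
        kl += dirichlet_kl(state.dir_emit[z], base["emit"][z])
    kl += state.niw.kl_to(niw_prior(state.hyper, state.k_gamma)).sum()
    return float(kl)


def elbo(state: VariationalStatePCFG, corpus: list[FeatureString]) -> float:
    """Evidence lower bound with the parse factor at its optimum."""
    return float(e_step(state, corpus).loglik - kl_penalty(state))


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

def fit(corpus: list[FeatureString], hyper: Hyperparams,
        cfg: FitConfig | None = None,
        ) -> tuple[VariationalStatePCFG, RunRecord, list[RunRecord]]:
    """Multi-restart CAVI; returns the best state plus per-run records."""
    if not corpus:
        raise ValueError("corpus is empty")
    cfg = cfg or FitConfig()
    X = np.concatenate([s.vectors for s in corpus])
    h = hyper.resolve(X)

    def run_one(seed: int):
        rng = np.random.default_rng(seed)
        state = init_state(corpus, h, rng)
        record = RunRecord(seed=seed)
        state = cavi_run(
            state,
            e_step=lambda st: (lambda stats: (stats, stats.loglik))(e_step(st, corpus)),
            m_step=lambda st, stats: m_step(st, stats),
            kl_penalty=kl_penalty,
            tol=cfg.tol, max_iter=cfg.max_iter, record=record)
        state.elbo_trace = record.elbo_trace
        state.n_sweeps = record.n_sweeps
        return state, record

    return multi_restart(run_one, cfg)


# ---------------------------------------------------------------------------
# posterior predictive
# ---------------------------------------------------------------------------

def mean_rule_table(state: VariationalStatePCFG) -> RuleWeightTable:
    """Posterior-mean rule probabilities (a plug-in point estimate)."""
    choice = state.dir_choice / state.dir_choice.sum(axis=1, keepdims=True)
    return RuleWeightTable(
        root_w=state.dir_root / state.dir_root.sum(),
        branch_choice_w=choice[:, _BRANCH],
        emit_choice_w=choice[:, _EMIT],
        branch_w=state.dir_branch / state.dir_branch.sum(axis=(1, 2), keepdims=True),
        emit_w=state.dir_emit / state.dir_emit.sum(axis=1, keepdims=True),
    )


def posterior_predictive_logdensity(state: VariationalStatePCFG,
                                    string: FeatureString) -> tuple[float, float]:
    """Plug-in log predictive density of a string and its per-point value.

    Posterior-mean rule probabilities with the NIW Student-t emission
    predictive; the per-point value divides by the string length.
    """
    from .grammar import inside_log_normalizer

    lls = state.niw.predictive_logpdf(string.vectors)
    table = mean_rule_table(state).with_leaf_scores(lls, log=True)
    total = inside_log_normalizer(table)
    return total, total / len(string)


def posterior_predictive_logdensity_mc(state: VariationalStatePCFG,
                                       string: FeatureString,
                                       n_samples: int = 1000,
                                       seed: int | None = None,
                                       ) -> tuple[float, float, float]:
    """Monte-Carlo predictive: average p(x | theta) over q(theta) samples.

    Returns (log density, per-point value, MC standard error of the log).
    """
    from .grammar import inside_log_normalizer

    rng = np.random.default_rng(seed)
    K, S = state.k_beta, state.k_gamma
    logs = np.empty(n_samples)
    for m in range(n_samples):
        choice = np.stack([rng.dirichlet(state.dir_choice[z]) for z in range(K)])
        table = RuleWeightTable(
            root_w=rng.dirichlet(state.dir_root),
            branch_choice_w=choice[:, _BRANCH],
            emit_choice_w=choice[:, _EMIT],
            branch_w=np.stack([rng.dirichlet(state.dir_branch[z].ravel()).reshape(K, K)
                               for z in range(K)]),
            emit_w=np.stack([rng.dirichlet(state.dir_emit[z]) for z in range(K)]),
        )
        mus, covs = state.niw.sample(rng)
        lls = np.stack([multivariate_normal.logpdf(string.vectors, mus[s], covs[s],
                                                   allow_singular=True)
                        for s in range(S)], axis=-1).reshape(len(string), S)
        logs[m] = inside_log_normalizer(table.with_leaf_scores(lls, log=True))
    total = float(logsumexp(logs) - np.log(n_samples))
    # delta-method standard error of log-mean from the sample of p-values
    w = np.exp(logs - logs.max())
    se = float(w.std(ddof=1) / (np.sqrt(n_samples) * w.mean()))
    return total, total / len(string), se
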