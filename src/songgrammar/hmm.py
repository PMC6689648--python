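"""HDP-HMM with variable initial state and Gaussian emissions.

The baseline regular model: hidden states with Dirichlet-process-tied
initial and transition distributions, per-state Gaussian emissions with NIW
priors, and (optionally) a per-state termination switch so that string
lengths are generative.  Fitted by the same truncated mean-field coordinate
ascent as the PCFG — forward-backward E pass under exp(E[log .]) weights,
conjugate M updates, point-mass stick weights ``omega`` re-optimized
numerically — so the two models differ only in their grammar class.

``hmm_as_right_branching_pcfg`` makes the regular-grammars-are-PCFGs
equivalence executable: the HMM is compiled to a weight table whose only
derivations are right-branching and whose string scores equal the forward
algorithm's.
"""

from __future__ import annotations

import copy
import logging
from dataclasses import dataclass, field

import numpy as np
from .grammar import logsumexp

from .data import FeatureString
from .grammar import RuleWeightTable
from .inference import FitConfig, RunRecord, cavi_run, multi_restart
from .priors import NIW, Hyperparams, dirichlet_expected_log, dirichlet_kl, niw_prior
from .sticks import optimize_sticks

logger = logging.getLogger(__name__)

__all__ = [
    "HMMParams",
    "VariationalStateHMM",
    "generate_hmm",
    "fit_hmm",
    "forward_logdensity",
    "hmm_predictive_logdensity",
    "hmm_as_right_branching_pcfg",
]

_CONT, _STOP = 0, 1


# ---------------------------------------------------------------------------
# explicit parameters & generation
# ---------------------------------------------------------------------------

@dataclass
class HMMParams:
    """A concrete Gaussian-emission HMM with per-state stop probabilities."""

    init: np.ndarray   # (K,)
    trans: np.ndarray  # (K, K) row-normalized
    stop: np.ndarray   # (K,) termination probability after emitting
    means: np.ndarray  # (K, D)
    covs: np.ndarray   # (K, D, D)

    @property
    def n_states(self) -> int:
        return self.init.shape[0]

    def sample_path(self, rng: np.random.Generator, max_len: int = 100) -> list[int]:
        k = int(rng.choice(self.n_states, p=self.init))
        path = [k]
        while rng.random() >= self.stop[k] and len(path) < max_len:
            k = int(rng.choice(self.n_states, p=self.trans[k]))
            path.append(k)
        return path

    def emit_vectors(self, path: list[int], rng: np.random.Generator) -> np.ndarray:
        return np.stack([rng.multivariate_normal(self.means[k], self.covs[k])
                         for k in path])


def sample_hmm_from_prior(hyper: Hyperparams, rng: np.random.Generator) -> HMMParams:
    from .pcfg import _truncated_gem

    h = hyper.resolve()
    K = h.k_omega
    omega = _truncated_gem(rng, K, h.alpha)
    base = np.maximum(h.alpha * omega, 1e-8)
    init = rng.dirichlet(base)
    trans = np.stack([rng.dirichlet(base) for _ in range(K)])
    stop = rng.beta(1.0, 1.0, size=K)
    means, covs = niw_prior(h, K).sample(rng)
    return HMMParams(init=init, trans=trans, stop=stop, means=means, covs=covs)


def generate_hmm(corpus_size: int, hyper: Hyperparams, seed: int | None,
                 max_len: int = 100, params: HMMParams | None = None,
                 ) -> tuple[list[FeatureString], list[list[int]], HMMParams]:
    """Sample a corpus and its latent state paths (rejecting over-long ones)."""
    rng = np.random.default_rng(seed)
    if params is None:
        params = sample_hmm_from_prior(hyper, rng)
    corpus, paths = [], []
    attempts = 0
    while len(corpus) < corpus_size:
        attempts += 1
        if attempts > 200 * corpus_size + 1000:
            raise RuntimeError("generation rejected too many over-long paths")
        path = params.sample_path(rng, max_len=max_len + 1)
        if len(path) > max_len:
            continue
        X = params.emit_vectors(path, rng)
        corpus.append(FeatureString(string_id=f"hmm{len(corpus):05d}", vectors=X))
        paths.append(path)
    return corpus, paths, params


# ---------------------------------------------------------------------------
# variational state
# ---------------------------------------------------------------------------

@dataclass
class VariationalStateHMM:
    hyper: Hyperparams
    omega: np.ndarray      # (K,) degenerate stick weights over states
    dir_init: np.ndarray   # (K,)
    dir_trans: np.ndarray  # (K, K)
    dir_stop: np.ndarray   # (K, 2): [continue, stop]
    niw: NIW
    model_termination: bool = True
    elbo_trace: list[float] = field(default_factory=list)
    n_sweeps: int = 0

    @property
    def k_omega(self) -> int:
        return self.dir_init.shape[0]

    def base_counts(self) -> dict[str, np.ndarray]:
        a = self.hyper.alpha
        K = self.k_omega
        return {
            "init": a * self.omega,
            "trans": np.broadcast_to(a * self.omega, (K, K)).copy(),
            "stop": np.ones((K, 2)),
        }


def init_state_hmm(corpus: list[FeatureString], hyper: Hyperparams,
                   rng: np.random.Generator, jitter: float = 0.05,
                   mean_jitter: float = 2.0,
                   model_termination: bool = True) -> VariationalStateHMM:
    X = np.concatenate([s.vectors for s in corpus])
    h = hyper.resolve(X)
    K = h.k_omega
    omega = np.full(K, 1.0 / K)
    prior = niw_prior(h, K)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    niw = NIW(mean=prior.mean + mean_jitter * sd * rng.standard_normal((K, h.dim)),
              kappa=prior.kappa.copy(), scale=prior.scale.copy(), dof=prior.dof.copy())
    state = VariationalStateHMM(
        hyper=h, omega=omega, dir_init=np.empty(K), dir_trans=np.empty((K, K)),
        dir_stop=np.empty((K, 2)), niw=niw, model_termination=model_termination)
    base = state.base_counts()
    state.dir_init = base["init"] * (1 + jitter * rng.uniform(size=K))
    state.dir_trans = base["trans"] * (1 + jitter * rng.uniform(size=(K, K)))
    state.dir_stop = base["stop"] * (1 + jitter * rng.uniform(size=(K, 2)))
    return state


# ---------------------------------------------------------------------------
# forward-backward
# ---------------------------------------------------------------------------

def _expected_log_params(state: VariationalStateHMM):
    log_init = dirichlet_expected_log(state.dir_init)
    log_trans = dirichlet_expected_log(state.dir_trans, axis=1)
    log_stopc = dirichlet_expected_log(state.dir_stop, axis=1)
    return log_init, log_trans, log_stopc[:, _CONT], log_stopc[:, _STOP]


def forward_logdensity(log_init: np.ndarray, log_trans: np.ndarray,
                       log_cont: np.ndarray, log_stop: np.ndarray | None,
                       em: np.ndarray) -> float:
    """Forward-algorithm log total over state paths for one string.

    ``em`` is (l, K) per-position log emission scores; pass ``log_stop``
    as None to score fixed-length sequences without a termination factor
    (``log_cont`` is then ignored too).
    """
    f = log_init + em[0]
    for t in range(1, em.shape[0]):
        step = log_trans if log_stop is None else log_cont[:, None] + log_trans
        f = logsumexp(f[:, None] + step, axis=0) + em[t]
    if log_stop is not None:
        f = f + log_stop
    return float(logsumexp(f))


@dataclass
class HMMStats:
    init: np.ndarray   # (K,)
    trans: np.ndarray  # (K, K)
    stop: np.ndarray   # (K, 2): [continue, stop]
    resp: np.ndarray   # (total positions, K)
    x: np.ndarray
    loglik: float


def e_step_hmm(state: VariationalStateHMM, corpus: list[FeatureString]) -> HMMStats:
    log_init, log_trans, log_cont, log_stop = _expected_log_params(state)
    K = state.k_omega
    use_stop = state.model_termination
    init_c = np.zeros(K)
    trans_c = np.zeros((K, K))
    stop_c = np.zeros((K, 2))
    resps, xs = [], []
    loglik = 0.0
    for s in corpus:
        em = state.niw.expected_log_gaussian(s.vectors)
        l = em.shape[0]
        step = (log_cont[:, None] + log_trans) if use_stop else log_trans
        # forward
        f = np.empty((l, K))
        f[0] = log_init + em[0]
        for t in range(1, l):
            f[t] = logsumexp(f[t - 1][:, None] + step, axis=0) + em[t]
        last = f[l - 1] + (log_stop if use_stop else 0.0)
        logz = float(logsumexp(last))
        if not np.isfinite(logz):
            raise FloatingPointError(f"string {s.string_id!r} has -inf forward total")
        # backward
        b = np.empty((l, K))
        b[l - 1] = log_stop if use_stop else 0.0
        for t in range(l - 2, -1, -1):
            b[t] = logsumexp(step + (em[t + 1] + b[t + 1])[None, :], axis=1)
        gamma = np.exp(f + b - logz)
        init_c += gamma[0]
        for t in range(l - 1):
            xi = np.exp(f[t][:, None] + step + (em[t + 1] + b[t + 1])[None, :] - logz)
            trans_c += xi
        if use_stop:
            stop_c[:, _CONT] += gamma[:-1].sum(axis=0)
            stop_c[:, _STOP] += gamma[-1]
        resps.append(gamma)
        xs.append(s.vectors)
        loglik += logz
    return HMMStats(init=init_c, trans=trans_c, stop=stop_c,
                    resp=np.concatenate(resps), x=np.concatenate(xs), loglik=loglik)


def m_step_hmm(state: VariationalStateHMM, stats: HMMStats,
               update_sticks: bool = True) -> VariationalStateHMM:
    new = copy.deepcopy(state)
    base = state.base_counts()
    new.dir_init = base["init"] + stats.init
    new.dir_trans = base["trans"] + stats.trans
    new.dir_stop = base["stop"] + stats.stop
    new.niw = NIW.posterior(niw_prior(state.hyper, state.k_omega), stats.resp, stats.x)
    if update_sticks:
        elog_init = dirichlet_expected_log(new.dir_init)
        elog_trans = dirichlet_expected_log(new.dir_trans, axis=1)
        usage = stats.init + stats.trans.sum(axis=0)
        new.omega = optimize_sticks(new.omega, usage, state.hyper.alpha,
                                    simple_elogs=[elog_init] + list(elog_trans))
    return new


def kl_penalty_hmm(state: VariationalStateHMM) -> float:
    base = state.base_counts()
    kl = dirichlet_kl(state.dir_init, base["init"])
    for k in range(state.k_omega):
        kl += dirichlet_kl(state.dir_trans[k], base["trans"][k])
        if state.model_termination:
            kl += dirichlet_kl(state.dir_stop[k], base["stop"][k])
    kl += state.niw.kl_to(niw_prior(state.hyper, state.k_omega)).sum()
    return float(kl)


def elbo_hmm(state: VariationalStateHMM, corpus: list[FeatureString]) -> float:
    return float(e_step_hmm(state, corpus).loglik - kl_penalty_hmm(state))


def fit_hmm(corpus: list[FeatureString], hyper: Hyperparams,
            cfg: FitConfig | None = None, model_termination: bool = True,
            ) -> tuple[VariationalStateHMM, RunRecord, list[RunRecord]]:
    """Multi-restart CAVI for the HMM; same engine and policy as the PCFG."""
    if not corpus:
        raise ValueError("corpus is empty")
    cfg = cfg or FitConfig()
    X = np.concatenate([s.vectors for s in corpus])
    h = hyper.resolve(X)

    def run_one(seed: int):
        rng = np.random.default_rng(seed)
        state = init_state_hmm(corpus, h, rng, model_termination=model_termination)
        record = RunRecord(seed=seed)
        state = cavi_run(
            state,
            e_step=lambda st: (lambda stats: (stats, stats.loglik))(e_step_hmm(st, corpus)),
            m_step=lambda st, stats: m_step_hmm(st, stats),
            kl_penalty=kl_penalty_hmm,
            tol=cfg.tol, max_iter=cfg.max_iter, record=record)
        state.elbo_trace = record.elbo_trace
        state.n_sweeps = record.n_sweeps
        return state, record

    return multi_restart(run_one, cfg)


# ---------------------------------------------------------------------------
# predictive density & the right-branching PCFG construction
# ---------------------------------------------------------------------------

def mean_params(state: VariationalStateHMM) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Posterior-mean (init, trans, cont, stop) probabilities."""
    init = state.dir_init / state.dir_init.sum()
    trans = state.dir_trans / state.dir_trans.sum(axis=1, keepdims=True)
    sc = state.dir_stop / state.dir_stop.sum(axis=1, keepdims=True)
    return init, trans, sc[:, _CONT], sc[:, _STOP]


def hmm_predictive_logdensity(state: VariationalStateHMM,
                              string: FeatureString) -> tuple[float, float]:
    """Plug-in log predictive (posterior-mean transitions, Student-t
    emissions) and the per-point value."""
    init, trans, cont, stop = mean_params(state)
    em = state.niw.predictive_logpdf(string.vectors)
    with np.errstate(divide="ignore"):
        total = forward_logdensity(
            np.log(init), np.log(trans), np.log(cont),
            np.log(stop) if state.model_termination else None, em)
    return total, total / len(string)


def hmm_as_right_branching_pcfg(init: np.ndarray, trans: np.ndarray,
                                cont: np.ndarray, stop: np.ndarray,
                                ) -> RuleWeightTable:
    """Compile fixed HMM parameters into a right-branching PCFG weight table.

    Non-terminal layout over 2K symbols: ``A_k = k`` continues the state
    sequence from state ``k``; ``E_k = K + k`` immediately emits terminal
    ``k``.  The only branch rules are ``A_k -> E_k A_j`` with weight
    ``cont[k] * trans[k, j]``; ``A_k`` emits terminal ``k`` with weight
    ``stop[k]``.  Terminal ``k`` scores observations with the HMM's state-k
    emission density, so every derivation is right-branching and the inside
    total equals the forward total.
    """
    init = np.asarray(init, float)
    K = init.shape[0]
    root_w = np.concatenate([init, np.zeros(K)])
    branch_choice_w = np.concatenate([np.ones(K), np.zeros(K)])
    emit_choice_w = np.ones(2 * K)
    branch_w = np.zeros((2 * K, 2 * K, 2 * K))
    for k in range(K):
        branch_w[k, K + k, :K] = cont[k] * np.asarray(trans, float)[k]
    emit_w = np.zeros((2 * K, K))
    emit_w[np.arange(K), np.arange(K)] = np.asarray(stop, float)
    emit_w[K + np.arange(K), np.arange(K)] = 1.0
    return RuleWeightTable(root_w=root_w, branch_choice_w=branch_choice_w,
                           emit_choice_w=emit_choice_w, branch_w=branch_w,
                           emit_w=emit_w)


def state_as_right_branching_pcfg(state: VariationalStateHMM) -> RuleWeightTable:
    """The construction applied to a trained state's posterior means."""
    init, trans, cont, stop = mean_params(state)
    if not state.model_termination:
        cont, stop = np.ones_like(cont), np.ones_like(stop)
    return hmm_as_right_branching_pcfg(init, trans, cont, stop)
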