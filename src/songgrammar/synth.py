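"""Synthetic inputs with known ground truth.

Feature-string corpora come from explicit PCFGs/HMMs with Gaussian
emissions: purely right-/left-branching grammars (regular), a
centre-embedding grammar producing matched a^m b^m pairs over two emission
clusters (non-regular for l >= 4, depth capped at 3), random PCFGs, and
HMMs.  Emission clusters sit on a configurable mean-separation scale (in
pooled-sigma units) so recovery difficulty is controlled.

Pulse-train audio — band-limited carrier bursts over a noise floor —
exercises the acoustic front-end without recordings.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .data import FeatureString
from .frontend import AudioSignal
from .grammar import ParseTree
from .hmm import HMMParams
from .pcfg import PCFGParams, _renumber_positions

logger = logging.getLogger(__name__)

__all__ = [
    "GroundTruthGrammar",
    "PulseTrainSpec",
    "make_grammar",
    "sample_corpus",
    "synthesize_pulse_audio",
]

_KINDS = ("right_branching", "left_branching", "center_embedding",
          "random_pcfg", "hmm")


def cluster_means(n_clusters: int, dim: int, separation: float,
                  sigma: float = 1.0) -> np.ndarray:
    """Cluster means spaced ``separation`` pooled-sigma units apart along
    the first axis, centred at the origin."""
    means = np.zeros((n_clusters, dim))
    offs = (np.arange(n_clusters) - (n_clusters - 1) / 2.0) * separation * sigma
    means[:, 0] = offs
    return means


@dataclass
class GroundTruthGrammar:
    """A known generator: either PCFG params or HMM params, plus its kind."""

    kind: str
    pcfg: PCFGParams | None = None
    hmm: HMMParams | None = None
    continue_prob: float = 0.8
    max_depth: int = 3  # centre-embedding only

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValueError(f"unknown grammar kind {self.kind!r}")
        if (self.kind == "hmm") != (self.hmm is not None):
            raise ValueError("hmm kind requires hmm params (and only then)")


def make_grammar(kind: str, dim: int = 13, separation: float = 5.0,
                 sigma: float = 1.0, continue_prob: float = 0.82,
                 n_states: int = 2, seed: int | None = None) -> GroundTruthGrammar:
    """Build a ground-truth grammar of the requested kind.

    ``continue_prob`` tunes the length profile; the default 0.82 puts
    roughly 55% of regular-grammar strings at length >= 4 (0.82^3 = 0.55),
    echoing the long-string share of the study's training corpus.
    """
    covs2 = np.stack([np.eye(dim) * sigma ** 2] * 2)
    means2 = cluster_means(2, dim, separation, sigma)
    if kind in ("right_branching", "left_branching"):
        # A (label 0) recurses; E (label 1) emits terminal 0; A's own
        # emission closes the string with terminal 1.
        p = continue_prob
        branch = np.zeros((2, 2, 2))
        if kind == "right_branching":
            branch[0, 1, 0] = 1.0  # A -> E A
        else:
            branch[0, 0, 1] = 1.0  # A -> A E
        emit = np.array([[0.0, 1.0], [1.0, 0.0]])
        params = PCFGParams(root=np.array([1.0, 0.0]),
                            branch_prob=np.array([p, 0.0]),
                            branch=branch, emit=emit,
                            means=means2, covs=covs2)
        return GroundTruthGrammar(kind=kind, pcfg=params, continue_prob=p)
    if kind == "center_embedding":
        # labels: S=0, Y=1, A=2 (emits a), B=3 (emits b).  S -> A Y always;
        # Y -> S B with prob 1/2 (one level deeper) or emits b to close, so
        # strings are exactly a^m b^m with geometric depth.
        branch = np.zeros((4, 4, 4))
        branch[0, 2, 1] = 1.0  # S -> A Y
        branch[1, 0, 3] = 1.0  # Y -> S B
        emit = np.zeros((4, 2))
        emit[2, 0] = 1.0  # a cluster
        emit[3, 1] = 1.0  # b cluster
        emit[1, 1] = 1.0  # Y closing emission is also a b
        params = PCFGParams(root=np.array([1.0, 0.0, 0.0, 0.0]),
                            branch_prob=np.array([1.0, 0.5, 0.0, 0.0]),
                            branch=branch, emit=emit,
                            means=means2, covs=covs2)
        return GroundTruthGrammar(kind=kind, pcfg=params, continue_prob=0.5)
    if kind == "random_pcfg":
        rng = np.random.default_rng(seed)
        K, S = 3, 3
        branch = np.stack([rng.dirichlet(np.ones(K * K)).reshape(K, K)
                           for _ in range(K)])
        params = PCFGParams(
            root=rng.dirichlet(np.ones(K)),
            branch_prob=rng.uniform(0.3, 0.7, K),
            branch=branch,
            emit=np.stack([rng.dirichlet(np.ones(S)) for _ in range(K)]),
            means=cluster_means(S, dim, separation, sigma),
            covs=np.stack([np.eye(dim) * sigma ** 2] * S))
        return GroundTruthGrammar(kind=kind, pcfg=params)
    if kind == "hmm":
        stop = 1.0 - continue_prob
        params = HMMParams(init=np.array([1.0, 0.0]),
                           trans=np.array([[0.0, 1.0], [1.0, 0.0]]),
                           stop=np.full(n_states, stop),
                           means=means2, covs=covs2)
        return GroundTruthGrammar(kind="hmm", hmm=params)
    raise ValueError(f"unknown grammar kind {kind!r}")


def _center_embedding_tree(depth: int) -> ParseTree:
    """The matched-pair tree for a^depth b^depth (labels as in make_grammar)."""
    # innermost: S -> A B? in our encoding the innermost Y emits b.
    # Build top-down: S(0) -> A(2):a  Y(1);  Y -> S B(3):b  (recurse) or Y:b.
    def s_node(d: int) -> ParseTree:
        a = ParseTree(label=2, terminal=0, pos=-1)
        return ParseTree(label=0, left=a, right=y_node(d))

    def y_node(d: int) -> ParseTree:
        if d <= 1:
            return ParseTree(label=1, terminal=1, pos=-1)
        return ParseTree(label=1, left=s_node(d - 1),
                         right=ParseTree(label=3, terminal=1, pos=-1))

    return _renumber_positions(s_node(depth))


def sample_corpus(grammar: GroundTruthGrammar, n: int, seed: int | None,
                  max_len: int = 30) -> tuple[list[FeatureString], list]:
    """n feature strings plus their latent structures (trees or paths).

    Over-long strings are rejected and redrawn (logged).  Centre-embedding
    strings are drawn by depth (geometric(1/2) truncated at ``max_depth``)
    so the fixture stays exactly matched a^m b^m.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    corpus: list[FeatureString] = []
    latents: list = []
    rejected = 0
    if grammar.kind == "hmm":
        params = grammar.hmm
        while len(corpus) < n:
            path = params.sample_path(rng, max_len=max_len + 1)
            if len(path) > max_len:
                rejected += 1
                continue
            X = params.emit_vectors(path, rng)
            corpus.append(FeatureString(f"hmm{len(corpus):05d}", X))
            latents.append(path)
    elif grammar.kind == "center_embedding":
        params = grammar.pcfg
        depths = np.minimum(rng.geometric(1 - grammar.continue_prob, size=n),
                            grammar.max_depth)
        for i, d in enumerate(depths):
            tree = _center_embedding_tree(int(d))
            X = params.emit_vectors(tree, rng)
            corpus.append(FeatureString(f"ce{i:05d}", X))
            latents.append(tree)
    else:
        params = grammar.pcfg
        while len(corpus) < n:
            tree = params.sample_tree(rng, max_len=max_len)
            if tree is None:
                rejected += 1
                if rejected > 200 * n + 1000:
                    raise RuntimeError("too many rejected strings")
                continue
            X = params.emit_vectors(tree, rng)
            corpus.append(FeatureString(f"{grammar.kind[:2]}{len(corpus):05d}", X))
            latents.append(tree)
    if rejected:
        logger.info("rejected %d over-long string(s)", rejected)
    return corpus, latents


# ---------------------------------------------------------------------------
# pulse-train audio
# ---------------------------------------------------------------------------

@dataclass
class PulseTrainSpec:
    """Carrier bursts at given times inside planted song regions.

    Each planted region carries a sustained carrier tone at
    ``base_amplitude`` (so the band-energy ratio stays high throughout) and
    the pulses add Hann-enveloped bursts of ``amplitude`` on top, their
    apices at pulse time + half the pulse width.  Outside the regions only
    the broadband noise floor remains.  If ``regions`` is omitted, a single
    region covering all pulses (with 100 ms margins) is planted.
    """

    pulse_times: list[float] = field(default_factory=list)
    regions: list[tuple[float, float]] | None = None
    carrier: float = 1000.0
    pulse_width: float = 0.080
    amplitude: float = 10.0
    # below the default 1.0 prominence threshold, so the sustained carrier
    # alone never yields a peak candidate at region onsets
    base_amplitude: float = 0.4
    noise_floor: float = 0.01
    rate: float = 16000.0
    duration: float | None = None

    def __post_init__(self) -> None:
        if self.carrier >= self.rate / 2:
            raise ValueError("carrier must be below Nyquist")
        if self.regions is None and self.pulse_times:
            start = max(0.0, min(self.pulse_times) - 0.1)
            end = max(self.pulse_times) + self.pulse_width + 0.1
            end = max(end, start + 0.6)  # satisfy the 500 ms region minimum
            self.regions = [(start, end)]
        self.regions = self.regions or []
        if self.duration is None:
            last = max([t + self.pulse_width for t in self.pulse_times]
                       + [e for _, e in self.regions] + [0.0])
            self.duration = last + 0.3
        for t in self.pulse_times:
            if t < 0 or t + self.pulse_width > self.duration:
                raise ValueError(f"pulse at {t}s falls outside the signal")
            if not any(s <= t and t + self.pulse_width <= e for s, e in self.regions):
                raise ValueError(f"pulse at {t}s lies outside every planted region")

    def apex_times(self) -> list[float]:
        return [t + self.pulse_width / 2 for t in self.pulse_times]


def synthesize_pulse_audio(spec: PulseTrainSpec, seed: int | None = None) -> AudioSignal:
    """Render the pulse train described by ``spec`` (WAV-writable)."""
    rng = np.random.default_rng(seed)
    n = int(round(spec.duration * spec.rate))
    x = spec.noise_floor * rng.standard_normal(n)
    tt = np.arange(n) / spec.rate
    for s, e in spec.regions:
        i0, i1 = int(round(s * spec.rate)), min(int(round(e * spec.rate)), n)
        x[i0:i1] += spec.base_amplitude * np.sin(2 * np.pi * spec.carrier * tt[i0:i1])
    nw = int(round(spec.pulse_width * spec.rate))
    t = np.arange(nw) / spec.rate
    burst_env = np.hanning(nw)
    for t0 in spec.pulse_times:
        i0 = int(round(t0 * spec.rate))
        burst = spec.amplitude * burst_env * np.sin(2 * np.pi * spec.carrier * t)
        m = max(0, min(nw, n - i0))
        x[i0:i0 + m] += burst[:m]
    return AudioSignal(samples=x, rate=spec.rate)
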