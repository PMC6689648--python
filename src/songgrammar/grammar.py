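"""Parse trees, branching taxonomy, and weighted dynamic programming.

The grammar class is binary-branching with a variable root: every node
carries a non-terminal label ``z``; a node either branches into an ordered
pair of children or emits a terminal ``s`` at one string position, where the
terminal scores the observed vector through a per-position leaf score.
The weight of a labeled parse is the product of its rule weights and leaf
scores; rule weights are arbitrary non-negative numbers (in inference they
are exponentials of expected logs, hence unnormalized).

Two execution routes are provided for every quantity: an O(l^3 K^2)-style
chart (``inside_log_normalizer``, ``viterbi_parse``) and brute-force
enumeration oracles (``enumerate_topologies``, ``enumerate_labeled_trees``)
used to validate the charts in tests.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, replace
from enum import Enum
from functools import lru_cache
from typing import Iterator

import numpy as np


def logsumexp(a, axis=None):
    """Max-shifted log-sum-exp; leaner than scipy's for the small arrays
    the charts use (called O(l^3) times per string per sweep)."""
    a = np.asarray(a, dtype=float)
    m = np.max(a, axis=axis, keepdims=True)
    m = np.where(np.isfinite(m), m, 0.0)
    with np.errstate(divide="ignore"):
        out = np.log(np.sum(np.exp(a - m), axis=axis))
    if axis is None:
        return float(out + m.ravel()[0])
    return out + np.squeeze(m, axis=axis)


__all__ = [
    "TopologyClass",
    "ParseTree",
    "RuleWeightTable",
    "count_parses",
    "enumerate_topologies",
    "classify_topology",
    "regular_tree",
    "inside_log_normalizer",
    "parse_posterior",
    "viterbi_parse",
    "tree_log_weight",
    "topology_log_inside",
    "enumerate_labeled_trees",
    "tree_to_string",
    "tree_from_string",
]

_MAX_ENUM_LEN = 12


class TopologyClass(Enum):
    LEFT = "left"
    RIGHT = "right"
    BOTH_REGULAR = "both_regular"
    NONREGULAR = "nonregular"


@dataclass(frozen=True)
class ParseTree:
    """A labeled binary parse node.

    A leaf has ``terminal``/``pos`` set and no children; an internal node
    has both children and no terminal.  The root node's ``label`` is the
    variable root symbol.
    """

    label: int
    left: "ParseTree | None" = None
    right: "ParseTree | None" = None
    terminal: int | None = None
    pos: int | None = None

    @property
    def is_leaf(self) -> bool:
        return self.terminal is not None

    def __post_init__(self) -> None:
        if self.is_leaf:
            if self.left is not None or self.right is not None or self.pos is None:
                raise ValueError("leaf nodes carry a position and no children")
        elif self.left is None or self.right is None:
            raise ValueError("internal nodes need exactly two children")

    def __len__(self) -> int:
        return 1 if self.is_leaf else len(self.left) + len(self.right)

    def topology(self):
        """Unlabeled shape: a leaf is its position, an internal node a pair."""
        if self.is_leaf:
            return self.pos
        return (self.left.topology(), self.right.topology())

    def leaves(self) -> list["ParseTree"]:
        if self.is_leaf:
            return [self]
        return self.left.leaves() + self.right.leaves()


# ---------------------------------------------------------------------------
# topology combinatorics
# ---------------------------------------------------------------------------

def count_parses(l: int) -> int:
    """Number of binary tree topologies over ``l`` leaves: Catalan(l-1)."""
    if l < 1:
        raise ValueError(f"string length must be >= 1, got {l}")
    n = l - 1
    return math.comb(2 * n, n) // (n + 1)


@lru_cache(maxsize=None)
def _span_topologies(i: int, j: int) -> tuple:
    if j - i == 1:
        return (i,)
    out = []
    for k in range(i + 1, j):
        for lt in _span_topologies(i, k):
            for rt in _span_topologies(k, j):
                out.append((lt, rt))
    return tuple(out)


def enumerate_topologies(l: int) -> list:
    """All distinct binary topologies over positions 0..l-1 (l <= 12)."""
    if l < 1:
        raise ValueError(f"string length must be >= 1, got {l}")
    if l > _MAX_ENUM_LEN:
        raise ValueError(f"enumeration guarded at l <= {_MAX_ENUM_LEN}, got {l}")
    return list(_span_topologies(0, l))


def _topo_len(topo) -> int:
    if isinstance(topo, int):
        return 1
    return _topo_len(topo[0]) + _topo_len(topo[1])


def classify_topology(tree) -> TopologyClass:
    """Branching class of a parse: LEFT/RIGHT regular, or NONREGULAR.

    Accepts a :class:`ParseTree` or a nested-tuple topology.  Strings of
    length <= 2 have a unique parse that is both left- and right-branching.
    """
    topo = tree.topology() if isinstance(tree, ParseTree) else tree
    l = _topo_len(topo)
    if l <= 2:
        return TopologyClass.BOTH_REGULAR

    def all_right_children_leaves(t) -> bool:
        if isinstance(t, int):
            return True
        return isinstance(t[1], int) and all_right_children_leaves(t[0])

    def all_left_children_leaves(t) -> bool:
        if isinstance(t, int):
            return True
        return isinstance(t[0], int) and all_left_children_leaves(t[1])

    if all_right_children_leaves(topo):
        return TopologyClass.LEFT
    if all_left_children_leaves(topo):
        return TopologyClass.RIGHT
    return TopologyClass.NONREGULAR


def regular_tree(l: int, side: TopologyClass):
    """The unique fully left- or right-branching topology over ``l`` leaves."""
    if l < 1:
        raise ValueError(f"string length must be >= 1, got {l}")
    if side not in (TopologyClass.LEFT, TopologyClass.RIGHT):
        raise ValueError("side must be LEFT or RIGHT")
    if side is TopologyClass.LEFT:
        topo = 0
        for i in range(1, l):
            topo = (topo, i)
    else:
        topo = l - 1
        for i in range(l - 2, -1, -1):
            topo = (i, topo)
    return topo


# ---------------------------------------------------------------------------
# weight tables
# ---------------------------------------------------------------------------

def _safe_log(x: np.ndarray) -> np.ndarray:
    with np.errstate(divide="ignore"):
        return np.log(np.asarray(x, dtype=float))


@dataclass
class RuleWeightTable:
    """Non-negative weights for every rule of the binary grammar.

    ``root_w[z]`` scores choosing ``z`` as the root label;
    ``branch_choice_w[z]``/``emit_choice_w[z]`` score the branch-vs-emit
    decision at a node labeled ``z``; ``branch_w[z, y1, y2]`` scores the
    ordered child pair; ``emit_w[z, s]`` scores emitting terminal ``s``.
    ``leaf_log_score[pos, s]`` is the log density of the observation at
    ``pos`` under terminal ``s`` (log form avoids underflow; use
    :meth:`with_leaf_scores` to attach linear densities).
    """

    root_w: np.ndarray
    branch_choice_w: np.ndarray
    emit_choice_w: np.ndarray
    branch_w: np.ndarray
    emit_w: np.ndarray
    leaf_log_score: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.root_w = np.asarray(self.root_w, dtype=float)
        self.branch_choice_w = np.asarray(self.branch_choice_w, dtype=float)
        self.emit_choice_w = np.asarray(self.emit_choice_w, dtype=float)
        self.branch_w = np.asarray(self.branch_w, dtype=float)
        self.emit_w = np.asarray(self.emit_w, dtype=float)
        K = self.root_w.shape[0]
        S = self.emit_w.shape[1]
        if self.branch_w.shape != (K, K, K) or self.emit_w.shape != (K, S):
            raise ValueError("inconsistent truncation dimensions in weight table")
        for arr in (self.root_w, self.branch_choice_w, self.emit_choice_w,
                    self.branch_w, self.emit_w):
            if np.any(arr < 0):
                raise ValueError("rule weights must be non-negative")
        if self.leaf_log_score is not None:
            self.leaf_log_score = np.asarray(self.leaf_log_score, dtype=float)
            if self.leaf_log_score.ndim != 2 or self.leaf_log_score.shape[1] != S:
                raise ValueError("leaf scores must be (l, n_terminals)")

    @property
    def n_nonterminals(self) -> int:
        return self.root_w.shape[0]

    @property
    def n_terminals(self) -> int:
        return self.emit_w.shape[1]

    def with_leaf_scores(self, scores: np.ndarray, log: bool = False) -> "RuleWeightTable":
        scores = np.asarray(scores, dtype=float)
        return replace(self, leaf_log_score=scores if log else _safe_log(scores))

    def _require_leaves(self, l: int | None) -> np.ndarray:
        if self.leaf_log_score is None:
            if l is None:
                raise ValueError("no leaf scores attached and no length given")
            return np.zeros((l, self.n_terminals))  # unit leaf scores
        if l is not None and l != self.leaf_log_score.shape[0]:
            raise ValueError("requested length disagrees with attached leaf scores")
        return self.leaf_log_score

    def logs(self):
        return (_safe_log(self.root_w), _safe_log(self.branch_choice_w),
                _safe_log(self.emit_choice_w), _safe_log(self.branch_w),
                _safe_log(self.emit_w))


# ---------------------------------------------------------------------------
# chart algorithms (log space, half-open spans [i, j))
# ---------------------------------------------------------------------------

def inside_chart(table: RuleWeightTable, l: int | None = None) -> dict:
    """Inside log-sums over half-open spans: chart[(i, j)][z]."""
    lls = table._require_leaves(l)
    l = lls.shape[0]
    log_root, log_bc, log_ec, log_branch, log_emit = table.logs()
    chart: dict = {}
    leaf_zs = log_ec[:, None] + log_emit  # (K, S)
    for i in range(l):
        chart[(i, i + 1)] = logsumexp(leaf_zs + lls[i][None, :], axis=1)
    for width in range(2, l + 1):
        for i in range(l - width + 1):
            j = i + width
            pair = np.full((table.n_nonterminals,) * 2, -np.inf)
            for k in range(i + 1, j):
                cand = chart[(i, k)][:, None] + chart[(k, j)][None, :]
                pair = np.logaddexp(pair, cand)
            chart[(i, j)] = log_bc + logsumexp(
                log_branch + pair[None, :, :], axis=(1, 2))
    return chart


def inside_log_normalizer(table: RuleWeightTable, l: int | None = None) -> float:
    """Log total weight of all labeled parses (the chart normalizer)."""
    lls = table._require_leaves(l)
    l = lls.shape[0]
    chart = inside_chart(table, l)
    log_root = table.logs()[0]
    return float(logsumexp(log_root + chart[(0, l)]))


def tree_log_weight(table: RuleWeightTable, tree: ParseTree) -> float:
    """Log weight of one fully labeled parse under the table."""
    lls = table._require_leaves(len(tree))
    log_root, log_bc, log_ec, log_branch, log_emit = table.logs()

    def rec(node: ParseTree) -> float:
        if node.is_leaf:
            return float(log_ec[node.label] + log_emit[node.label, node.terminal]
                         + lls[node.pos, node.terminal])
        return float(log_bc[node.label]
                     + log_branch[node.label, node.left.label, node.right.label]
                     + rec(node.left) + rec(node.right))

    return float(log_root[tree.label]) + rec(tree)


def topology_log_inside(table: RuleWeightTable, topo) -> float:
    """Log sum of weights over all labelings of one fixed topology.

    Used for the left-/right-branching totals, where the topology is
    pinned but labels are marginalized.
    """
    lls = table._require_leaves(_topo_len(topo))
    log_root, log_bc, log_ec, log_branch, log_emit = table.logs()
    leaf_zs = log_ec[:, None] + log_emit

    def rec(node) -> np.ndarray:
        if isinstance(node, int):
            return logsumexp(leaf_zs + lls[node][None, :], axis=1)
        vl, vr = rec(node[0]), rec(node[1])
        pair = vl[:, None] + vr[None, :]
        return log_bc + logsumexp(log_branch + pair[None, :, :], axis=(1, 2))

    return float(logsumexp(log_root + rec(topo)))


def parse_posterior(table: RuleWeightTable, tree: ParseTree) -> float:
    """Posterior probability of a labeled parse: its weight over the total."""
    lw = tree_log_weight(table, tree)
    logz = inside_log_normalizer(table, len(tree))
    if lw == -np.inf and logz == -np.inf:
        return 0.0
    return float(np.exp(lw - logz))


def viterbi_parse(table: RuleWeightTable, l: int | None = None) -> tuple[ParseTree, float]:
    """Highest-weight labeled parse and its log weight.

    Ties break deterministically: splits are scanned left to right and only
    strict improvements replace the incumbent, so equal-weight alternatives
    resolve to the earliest split point — under uniform weights this yields
    the right-branching topology; label ties resolve to the smallest indices.
    """
    lls = table._require_leaves(l)
    l = lls.shape[0]
    K = table.n_nonterminals
    log_root, log_bc, log_ec, log_branch, log_emit = table.logs()

    best: dict = {}
    back: dict = {}
    leaf_zs = log_ec[:, None] + log_emit  # (K, S)
    for i in range(l):
        scores = leaf_zs + lls[i][None, :]
        best[(i, i + 1)] = scores.max(axis=1)
        back[(i, i + 1)] = scores.argmax(axis=1)  # terminal per label
    for width in range(2, l + 1):
        for i in range(l - width + 1):
            j = i + width
            b = np.full(K, -np.inf)
            bp = np.stack([np.full(K, i + 1), np.zeros(K, dtype=int),
                           np.zeros(K, dtype=int)], axis=1)
            for k in range(i + 1, j):
                pair = log_branch + (best[(i, k)][None, :, None]
                                     + best[(k, j)][None, None, :])
                flat = pair.reshape(K, -1)
                idx = flat.argmax(axis=1)
                cand = log_bc + flat[np.arange(K), idx]
                better = cand > b
                b[better] = cand[better]
                y1, y2 = np.unravel_index(idx[better], (K, K))
                bp[better] = np.stack([np.full(y1.shape, k), y1, y2], axis=1)
            best[(i, j)] = b
            back[(i, j)] = bp

    root_scores = log_root + best[(0, l)]
    r = int(root_scores.argmax())

    def build(i: int, j: int, z: int) -> ParseTree:
        if j - i == 1:
            return ParseTree(label=z, terminal=int(back[(i, j)][z]), pos=i)
        k, y1, y2 = (int(v) for v in back[(i, j)][z])
        return ParseTree(label=z, left=build(i, k, y1), right=build(k, j, y2))

    return build(0, l, r), float(root_scores[r])


# ---------------------------------------------------------------------------
# enumeration oracle over fully labeled parses (tests only; exponential)
# ---------------------------------------------------------------------------

def enumerate_labeled_trees(l: int, n_nonterminals: int, n_terminals: int) -> Iterator[ParseTree]:
    """Yield every fully labeled parse of a length-``l`` string.

    Exponential in ``l`` — guarded for use as a brute-force test oracle.
    """
    n_trees = (count_parses(l) * n_nonterminals ** (2 * l - 1)
               * n_terminals ** l)
    if n_trees > 200_000:
        raise ValueError(f"labeled enumeration would yield {n_trees} trees")

    def labelings(topo) -> Iterator[ParseTree]:
        if isinstance(topo, int):
            for z in range(n_nonterminals):
                for s in range(n_terminals):
                    yield ParseTree(label=z, terminal=s, pos=topo)
        else:
            for lt in labelings(topo[0]):
                for rt in labelings(topo[1]):
                    for z in range(n_nonterminals):
                        yield ParseTree(label=z, left=lt, right=rt)

    for topo in enumerate_topologies(l):
        yield from labelings(topo)


# ---------------------------------------------------------------------------
# bracketed-string serialization
# ---------------------------------------------------------------------------

def tree_to_string(tree: ParseTree) -> str:
    """Bracketed form with integer labels, e.g. ``(3 (1 s4) (2 (0 s7) (0 s2)))``."""
    if tree.is_leaf:
        return f"({tree.label} s{tree.terminal})"
    return f"({tree.label} {tree_to_string(tree.left)} {tree_to_string(tree.right)})"


_TOKEN = re.compile(r"\(|\)|s\d+|\d+")


def tree_from_string(text: str) -> ParseTree:
    """Parse the bracketed form back; leaf positions are assigned left to right."""
    tokens = _TOKEN.findall(text)
    pos = 0

    def parse(i: int) -> tuple[ParseTree, int]:
        nonlocal pos
        if tokens[i] != "(":
            raise ValueError(f"expected '(' at token {i}")
        label = int(tokens[i + 1])
        if tokens[i + 2].startswith("s"):
            node = ParseTree(label=label, terminal=int(tokens[i + 2][1:]), pos=pos)
            pos += 1
            if tokens[i + 3] != ")":
                raise ValueError("malformed leaf")
            return node, i + 4
        left, i2 = parse(i + 2)
        right, i3 = parse(i2)
        if tokens[i3] != ")":
            raise ValueError("unbalanced brackets")
        return ParseTree(label=label, left=left, right=right), i3 + 1

    tree, end = parse(0)
    if end != len(tokens):
        raise ValueError("trailing tokens after parse tree")
    return tree
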