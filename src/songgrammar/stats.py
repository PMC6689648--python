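"""Posterior diagnostics: expected parse counts, predictive summaries,
and rule-compactness metrics.

Parse accounting per string of length l >= 3: the posterior mass of the
unique left- and right-branching topologies (summed over all labelings via
a topology-constrained inside pass), non-regular mass as the complement,
and the Viterbi parse's mass credited to its topology class ("optimal").
Strings shorter than 3 have a unique parse and are counted separately.
The uniform baseline credits each string 1 / (number of topologies).

Compactness: the expected token frequency of a rule is its Dirichlet
variational parameter minus its DP base count; type counts apply a step
function 1[freq >= 1] or tanh to those frequencies.
"""

from __future__ import annotations

import csv
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .data import FeatureString
from .grammar import (TopologyClass, count_parses, inside_log_normalizer,
                      regular_tree, topology_log_inside, viterbi_parse,
                      classify_topology)
from .hmm import VariationalStateHMM, hmm_predictive_logdensity
from .pcfg import (VariationalStatePCFG, expected_log_weights,
                   posterior_predictive_logdensity)

__all__ = [
    "ParseCountReport",
    "PredictiveReport",
    "RuleCountReport",
    "expected_parse_counts",
    "uniform_baseline",
    "predictive_report",
    "expected_rule_frequencies",
    "rule_type_counts",
    "occupancy",
    "compare_report",
]

_CATS = ("LEFT", "RIGHT", "NONREGULAR")


@dataclass
class ParseCountReport:
    """Expected counts of parse categories over a corpus (totals, optimal,
    uniform baseline), with short strings (l < 3) reported separately."""

    total: dict[str, float]
    optimal: dict[str, float]
    uniform_baseline: float
    short_strings: int
    n_strings: int
    n_length_ge3: int
    n_length_ge4: int

    @property
    def percentages(self) -> dict[str, float]:
        denom = self.n_length_ge3
        if denom == 0:
            return {c: 0.0 for c in _CATS}
        return {c: 100.0 * self.total[c] / denom for c in _CATS}

    def to_dict(self) -> dict:
        d = asdict(self)
        d["percentages"] = self.percentages
        return d


@dataclass
class PredictiveReport:
    """Per-string per-point log predictive densities and their summaries."""

    model_kind: str
    per_point: list[float]
    lengths: list[int]
    mean: float
    std: float
    mean_ge4: float
    std_ge4: float
    n_strings: int
    n_length_ge4: int

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class RuleCountReport:
    """Expected rule-type counts under step and tanh activations."""

    model_kind: str
    step_by_class: dict[str, float]
    tanh_by_class: dict[str, float]
    step_total: float = field(init=False)
    tanh_total: float = field(init=False)

    def __post_init__(self) -> None:
        self.step_total = float(sum(self.step_by_class.values()))
        self.tanh_total = float(sum(self.tanh_by_class.values()))

    def to_dict(self) -> dict:
        return asdict(self)


# ---------------------------------------------------------------------------
# parse counts
# ---------------------------------------------------------------------------

def expected_parse_counts(state: VariationalStatePCFG,
                          corpus: list[FeatureString]) -> ParseCountReport:
    table = expected_log_weights(state)
    total = {c: 0.0 for c in _CATS}
    optimal = {c: 0.0 for c in _CATS}
    short = 0
    n_ge3 = n_ge4 = 0
    for s in corpus:
        l = len(s)
        if l < 3:
            short += 1
            continue
        n_ge3 += 1
        n_ge4 += l >= 4
        lls = state.niw.expected_log_gaussian(s.vectors)
        t = table.with_leaf_scores(lls, log=True)
        logz = inside_log_normalizer(t)
        left = np.exp(topology_log_inside(t, regular_tree(l, TopologyClass.LEFT)) - logz)
        right = np.exp(topology_log_inside(t, regular_tree(l, TopologyClass.RIGHT)) - logz)
        total["LEFT"] += left
        total["RIGHT"] += right
        total["NONREGULAR"] += max(0.0, 1.0 - left - right)
        tree, logw = viterbi_parse(t)
        cls = classify_topology(tree)
        optimal[cls.name] += np.exp(logw - logz)
    return ParseCountReport(total=total, optimal=optimal,
                            uniform_baseline=uniform_baseline(corpus),
                            short_strings=short, n_strings=len(corpus),
                            n_length_ge3=n_ge3, n_length_ge4=n_ge4)


def uniform_baseline(corpus: list[FeatureString]) -> float:
    """Expected count of a single parse were all topologies equiprobable:
    the sum over strings (l >= 3) of the reciprocal topology count."""
    if not corpus:
        raise ValueError("corpus is empty")
    return float(sum(1.0 / count_parses(len(s)) for s in corpus if len(s) >= 3))


# ---------------------------------------------------------------------------
# predictive power
# ---------------------------------------------------------------------------

def predictive_report(model_state, corpus: list[FeatureString],
                      model_kind: str) -> PredictiveReport:
    """Per-point log predictive densities with full and l >= 4 summaries.

    ``model_kind`` is "PCFG" or "HMM"; std is the population standard
    deviation (divisor N).
    """
    kind = model_kind.upper()
    if kind == "PCFG":
        vals = [posterior_predictive_logdensity(model_state, s)[1] for s in corpus]
    elif kind == "HMM":
        vals = [hmm_predictive_logdensity(model_state, s)[1] for s in corpus]
    else:
        raise ValueError(f"unknown model kind {model_kind!r}")
    vals = np.asarray(vals)
    lengths = np.array([len(s) for s in corpus])
    ge4 = vals[lengths >= 4]
    return PredictiveReport(
        model_kind=kind, per_point=vals.tolist(), lengths=lengths.tolist(),
        mean=float(vals.mean()), std=float(vals.std()),
        mean_ge4=float(ge4.mean()) if ge4.size else float("nan"),
        std_ge4=float(ge4.std()) if ge4.size else float("nan"),
        n_strings=len(corpus), n_length_ge4=int((lengths >= 4).sum()))


# ---------------------------------------------------------------------------
# compactness
# ---------------------------------------------------------------------------

def expected_rule_frequencies(state) -> dict[str, np.ndarray]:
    """Expected token frequency per rule: Dirichlet parameter minus its DP
    base count, clamped at zero against floating-point drift."""
    base = state.base_counts()
    if isinstance(state, VariationalStatePCFG):
        raw = {"root": state.dir_root - base["root"],
               "choice": state.dir_choice - base["choice"],
               "branch": state.dir_branch - base["branch"],
               "emit": state.dir_emit - base["emit"]}
    elif isinstance(state, VariationalStateHMM):
        raw = {"init": state.dir_init - base["init"],
               "trans": state.dir_trans - base["trans"],
               "stop": state.dir_stop - base["stop"]}
    else:
        raise TypeError(f"unsupported state type {type(state).__name__}")
    return {k: np.maximum(v, 0.0) for k, v in raw.items()}


# the study counts production rules proper: root/branch/terminal-emission
# for the PCFG, initial/transition for the HMM (switch factors excluded)
_PRODUCTION_CLASSES = {"PCFG": ("root", "branch", "emit"), "HMM": ("init", "trans")}


def rule_type_counts(frequencies: dict[str, np.ndarray], activation: str,
                     model_kind: str = "PCFG",
                     classes: tuple[str, ...] | None = None) -> RuleCountReport:
    """Type counts per rule class: step counts rules with frequency >= 1,
    tanh sums tanh(frequency)."""
    if activation not in ("step", "tanh"):
        raise ValueError(f"unknown activation {activation!r}")
    kind = model_kind.upper()
    classes = classes or _PRODUCTION_CLASSES.get(kind, tuple(frequencies))
    step_by, tanh_by = {}, {}
    for cls in classes:
        f = np.asarray(frequencies[cls], dtype=float).ravel()
        if np.any(f < 0):
            raise ValueError(f"negative frequency in class {cls!r}")
        step_by[cls] = float((f >= 1.0).sum())
        tanh_by[cls] = float(np.tanh(f).sum())
    report = RuleCountReport(model_kind=kind, step_by_class=step_by,
                             tanh_by_class=tanh_by)
    return report


def occupancy(frequencies: dict[str, np.ndarray], threshold: float = 0.05,
              model_kind: str = "PCFG") -> dict[str, int]:
    """Components with expected usage frequency above ``threshold``."""
    kind = model_kind.upper()
    if kind == "PCFG":
        nonterminal = (frequencies["root"]
                       + frequencies["branch"].sum(axis=(1, 2))
                       + frequencies["emit"].sum(axis=1))
        terminal = frequencies["emit"].sum(axis=0)
        return {"nonterminals": int((nonterminal > threshold).sum()),
                "terminals": int((terminal > threshold).sum())}
    state_usage = frequencies["init"] + frequencies["trans"].sum(axis=0)
    return {"states": int((state_usage > threshold).sum())}


# ---------------------------------------------------------------------------
# side-by-side comparison
# ---------------------------------------------------------------------------

def compare_report(pcfg_parse: ParseCountReport,
                   pcfg_pred: PredictiveReport, hmm_pred: PredictiveReport,
                   pcfg_rules: RuleCountReport, hmm_rules: RuleCountReport,
                   out_dir) -> dict:
    """Write parse counts, predictive summaries and rule-count tables as
    JSON + CSV into ``out_dir``; returns the combined summary dict."""
    if pcfg_pred.n_strings != hmm_pred.n_strings:
        raise ValueError("PCFG and HMM predictive reports cover different corpora")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    (out / "parse_counts.json").write_text(
        json.dumps(pcfg_parse.to_dict(), indent=2))
    with open(out / "predictive.csv", "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["string_index", "length", "pcfg_per_point", "hmm_per_point"])
        for i, (l, a, b) in enumerate(zip(pcfg_pred.lengths, pcfg_pred.per_point,
                                          hmm_pred.per_point)):
            w.writerow([i, l, a, b])
    rules = {"PCFG": pcfg_rules.to_dict(), "HMM": hmm_rules.to_dict()}
    (out / "rule_counts.json").write_text(json.dumps(rules, indent=2))
    summary = {
        "parse_counts": pcfg_parse.to_dict(),
        "predictive": {"PCFG": {"mean": pcfg_pred.mean, "std": pcfg_pred.std,
                                "mean_ge4": pcfg_pred.mean_ge4, "std_ge4": pcfg_pred.std_ge4},
                       "HMM": {"mean": hmm_pred.mean, "std": hmm_pred.std,
                               "mean_ge4": hmm_pred.mean_ge4, "std_ge4": hmm_pred.std_ge4}},
        "rule_type_counts": {
            "step": {"PCFG": pcfg_rules.step_total, "HMM": hmm_rules.step_total},
            "tanh": {"PCFG": pcfg_rules.tanh_total, "HMM": hmm_rules.tanh_total},
        },
    }
    with open(out / "comparison.csv", "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["metric", "PCFG", "HMM"])
        w.writerow(["predictive_mean", pcfg_pred.mean, hmm_pred.mean])
        w.writerow(["predictive_std", pcfg_pred.std, hmm_pred.std])
        w.writerow(["predictive_mean_ge4", pcfg_pred.mean_ge4, hmm_pred.mean_ge4])
        w.writerow(["rule_types_step", pcfg_rules.step_total, hmm_rules.step_total])
        w.writerow(["rule_types_tanh", pcfg_rules.tanh_total, hmm_rules.tanh_total])
    (out / "comparison.json").write_text(json.dumps(summary, indent=2))
    return summary
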