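"""Numeric re-optimization of degenerate (point-mass) stick weights.

The top-level HDP weights (beta over non-terminals, gamma over terminals,
omega over HMM states) get point-mass variational factors truncated at a
fixed level.  Within a truncation the weight vector is re-optimized by
ascent on the objective terms that involve it: the expected log prior
densities of the Dirichlet rule factors whose base counts are built from it
(the stick-breaking GEM(1) prior density itself is flat).  The update is
guaranteed not to decrease the objective: the incumbent vector is kept
unless a candidate strictly improves on it.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import minimize
from scipy.special import gammaln

__all__ = ["stick_objective", "optimize_sticks"]

_EPS = 1e-10


def _dir_log_prior(base: np.ndarray, elog: np.ndarray) -> float:
    """E_q[log Dirichlet(phi; base)] up to q-independent constants.

    ``elog`` holds E_q[log phi] for the corresponding factor.
    """
    base = np.maximum(base, _EPS)
    return float(gammaln(base.sum()) - gammaln(base).sum() + ((base - 1) * elog).sum())


def stick_objective(weights: np.ndarray, alpha: float,
                    simple_elogs: list[np.ndarray],
                    outer_elogs: list[np.ndarray]) -> float:
    """Objective for a stick vector: sum of expected Dirichlet log priors.

    ``simple_elogs`` are E[log phi] vectors for factors with base counts
    ``alpha * weights``; ``outer_elogs`` are (K, K) matrices for factors
    with base counts ``alpha * outer(weights, weights)`` (branch pairs).
    """
    total = 0.0
    for elog in simple_elogs:
        total += _dir_log_prior(alpha * weights, elog)
    if outer_elogs:
        base = alpha * np.outer(weights, weights)
        for elog in outer_elogs:
            total += _dir_log_prior(base.ravel(), np.asarray(elog).ravel())
    return total


def optimize_sticks(current: np.ndarray, usage: np.ndarray, alpha: float,
                    simple_elogs: list[np.ndarray],
                    outer_elogs: list[np.ndarray] | None = None,
                    maxiter: int = 100) -> np.ndarray:
    """Return a stick vector with objective >= that of ``current``.

    Runs L-BFGS in softmax coordinates from two starts — the incumbent and
    the normalized expected usage counts — and keeps the best of the three.
    """
    outer_elogs = outer_elogs or []
    current = np.asarray(current, dtype=float)

    def neg(u: np.ndarray) -> float:
        w = np.exp(u - u.max())
        w /= w.sum()
        return -stick_objective(w, alpha, simple_elogs, outer_elogs)

    best_w = current
    best_val = stick_objective(current, alpha, simple_elogs, outer_elogs)
    usage = np.asarray(usage, dtype=float)
    usage_start = usage / usage.sum() if usage.sum() > 0 else current
    for start in (current, usage_start):
        res = minimize(neg, np.log(np.maximum(start, _EPS)), method="L-BFGS-B",
                       options={"maxiter": maxiter})
        w = np.exp(res.x - res.x.max())
        w /= w.sum()
        val = stick_objective(w, alpha, simple_elogs, outer_elogs)
        if val > best_val:
            best_w, best_val = w, val
    return best_w
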