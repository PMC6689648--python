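"""Generic coordinate-ascent variational inference driver.

Both models (PCFG and HMM) share the same outer loop: multi-restart
coordinate ascent where each sweep runs an E-pass over the corpus, a
conjugate M-update, and a numeric re-optimization of the degenerate stick
weights; a run stops when the objective improves by less than ``tol`` or
after ``max_iter`` sweeps, and the best final objective across restarts
wins.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable

import numpy as np

logger = logging.getLogger(__name__)

__all__ = ["FitConfig", "RunRecord", "cavi_run", "multi_restart"]


@dataclass
class FitConfig:
    """Restart/stopping policy.  Defaults are desk-scale; the study used
    500 restarts, tol 0.1, 300 max iterations."""

    n_restarts: int = 10
    tol: float = 0.1
    max_iter: int = 300
    seed: int | None = None
    seeds: list[int] | None = None

    def __post_init__(self) -> None:
        if self.n_restarts < 1:
            raise ValueError("n_restarts must be >= 1")
        if self.tol <= 0:
            raise ValueError("tol must be > 0")

    def restart_seeds(self) -> list[int]:
        if self.seeds is not None:
            if len(self.seeds) != self.n_restarts:
                raise ValueError("seeds list must match n_restarts")
            return list(self.seeds)
        ss = np.random.SeedSequence(self.seed)
        return [int(s.generate_state(1)[0]) for s in ss.spawn(self.n_restarts)]


@dataclass
class RunRecord:
    seed: int
    elbo_trace: list[float] = field(default_factory=list)
    n_sweeps: int = 0
    converged: bool = False
    error: str | None = None

    @property
    def final_elbo(self) -> float:
        return self.elbo_trace[-1] if self.elbo_trace else -np.inf


def cavi_run(state, e_step: Callable, m_step: Callable, kl_penalty: Callable,
             tol: float, max_iter: int, record: RunRecord):
    """One coordinate-ascent run; mutates ``record`` with the trace.

    ``e_step(state) -> (stats, loglik)``; ``m_step(state, stats) -> state``;
    ``kl_penalty(state) -> float`` (the KL of the parameter factors to their
    priors, subtracted from the data term to form the ELBO).
    """
    while True:
        stats, loglik = e_step(state)
        elbo = float(loglik - kl_penalty(state))
        if not np.isfinite(elbo):
            raise FloatingPointError(f"non-finite ELBO at sweep {record.n_sweeps}")
        record.elbo_trace.append(elbo)
        if len(record.elbo_trace) >= 2:
            if record.elbo_trace[-1] - record.elbo_trace[-2] < tol:
                record.converged = True
                break
        if record.n_sweeps >= max_iter:
            break
        state = m_step(state, stats)
        record.n_sweeps += 1
    return state


def multi_restart(run_one: Callable[[int], tuple], cfg: FitConfig):
    """Run ``run_one(seed) -> (state, RunRecord)`` per restart, keep the best.

    A failed restart is logged and skipped; if every restart fails, raises
    with the collected diagnostics.
    """
    best_state, best_record = None, None
    records: list[RunRecord] = []
    for seed in cfg.restart_seeds():
        try:
            state, record = run_one(seed)
        except (FloatingPointError, np.linalg.LinAlgError) as exc:
            record = RunRecord(seed=seed, error=str(exc))
            logger.warning("restart seed=%d failed: %s", seed, exc)
            records.append(record)
            continue
        records.append(record)
        if best_record is None or record.final_elbo > best_record.final_elbo:
            best_state, best_record = state, record
    if best_state is None:
        msgs = "; ".join(f"seed={r.seed}: {r.error}" for r in records)
        raise RuntimeError(f"all {cfg.n_restarts} restarts failed: {msgs}")
    return best_state, best_record, records
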