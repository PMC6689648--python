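"""Model-state persistence: one ``.npz`` archive with a JSON header."""

from __future__ import annotations

import json

import numpy as np

from .priors import NIW, Hyperparams
from .hmm import VariationalStateHMM
from .pcfg import VariationalStatePCFG

__all__ = ["save_state", "load_state"]


def _hyper_meta(h: Hyperparams) -> dict:
    return {"dim": h.dim, "alpha": h.alpha, "k_beta": h.k_beta,
            "k_gamma": h.k_gamma, "k_omega": h.k_omega,
            "niw_dof": h.niw_dof, "niw_kappa": h.niw_kappa}


def save_state(state, path) -> None:
    if isinstance(state, VariationalStatePCFG):
        kind = "pcfg"
        arrays = {"beta": state.beta, "gamma": state.gamma,
                  "dir_root": state.dir_root, "dir_choice": state.dir_choice,
                  "dir_branch": state.dir_branch, "dir_emit": state.dir_emit}
    elif isinstance(state, VariationalStateHMM):
        kind = "hmm"
        arrays = {"omega": state.omega, "dir_init": state.dir_init,
                  "dir_trans": state.dir_trans, "dir_stop": state.dir_stop}
    else:
        raise TypeError(f"cannot serialize {type(state).__name__}")
    meta = {"kind": kind, "hyper": _hyper_meta(state.hyper),
            "elbo_trace": list(state.elbo_trace), "n_sweeps": state.n_sweeps,
            "model_termination": getattr(state, "model_termination", None)}
    np.savez(path, header=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
             niw_mean=state.niw.mean, niw_kappa=state.niw.kappa,
             niw_scale=state.niw.scale, niw_dof=state.niw.dof,
             prior_mean=np.asarray(state.hyper.niw_mean, float),
             prior_scale=np.asarray(state.hyper.niw_scale, float),
             **arrays)


def load_state(path):
    with np.load(path) as z:
        meta = json.loads(bytes(z["header"]).decode())
        h = meta["hyper"]
        hyper = Hyperparams(dim=h["dim"], alpha=h["alpha"], k_beta=h["k_beta"],
                            k_gamma=h["k_gamma"], k_omega=h["k_omega"],
                            niw_dof=h["niw_dof"], niw_kappa=h["niw_kappa"],
                            niw_mean=z["prior_mean"], niw_scale=z["prior_scale"])
        niw = NIW(mean=z["niw_mean"], kappa=z["niw_kappa"],
                  scale=z["niw_scale"], dof=z["niw_dof"])
        if meta["kind"] == "pcfg":
            state = VariationalStatePCFG(
                hyper=hyper, beta=z["beta"], gamma=z["gamma"],
                dir_root=z["dir_root"], dir_choice=z["dir_choice"],
                dir_branch=z["dir_branch"], dir_emit=z["dir_emit"], niw=niw,
                elbo_trace=meta["elbo_trace"], n_sweeps=meta["n_sweeps"])
        else:
            state = VariationalStateHMM(
                hyper=hyper, omega=z["omega"], dir_init=z["dir_init"],
                dir_trans=z["dir_trans"], dir_stop=z["dir_stop"], niw=niw,
                model_termination=bool(meta["model_termination"]),
                elbo_trace=meta["elbo_trace"], n_sweeps=meta["n_sweeps"])
    return state
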