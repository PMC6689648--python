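"""Hyperparameters and Gaussian/normal-inverse-Wishart (NIW) machinery.

Both models share the same emission treatment: each terminal (or hidden
state) owns a Gaussian over feature vectors with an NIW prior; variational
factors over (mean, covariance) stay NIW by conjugacy.  This module holds
the closed forms those updates need: expected log densities under an NIW
factor, conjugate updates from soft counts, KL to the prior, the Student-t
posterior predictive, and sampling (for the Monte-Carlo predictive check).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.special import digamma, multigammaln
from scipy.stats import invwishart, multivariate_t

__all__ = ["Hyperparams", "NIW", "niw_prior", "dirichlet_kl", "dirichlet_expected_log"]


def dirichlet_expected_log(a: np.ndarray, axis: int = -1) -> np.ndarray:
    """E[log phi] under Dirichlet(a) along ``axis`` (digamma differences)."""
    a = np.asarray(a, dtype=float)
    return digamma(a) - digamma(a.sum(axis=axis, keepdims=True))


def dirichlet_kl(a: np.ndarray, b: np.ndarray) -> float:
    """KL( Dirichlet(a) || Dirichlet(b) ) for flat parameter vectors."""
    from scipy.special import gammaln

    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    elog = digamma(a) - digamma(a.sum())
    return float(gammaln(a.sum()) - gammaln(a).sum()
                 - gammaln(b.sum()) + gammaln(b).sum()
                 + ((a - b) * elog).sum())


@dataclass
class Hyperparams:
    """Model hyperparameters; defaults mirror the study's settings.

    All Dirichlet-process / beta concentrations are 1; the inverse-Wishart
    scale is the identity, its degrees of freedom ``D - 1 + 0.001``, the
    Gaussian prior mean the sample mean of the training vectors, and the
    prior precision scalar ``k0`` equal to the degrees of freedom.
    """

    dim: int = 13
    alpha: float = 1.0
    k_beta: int = 40
    k_gamma: int = 100
    k_omega: int = 100
    niw_mean: np.ndarray | None = None
    niw_scale: np.ndarray | None = None
    niw_dof: float | None = None
    niw_kappa: float | None = None

    def resolve(self, data: np.ndarray | None = None) -> "Hyperparams":
        """Fill data-dependent defaults (prior mean = sample mean of ``data``)."""
        D = self.dim
        dof = self.niw_dof if self.niw_dof is not None else D - 1 + 0.001
        kappa = self.niw_kappa if self.niw_kappa is not None else dof
        scale = self.niw_scale if self.niw_scale is not None else np.eye(D)
        if self.niw_mean is not None:
            mean = np.asarray(self.niw_mean, dtype=float)
        elif data is not None and len(data):
            mean = np.asarray(data, dtype=float).reshape(-1, D).mean(axis=0)
        else:
            mean = np.zeros(D)
        if dof <= D - 1:
            raise ValueError(f"NIW dof must exceed D-1={D - 1}, got {dof}")
        return replace(self, niw_mean=mean, niw_scale=np.asarray(scale, float),
                       niw_dof=float(dof), niw_kappa=float(kappa))


@dataclass
class NIW:
    """A bank of K independent NIW factors over (mean, covariance) pairs."""

    mean: np.ndarray   # (K, D)
    kappa: np.ndarray  # (K,)
    scale: np.ndarray  # (K, D, D)
    dof: np.ndarray    # (K,)

    def __post_init__(self) -> None:
        self.mean = np.atleast_2d(np.asarray(self.mean, float))
        self.kappa = np.atleast_1d(np.asarray(self.kappa, float))
        self.scale = np.asarray(self.scale, float)
        self.dof = np.atleast_1d(np.asarray(self.dof, float))
        if np.any(self.kappa <= 0) or np.any(self.dof <= self.dim - 1):
            raise ValueError("invalid NIW parameters")

    @property
    def n_components(self) -> int:
        return self.mean.shape[0]

    @property
    def dim(self) -> int:
        return self.mean.shape[1]

    # -- expectations -----------------------------------------------------

    def expected_logdet_precision(self) -> np.ndarray:
        """E[log |Sigma^-1|] per component."""
        D = self.dim
        i = np.arange(1, D + 1)
        terms = digamma((self.dof[:, None] + 1 - i[None, :]) / 2).sum(axis=1)
        sign, logdet = np.linalg.slogdet(self.scale)
        if np.any(sign <= 0):
            raise np.linalg.LinAlgError("NIW scale matrix not positive definite")
        return terms + D * np.log(2.0) - logdet

    def expected_log_gaussian(self, x: np.ndarray) -> np.ndarray:
        """E_q[log N(x | mean, cov)] for each x and component; shape (n, K)."""
        x = np.atleast_2d(np.asarray(x, float))
        D = self.dim
        eld = self.expected_logdet_precision()  # (K,)
        out = np.empty((x.shape[0], self.n_components))
        for k in range(self.n_components):
            diff = x - self.mean[k]
            sol = np.linalg.solve(self.scale[k], diff.T).T
            maha = self.dof[k] * np.einsum("nd,nd->n", diff, sol)
            out[:, k] = 0.5 * (eld[k] - D / self.kappa[k] - maha) - 0.5 * D * np.log(2 * np.pi)
        return out

    # -- conjugate update ---------------------------------------------------

    @staticmethod
    def posterior(prior: "NIW", resp: np.ndarray, x: np.ndarray) -> "NIW":
        """Conjugate update of a K-component prior with responsibilities.

        ``resp`` is (n, K) soft assignment mass; ``x`` is (n, D).
        """
        x = np.atleast_2d(np.asarray(x, float))
        resp = np.asarray(resp, float)
        K, D = prior.n_components, prior.dim
        N = resp.sum(axis=0)  # (K,)
        mean = np.empty((K, D))
        kappa = prior.kappa + N
        dof = prior.dof + N
        scale = np.empty((K, D, D))
        for k in range(K):
            if N[k] > 1e-12:
                xbar = resp[:, k] @ x / N[k]
                diff = x - xbar
                S = (resp[:, k][:, None] * diff).T @ diff
                dm = (xbar - prior.mean[k])[:, None]
                scale[k] = (prior.scale[k] + S
                            + (prior.kappa[k] * N[k] / (prior.kappa[k] + N[k])) * (dm @ dm.T))
                mean[k] = (prior.kappa[k] * prior.mean[k] + N[k] * xbar) / kappa[k]
            else:
                scale[k] = prior.scale[k]
                mean[k] = prior.mean[k]
        return NIW(mean=mean, kappa=kappa, scale=scale, dof=dof)

    # -- divergences & predictive -------------------------------------------

    def kl_to(self, prior: "NIW") -> np.ndarray:
        """KL(q || p) per component, both NIW banks of equal shape."""
        D = self.dim
        eld = self.expected_logdet_precision()
        kl = np.empty(self.n_components)
        for k in range(self.n_components):
            m, kap, Psi, nu = self.mean[k], self.kappa[k], self.scale[k], self.dof[k]
            m0, kap0, Psi0, nu0 = prior.mean[k], prior.kappa[k], prior.scale[k], prior.dof[k]
            dm = m - m0
            sol = np.linalg.solve(Psi, dm)
            kl_norm = (0.5 * D * np.log(kap / kap0) - 0.5 * D
                       + 0.5 * kap0 * D / kap + 0.5 * kap0 * nu * dm @ sol)
            _, ld = np.linalg.slogdet(Psi)
            _, ld0 = np.linalg.slogdet(Psi0)
            tr0 = nu * np.trace(np.linalg.solve(Psi, Psi0))
            e_log_q = (0.5 * nu * ld - 0.5 * nu * D * np.log(2.0) - multigammaln(nu / 2, D)
                       + 0.5 * (nu + D + 1) * eld[k] - 0.5 * nu * D)
            e_log_p = (0.5 * nu0 * ld0 - 0.5 * nu0 * D * np.log(2.0) - multigammaln(nu0 / 2, D)
                       + 0.5 * (nu0 + D + 1) * eld[k] - 0.5 * tr0)
            kl[k] = kl_norm + e_log_q - e_log_p
        return kl

    def predictive_logpdf(self, x: np.ndarray) -> np.ndarray:
        """Student-t posterior predictive log density; shape (n, K).

        x | NIW(m, k, Psi, nu)  ~  t_{nu-D+1}(m, Psi (k+1) / (k (nu-D+1))).
        """
        x = np.atleast_2d(np.asarray(x, float))
        D = self.dim
        out = np.empty((x.shape[0], self.n_components))
        for k in range(self.n_components):
            df = self.dof[k] - D + 1
            shape = self.scale[k] * (self.kappa[k] + 1) / (self.kappa[k] * df)
            out[:, k] = multivariate_t.logpdf(x, loc=self.mean[k], shape=shape, df=df)
        return out

    def sample(self, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
        """Draw (means, covariances) from each NIW factor."""
        K, D = self.n_components, self.dim
        mus = np.empty((K, D))
        covs = np.empty((K, D, D))
        for k in range(K):
            # low dof (D - 1 + 0.001) makes the IW extremely heavy-tailed;
            # reject the rare draws that overflow float range
            for _ in range(100):
                cov = np.atleast_2d(invwishart.rvs(
                    df=self.dof[k], scale=self.scale[k], random_state=rng))
                cov = (cov + cov.T) / 2
                if np.all(np.isfinite(cov)):
                    try:
                        chol = np.linalg.cholesky(cov)
                        break
                    except np.linalg.LinAlgError:
                        continue
            else:
                raise FloatingPointError("could not draw a finite PD covariance")
            mus[k] = self.mean[k] + chol @ rng.standard_normal(D) / np.sqrt(self.kappa[k])
            covs[k] = cov
        return mus, covs


def niw_prior(hyper: Hyperparams, n_components: int) -> NIW:
    """Replicate the resolved NIW prior across ``n_components`` factors."""
    h = hyper if hyper.niw_dof is not None else hyper.resolve()
    K, D = n_components, h.dim
    return NIW(
        mean=np.tile(np.asarray(h.niw_mean, float), (K, 1)),
        kappa=np.full(K, h.niw_kappa),
        scale=np.tile(np.asarray(h.niw_scale, float), (K, 1, 1)),
        dof=np.full(K, h.niw_dof),
    )
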