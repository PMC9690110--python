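"""Conjugate Normal-Inverse-Wishart cluster model.

Each cluster k carries a Gaussian likelihood N_p(mu_k, Sigma_k) with a
conjugate NIW(mu0, lambda0, Psi0, nu0) prior on (mu_k, Sigma_k).  The
posterior after observing the cluster's members is again NIW with the
standard closed-form updates, and the posterior predictive density of a
new point is a multivariate Student-t with nu1 - p + 1 degrees of
freedom, location mu1 and scale Psi1 (lambda1 + 1) / (lambda1 (nu1 - p + 1)).

Default hyperparameters place the location at the grand mean with unit
precision scale and nu0 = p degrees of freedom.  For the scale matrix
two conventions are offered: the default ``psi0="scatter"`` sets
Psi0 = (p - 1) * S-hat with S-hat the global sample covariance, so the
prior cluster scale is commensurate with the data's overall spread;
``psi0="printed"`` sets Psi0 = (p - 1) * [centered scatter]^{-1}, a
formula that appears in the method's published description but yields a
near-degenerate prior scale (entries of order 1/(n * var)) whose
overconfident predictives demonstrably break cluster recovery — see
docs/methods.md for the analysis.  Both are undefined at p = 1, where a
user-supplied Psi0 is required.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln

__all__ = [
    "NIWParams",
    "NIWPosterior",
    "default_hyperparams",
    "niw_posterior",
    "posterior_from_stats",
    "log_predictive",
    "log_predictive_batch",
    "loo_log_predictive",
]


@dataclass(frozen=True)
class NIWParams:
    mu0: np.ndarray
    lambda0: float
    Psi0: np.ndarray
    nu0: float

    def __post_init__(self) -> None:
        mu0 = np.atleast_1d(np.asarray(self.mu0, dtype=float))
        Psi0 = np.atleast_2d(np.asarray(self.Psi0, dtype=float))
        p = mu0.size
        if self.lambda0 <= 0:
            raise ValueError("lambda0 must be positive")
        if self.nu0 <= p - 1:
            raise ValueError(f"nu0 must exceed p - 1 = {p - 1}")
        if Psi0.shape != (p, p) or not np.allclose(Psi0, Psi0.T):
            raise ValueError("Psi0 must be a symmetric p x p matrix")
        if np.any(np.linalg.eigvalsh(Psi0) <= 0):
            raise ValueError("Psi0 must be positive-definite")
        object.__setattr__(self, "mu0", mu0)
        object.__setattr__(self, "Psi0", Psi0)

    @property
    def p(self) -> int:
        return self.mu0.size


@dataclass(frozen=True)
class NIWPosterior:
    mu1: np.ndarray
    lambda1: float
    Psi1: np.ndarray
    nu1: float
    n_k: int
    xbar_k: np.ndarray | None

    @property
    def p(self) -> int:
        return self.mu1.size


def default_hyperparams(
    X: np.ndarray, Psi0: np.ndarray | None = None, psi0: str = "scatter"
) -> NIWParams:
    """Data-driven defaults: mu0 = grand mean, lambda0 = 1, nu0 = p.

    ``psi0`` selects the scale-matrix convention when ``Psi0`` is not
    given explicitly: ``"scatter"`` (default) uses
    (p - 1) * [centered scatter] / (n - 1), i.e. (p - 1) times the
    global sample covariance; ``"printed"`` uses
    (p - 1) * [centered scatter]^{-1}.  Both degenerate at p = 1, where
    Psi0 must be supplied explicitly.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n, p = X.shape
    if n < 2:
        raise ValueError("need at least 2 subjects")
    mu0 = X.mean(axis=0)
    if Psi0 is None:
        if p == 1:
            raise ValueError(
                "the default Psi0 conventions vanish at p = 1; supply Psi0 explicitly"
            )
        Xc = X - mu0
        scatter = Xc.T @ Xc
        if psi0 == "scatter":
            Psi0 = (p - 1) * scatter / (n - 1)
        elif psi0 == "printed":
            try:
                inv = np.linalg.inv(scatter)
            except np.linalg.LinAlgError as exc:
                raise ValueError(
                    "global scatter matrix is singular; add a ridge or supply Psi0"
                ) from exc
            Psi0 = (p - 1) * 0.5 * (inv + inv.T)
        else:
            raise ValueError("psi0 must be 'scatter' or 'printed'")
    return NIWParams(mu0=mu0, lambda0=1.0, Psi0=Psi0, nu0=float(p))


def posterior_from_stats(
    prior: NIWParams, n_k: int, sum_x: np.ndarray, sum_xxT: np.ndarray
) -> NIWPosterior:
    """Posterior from sufficient statistics (member count, sum, outer-product sum)."""
    if n_k == 0:
        return NIWPosterior(
            mu1=prior.mu0, lambda1=prior.lambda0, Psi1=prior.Psi0, nu1=prior.nu0,
            n_k=0, xbar_k=None,
        )
    xbar = sum_x / n_k
    lam1 = prior.lambda0 + n_k
    mu1 = (prior.lambda0 * prior.mu0 + n_k * xbar) / lam1
    S = sum_xxT - n_k * np.outer(xbar, xbar)  # centered scatter of members
    d = xbar - prior.mu0
    Psi1 = prior.Psi0 + S + (prior.lambda0 * n_k / lam1) * np.outer(d, d)
    return NIWPosterior(
        mu1=mu1, lambda1=lam1, Psi1=0.5 * (Psi1 + Psi1.T), nu1=prior.nu0 + n_k,
        n_k=n_k, xbar_k=xbar,
    )


def niw_posterior(prior: NIWParams, cluster_data: np.ndarray) -> NIWPosterior:
    """Conjugate update on the rows of ``cluster_data`` (may be empty)."""
    Xk = np.asarray(cluster_data, dtype=float)
    if Xk.size == 0:
        return posterior_from_stats(prior, 0, np.zeros(prior.p), np.zeros((prior.p, prior.p)))
    if Xk.ndim == 1:
        Xk = Xk[:, None]
    return posterior_from_stats(prior, Xk.shape[0], Xk.sum(axis=0), Xk.T @ Xk)


def _student_t_const(nu: float, p: int) -> float:
    return float(gammaln((nu + p) / 2) - gammaln(nu / 2) - (p / 2) * np.log(nu * np.pi))


def log_predictive_batch(X: np.ndarray, post: NIWPosterior) -> np.ndarray:
    """Posterior-predictive log-density of each row of ``X`` under a cluster.

    The predictive is multivariate Student-t with ``nu1 - p + 1`` degrees
    of freedom; for an empty cluster this is the prior predictive.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    p = post.p
    nu = post.nu1 - p + 1
    if nu <= 0:
        raise ValueError("predictive degrees of freedom nu1 - p + 1 must be positive")
    scale = post.Psi1 * (post.lambda1 + 1) / (post.lambda1 * nu)
    sign, logdet = np.linalg.slogdet(scale)
    if sign <= 0:
        raise np.linalg.LinAlgError("predictive scale matrix is not positive-definite")
    dev = X - post.mu1
    sol = np.linalg.solve(scale, dev.T).T
    maha = np.einsum("ij,ij->i", dev, sol)
    return _student_t_const(nu, p) - 0.5 * logdet - ((nu + p) / 2) * np.log1p(maha / nu)


def log_predictive(x: np.ndarray, post: NIWPosterior) -> float:
    """Posterior-predictive log-density of a single point."""
    return float(log_predictive_batch(np.atleast_1d(x)[None, :], post)[0])


def loo_log_predictive(Xm: np.ndarray, prior: NIWParams) -> np.ndarray:
    """Leave-one-out predictive log-density for every member of a cluster.

    Entry i is the log-density of member i under the posterior fitted on
    the other members (the prior predictive when the cluster is a
    singleton).  Vectorized over members; used in the collapsed Gibbs
    sweep, where each subject is scored against its own table with
    itself removed.
    """
    Xm = np.atleast_2d(np.asarray(Xm, dtype=float))
    m, p = Xm.shape
    if m == 1:
        post0 = posterior_from_stats(prior, 0, np.zeros(p), np.zeros((p, p)))
        return log_predictive_batch(Xm, post0)
    sum_x = Xm.sum(axis=0)
    sum_xxT = Xm.T @ Xm
    nk = m - 1
    lam1 = prior.lambda0 + nk
    nu = prior.nu0 + nk - p + 1
    # per-member downdated statistics, stacked over the leading axis
    xbar = (sum_x[None, :] - Xm) / nk                      # (m, p)
    mu1 = (prior.lambda0 * prior.mu0[None, :] + nk * xbar) / lam1
    S2 = sum_xxT[None, :, :] - np.einsum("mi,mj->mij", Xm, Xm)
    S = S2 - nk * np.einsum("mi,mj->mij", xbar, xbar)
    d = xbar - prior.mu0[None, :]
    Psi1 = prior.Psi0[None, :, :] + S + (prior.lambda0 * nk / lam1) * np.einsum(
        "mi,mj->mij", d, d
    )
    scale = Psi1 * (lam1 + 1) / (lam1 * nu)
    sign, logdet = np.linalg.slogdet(scale)
    dev = Xm - mu1
    sol = np.linalg.solve(scale, dev[:, :, None])[:, :, 0]
    maha = np.einsum("mi,mi->m", dev, sol)
    return _student_t_const(nu, p) - 0.5 * logdet - ((nu + p) / 2) * np.log1p(maha / nu)
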