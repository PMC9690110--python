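"""Ewens-Pitman Attraction (EPA) baseline sampler, with CRP special case.

EPA is a sequential seating prior: subjects are visited in a random
permutation and each joins an existing cluster with probability
proportional to its normalized similarity to the cluster's seated
members, scaled by ((i-1) - delta*q) / (alpha + i - 1), or opens a new
cluster with probability (alpha + delta*q) / (alpha + i - 1), where q is
the number of clusters seated so far.  With zero discount (delta = 0)
and constant similarity this reduces exactly to the Chinese Restaurant
Process.  The mass parameter alpha is resampled each sweep from West's
approximate gamma posterior given the current cluster count:

    alpha | K  ~  Gamma(a + K - 1,  rate = b + gamma_Euler + log n).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .gibbs_sampler import ChainRecord, SamplerConfig, _prepare_inputs
from .niw_likelihood import (
    NIWParams,
    log_predictive_batch,
    posterior_from_stats,
)
from .similarity import DistanceMatrix, SimilarityMatrix

__all__ = [
    "EPAParams",
    "epa_conditional",
    "sample_alpha_west",
    "run_epa_sampler",
    "run_crp_sampler",
]

EULER_GAMMA = float(np.euler_gamma)


@dataclass(frozen=True)
class EPAParams:
    """Mass alpha > -delta, discount delta in [0, 1), and the (a, b)
    parameters of West's gamma prior for alpha (a = b = 1 gives a unit
    exponential prior)."""

    alpha: float = 1.0
    delta: float = 0.0
    a: float = 1.0
    b: float = 1.0

    def __post_init__(self) -> None:
        if not 0 <= self.delta < 1:
            raise ValueError("delta must lie in [0, 1)")
        if self.alpha <= -self.delta:
            raise ValueError("alpha must exceed -delta")
        if self.a <= 0 or self.b <= 0:
            raise ValueError("a and b must be positive")


def epa_conditional(
    i_pos: int,
    partial: np.ndarray,
    sigma: np.ndarray,
    L: SimilarityMatrix | np.ndarray,
    params: EPAParams,
) -> tuple[np.ndarray, np.ndarray]:
    """Seating probabilities for the subject at permutation position ``i_pos``.

    Parameters
    ----------
    i_pos : int
        1-based position i in the permutation; must be >= 2 (the first
        subject deterministically opens a cluster).
    partial : array of i-1 labels
        Cluster labels already assigned to sigma[0], ..., sigma[i-2].
    sigma : permutation of 0..n-1
    L : similarity matrix (or raw array)

    Returns ``(cluster_labels, probs)`` where the last entry of
    ``probs`` is the probability of opening a new cluster.
    """
    if i_pos < 2:
        raise ValueError("the first permuted subject opens a cluster with probability 1")
    lam = L.values if isinstance(L, SimilarityMatrix) else np.asarray(L)
    i1 = i_pos - 1  # subjects already seated
    partial = np.asarray(partial)
    if partial.size != i1:
        raise ValueError("partial assignment length must be i_pos - 1")
    seated = sigma[:i1]
    subj = sigma[i_pos - 1]
    sims = lam[subj, seated]
    total = sims.sum()
    if total <= 0:
        raise RuntimeError("zero total similarity to seated subjects")
    labels = np.unique(partial)
    q = labels.size
    denom = params.alpha + i1
    scale = (i1 - params.delta * q) / denom
    probs = np.empty(q + 1)
    for idx, k in enumerate(labels):
        probs[idx] = scale * sims[partial == k].sum() / total
    probs[q] = (params.alpha + params.delta * q) / denom
    return labels, probs


def sample_alpha_west(
    n_clusters: int, n: int, params: EPAParams, rng: np.random.Generator
) -> float:
    """Draw alpha from Gamma(a + K - 1, rate = b + euler_gamma + log n)."""
    shape = params.a + n_clusters - 1
    if shape <= 0:
        raise ValueError("gamma shape a + K - 1 must be positive")
    rate = params.b + EULER_GAMMA + np.log(n)
    return float(rng.gamma(shape, 1.0 / rate))


class _ClusterStats:
    """Incremental sufficient statistics with a lazily cached vector of
    posterior-predictive log-densities for all n subjects."""

    __slots__ = ("members", "sum_x", "sum_xxT", "_cache")

    def __init__(self, p: int):
        self.members: list[int] = []
        self.sum_x = np.zeros(p)
        self.sum_xxT = np.zeros((p, p))
        self._cache: np.ndarray | None = None

    def add(self, i: int, x: np.ndarray) -> None:
        self.members.append(i)
        self.sum_x += x
        self.sum_xxT += np.outer(x, x)
        self._cache = None

    def logpred(self, X: np.ndarray, prior: NIWParams) -> np.ndarray:
        if self._cache is None:
            post = posterior_from_stats(prior, len(self.members), self.sum_x, self.sum_xxT)
            self._cache = log_predictive_batch(X, post)
        return self._cache


def _epa_sweep(
    rng: np.random.Generator,
    n: int,
    lam: np.ndarray,
    params: EPAParams,
    alpha: float,
    X: np.ndarray | None,
    prior: NIWParams | None,
    prior_logpred: np.ndarray | None,
) -> np.ndarray:
    """One full sequential reseating under a fresh uniform permutation."""
    sigma = rng.permutation(n)
    labels = np.zeros(n, dtype=np.int64)
    use_lik = X is not None
    clusters: list[_ClusterStats] = []
    p = X.shape[1] if use_lik else 0

    first = sigma[0]
    labels[first] = 1
    if use_lik:
        cs = _ClusterStats(p)
        cs.add(first, X[first])
        clusters.append(cs)
    q = 1
    for pos in range(2, n + 1):
        subj = sigma[pos - 1]
        i1 = pos - 1
        seated = sigma[:i1]
        sims = lam[subj, seated]
        total = sims.sum()
        denom = alpha + i1
        scale = (i1 - params.delta * q) / denom
        w = np.empty(q + 1)
        seated_labels = labels[seated]
        for k in range(1, q + 1):
            w[k - 1] = scale * sims[seated_labels == k].sum() / total
        w[q] = (alpha + params.delta * q) / denom
        if use_lik:
            loglik = np.empty(q + 1)
            for k in range(q):
                loglik[k] = clusters[k].logpred(X, prior)[subj]
            loglik[q] = prior_logpred[subj]
            logw = np.log(w) + loglik
            logw -= logw.max()
            w = np.exp(logw)
        choice = int(rng.choice(q + 1, p=w / w.sum()))
        if choice == q:  # open a new cluster
            q += 1
            labels[subj] = q
            if use_lik:
                clusters.append(_ClusterStats(p))
                clusters[-1].add(subj, X[subj])
        else:
            labels[subj] = choice + 1
            if use_lik:
                clusters[choice].add(subj, X[subj])
    return labels


def _collapsed_sweep(
    rng: np.random.Generator,
    labels: np.ndarray,
    lam: np.ndarray,
    params: EPAParams,
    alpha: float,
    X: np.ndarray | None,
    prior: NIWParams | None,
    prior_logpred: np.ndarray | None,
) -> np.ndarray:
    """One per-subject collapsed reseat: each subject is treated as the
    last arrival given everyone else (delta = 0 form), times the NIW
    predictive of its candidate table; a fresh singleton table is always
    on offer with mass alpha."""
    n = labels.size
    use_lik = X is not None
    lamsum = lam.sum(axis=1) - np.diag(lam)
    for i in range(n):
        labels[i] = 0
        uniq = np.unique(labels[labels > 0])
        q = uniq.size
        logw = np.empty(q + 1)
        for idx, k in enumerate(uniq):
            m = np.flatnonzero(labels == k)
            w = ((n - 1 - params.delta * q) / (alpha + n - 1)) * lam[i, m].sum() / lamsum[i]
            logw[idx] = np.log(w)
            if use_lik:
                Xm = X[m]
                post = posterior_from_stats(prior, m.size, Xm.sum(axis=0), Xm.T @ Xm)
                logw[idx] += log_predictive_batch(X[i][None, :], post)[0]
        logw[q] = np.log((alpha + params.delta * q) / (alpha + n - 1))
        if use_lik:
            logw[q] += prior_logpred[i]
        logw -= logw.max()
        pr = np.exp(logw)
        pr /= pr.sum()
        choice = int(rng.choice(q + 1, p=pr))
        labels[i] = int(uniq[choice]) if choice < q else (int(uniq.max()) + 1 if q else 1)
    _, inv = np.unique(labels, return_inverse=True)
    return (inv + 1).astype(np.int64)


def run_epa_sampler(
    X: np.ndarray | None = None,
    D: DistanceMatrix | None = None,
    config: SamplerConfig | None = None,
    params: EPAParams | None = None,
    constant_similarity: bool = False,
    niw: NIWParams | None = None,
    update_alpha: bool = True,
    scheme: str = "reseat",
) -> ChainRecord:
    """Gibbs-style EPA sampler sharing the TIP consensus machinery.

    With the default ``scheme="reseat"``, every iteration reseats all
    subjects sequentially under a fresh uniform permutation using the
    EPA conditionals (times the NIW predictive when the likelihood is
    on); ``scheme="collapsed"`` instead runs a persistent per-subject
    collapsed chain in which each subject is reseated given all others
    (last-arrival conditionals), which mixes like a standard DP-mixture
    sampler.  After each sweep alpha is updated from West's posterior
    given the realized cluster count (``update_alpha=False`` keeps
    alpha fixed at ``params.alpha``, making the likelihood-free reseat
    chain an exact sequential-seating sampler).  Setting
    ``constant_similarity=True`` together with ``delta=0`` gives the
    CRP baseline.
    """
    config = config or SamplerConfig()
    params = params or EPAParams()
    if scheme not in {"reseat", "collapsed"}:
        raise ValueError("scheme must be 'reseat' or 'collapsed'")
    X, D, L, niw_default = _prepare_inputs(X, D, config)
    if niw is None:
        niw = niw_default
    n = D.n
    lam = np.ones((n, n)) if constant_similarity else L.values
    rng = np.random.default_rng(config.seed)

    use_lik = config.use_likelihood
    Xl = X if use_lik else None
    prior_logpred = None
    if use_lik:
        empty = posterior_from_stats(niw, 0, np.zeros(niw.p), np.zeros((niw.p, niw.p)))
        prior_logpred = log_predictive_batch(X, empty)

    alpha = params.alpha
    labels = np.arange(1, n + 1, dtype=np.int64)  # collapsed chain state
    total = config.burn_in + config.samples
    draws = np.empty((config.samples, n), dtype=np.int64)
    K_trace = np.empty(total, dtype=np.int64)
    log_info: list[dict] = []
    for t in range(total):
        if scheme == "reseat":
            labels = _epa_sweep(rng, n, lam, params, alpha, Xl, niw, prior_logpred)
        else:
            labels = _collapsed_sweep(
                rng, labels, lam, params, alpha, Xl, niw, prior_logpred
            )
        K = int(labels.max())
        if update_alpha:
            alpha = sample_alpha_west(K, n, params, rng)
        K_trace[t] = K
        log_info.append({"K": K, "alpha": alpha})
        if t >= config.burn_in:
            draws[t - config.burn_in] = labels
    return ChainRecord(draws=draws, K_trace=K_trace, log_info=log_info, config=config)


def run_crp_sampler(
    X: np.ndarray | None = None,
    D: DistanceMatrix | None = None,
    config: SamplerConfig | None = None,
    params: EPAParams | None = None,
    niw: NIWParams | None = None,
    update_alpha: bool = True,
) -> ChainRecord:
    """CRP baseline: EPA with zero discount and constant similarity."""
    params = params or EPAParams()
    if params.delta != 0:
        raise ValueError("the CRP requires delta = 0")
    return run_epa_sampler(
        X=X, D=D, config=config, params=params, constant_similarity=True, niw=niw,
        update_alpha=update_alpha,
    )
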