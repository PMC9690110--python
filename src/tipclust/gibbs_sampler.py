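"""Collapsed Gibbs sampler driven by the Table Invitation Prior.

Each iteration: a host subject r is drawn uniformly, its invitation size
is sampled (Poisson with mean set by the first change point in r's
sorted distances), and the invited subjects are moved to a new table
K+1.  Every subject's seat is then re-sampled in turn from

    P(c_i = k)  propto  prior_weight(i, k) * predictive(x_i | table k)

over tables {1, ..., K+1}, where the prior weight is subject i's summed
similarity to table k's occupants and the predictive is the table's
NIW posterior-predictive density, both with subject i itself removed.
Two sweep styles are available:

* ``sequential`` (default): table memberships evolve as the sweep
  proceeds, i.e. the classic collapsed-Gibbs update.  This mixes far
  better — bulk moves proposed by the invitation are consolidated or
  undone one subject at a time within the same sweep.
* ``simultaneous``: all n seats are drawn independently from the
  weights computed on the frozen modified partition c-tilde (the
  literal one-shot reading of the prior; self-similarity included
  unless ``exclude_self``).

Tables emptied by the sweep are dropped and labels are relabelled
1..K at sweep end.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln

from .changepoint import (
    ChangePointConfig,
    ChangePointSet,
    binary_segmentation,
    estimate_invitation_size,
    sorted_row_distances,
)
from .niw_likelihood import (
    NIWParams,
    default_hyperparams,
    log_predictive_batch,
    loo_log_predictive,
    posterior_from_stats,
)
from .similarity import (
    DistanceMatrix,
    SimilarityMatrix,
    compute_distance_matrix,
    estimate_tau,
    similarity_matrix,
)
from .tip_prior import ChainState, invited_set, propose_partition, tip_prior_weights

__all__ = ["SamplerConfig", "ChainRecord", "initialize", "gibbs_iteration", "run_sampler"]


@dataclass(frozen=True)
class SamplerConfig:
    """Run-length, seeding and behavioural switches for the samplers."""

    burn_in: int = 1000
    samples: int = 1000
    seed: int = 0
    init: str = "one_cluster"
    init_k: int = 2  # only used by the random_k rule
    use_likelihood: bool = True
    sweep: str = "sequential"  # sequential | simultaneous
    shuffle_sweep: bool = False  # visit subjects in random order each sweep
    exclude_self: bool = False  # simultaneous sweep only
    metric: str = "euclidean"
    changepoint: ChangePointConfig = field(default_factory=ChangePointConfig)

    def __post_init__(self) -> None:
        if self.samples < 1:
            raise ValueError("samples must be >= 1")
        if self.burn_in < 0:
            raise ValueError("burn_in must be >= 0")
        if self.sweep not in {"sequential", "simultaneous"}:
            raise ValueError("sweep must be 'sequential' or 'simultaneous'")


@dataclass
class ChainRecord:
    """Post-burn-in draws plus per-iteration diagnostics."""

    draws: np.ndarray  # (samples, n) int labels
    K_trace: np.ndarray  # (burn_in + samples,) cluster counts
    log_info: list[dict]
    config: SamplerConfig

    @property
    def samples(self) -> int:
        return self.draws.shape[0]

    @property
    def n(self) -> int:
        return self.draws.shape[1]


def initialize(n: int, rule: str, rng: np.random.Generator, k: int = 2) -> ChainState:
    """Starting partition: everyone at one table, all singletons, or a
    seeded random k-label assignment (re-drawn until all k labels occur)."""
    if rule == "one_cluster":
        return ChainState(np.ones(n, dtype=np.int64), t=0)
    if rule == "singletons":
        return ChainState(np.arange(1, n + 1, dtype=np.int64), t=0)
    if rule == "random_k":
        if not 1 <= k <= n:
            raise ValueError(f"random_k needs 1 <= k <= {n}")
        while True:
            labels = rng.integers(1, k + 1, size=n)
            if np.unique(labels).size == k:
                return ChainState(labels.astype(np.int64), t=0)
    raise ValueError(f"unknown initialization rule {rule!r}")


def _relabel(labels: np.ndarray) -> np.ndarray:
    """Map labels onto contiguous 1..K preserving numeric order."""
    _, inv = np.unique(labels, return_inverse=True)
    return (inv + 1).astype(np.int64)


class _TableCache:
    """Per-table sufficient statistics with lazily refreshed predictive
    parameters (location, inverse scale, log-determinant, t constant)."""

    __slots__ = ("prior", "p", "cnt", "sx", "sxx", "_params", "_dirty")

    def __init__(self, prior: NIWParams, K1: int):
        self.prior = prior
        p = prior.p
        self.p = p
        self.cnt = np.zeros(K1, dtype=np.int64)
        self.sx = np.zeros((K1, p))
        self.sxx = np.zeros((K1, p, p))
        self._params: list[tuple | None] = [None] * K1
        self._dirty = [True] * K1

    def add(self, k: int, x: np.ndarray) -> None:
        self.cnt[k] += 1
        self.sx[k] += x
        self.sxx[k] += np.outer(x, x)
        self._dirty[k] = True

    def remove(self, k: int, x: np.ndarray) -> None:
        self.cnt[k] -= 1
        self.sx[k] -= x
        self.sxx[k] -= np.outer(x, x)
        self._dirty[k] = True

    def _refresh(self, k: int) -> tuple:
        pr, p = self.prior, self.p
        post = posterior_from_stats(pr, int(self.cnt[k]), self.sx[k], self.sxx[k])
        nu = post.nu1 - p + 1
        scale = post.Psi1 * (post.lambda1 + 1) / (post.lambda1 * nu)
        inv = np.linalg.inv(scale)
        sign, logdet = np.linalg.slogdet(scale)
        const = float(
            gammaln((nu + p) / 2) - gammaln(nu / 2) - (p / 2) * np.log(nu * np.pi)
        ) - 0.5 * logdet
        params = (post.mu1, inv, const, nu, p)
        self._params[k] = params
        self._dirty[k] = False
        return params

    def logpred(self, k: int, x: np.ndarray) -> float:
        params = self._params[k] if not self._dirty[k] else self._refresh(k)
        mu1, inv, const, nu, p = params
        d = x - mu1
        maha = float(d @ inv @ d)
        return const - ((nu + p) / 2) * np.log1p(maha / nu)


def _sequential_sweep(
    labels: np.ndarray,
    K1: int,
    X: np.ndarray | None,
    lam: np.ndarray,
    niw: NIWParams | None,
    use_likelihood: bool,
    order: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Collapsed per-subject reseating over tables {1..K1}; labels are
    0-based internally and evolve as the sweep proceeds."""
    n = labels.size
    W = lam @ np.eye(K1)[labels]  # (n, K1) summed similarity to each table
    cache = None
    if use_likelihood:
        cache = _TableCache(niw, K1)
        for k in range(K1):
            members = np.flatnonzero(labels == k)
            if members.size:
                Xm = X[members]
                cache.cnt[k] = members.size
                cache.sx[k] = Xm.sum(axis=0)
                cache.sxx[k] = Xm.T @ Xm
    neglog = -np.log(rng.random((n, K1)))  # exponential variates for Gumbel-max
    for i in order:
        ki = labels[i]
        # remove subject i from play: its own table's weight loses lambda(i,.)
        W[:, ki] -= lam[:, i]
        if use_likelihood:
            cache.remove(ki, X[i])
        w = W[i]
        with np.errstate(divide="ignore"):
            logw = np.log(np.maximum(w, 0.0))
        if use_likelihood:
            for k in range(K1):
                if w[k] > 0:
                    logw[k] += cache.logpred(k, X[i])
        # Gumbel-max draw using this subject's pre-drawn exponentials
        knew = int(np.argmax(logw - np.log(neglog[i])))
        labels[i] = knew
        W[:, knew] += lam[:, i]
        if use_likelihood:
            cache.add(knew, X[i])
    return labels


def _simultaneous_sweep(
    proposal_assignments: np.ndarray,
    K1: int,
    X: np.ndarray | None,
    L: SimilarityMatrix,
    niw: NIWParams | None,
    config: SamplerConfig,
    rng: np.random.Generator,
    proposal,
) -> np.ndarray:
    """All n seats drawn independently from the frozen modified partition."""
    n = proposal_assignments.size
    W = tip_prior_weights(L, proposal, exclude_self=config.exclude_self)
    with np.errstate(divide="ignore"):
        logw = np.log(W)
    if config.use_likelihood:
        loglik = np.zeros((n, K1))
        for k in range(1, K1 + 1):
            members = np.flatnonzero(proposal_assignments == k)
            if members.size == 0:
                continue
            Xm = X[members]
            post = posterior_from_stats(niw, members.size, Xm.sum(axis=0), Xm.T @ Xm)
            loglik[:, k - 1] = log_predictive_batch(X, post)
            loglik[members, k - 1] = loo_log_predictive(Xm, niw)
        logw = logw + loglik
    gumbel = -np.log(-np.log(rng.random((n, K1))))
    return np.argmax(logw + gumbel, axis=1) + 1


def gibbs_iteration(
    state: ChainState,
    D: DistanceMatrix,
    L: SimilarityMatrix,
    niw: NIWParams | None,
    X: np.ndarray | None,
    config: SamplerConfig,
    rng: np.random.Generator,
    changepoint_cache: dict[int, ChangePointSet] | None = None,
) -> tuple[ChainState, dict]:
    """One full sweep; returns the new state and a diagnostics record."""
    n = D.n
    if n == 1:
        return ChainState(np.array([1], dtype=np.int64), t=state.t + 1), {
            "r": 0, "n_tau": 1, "K": 1,
        }
    if config.use_likelihood and (X is None or niw is None):
        raise ValueError("use_likelihood=True requires the data matrix X")
    r = int(rng.integers(n))
    cps = changepoint_cache.get(r) if changepoint_cache is not None else None
    size = estimate_invitation_size(D, r, rng, config.changepoint, changepoints=cps)
    invited = invited_set(L, r, size)
    proposal = propose_partition(state, invited)
    K1 = proposal.new_label

    if config.sweep == "sequential":
        order = rng.permutation(n) if config.shuffle_sweep else np.arange(n)
        labels0 = (proposal.assignments - 1).astype(np.int64)
        new_labels = (
            _sequential_sweep(
                labels0, K1, X, L.values, niw, config.use_likelihood, order, rng
            )
            + 1
        )
    else:
        new_labels = _simultaneous_sweep(
            proposal.assignments, K1, X, L, niw, config, rng, proposal
        )
    new_labels = _relabel(new_labels)
    new_state = ChainState(new_labels, t=state.t + 1)
    info = {"r": r, "n_tau": size.n_tau, "K": int(new_labels.max())}
    return new_state, info


def _prepare_inputs(
    X: np.ndarray | None,
    D: DistanceMatrix | None,
    config: SamplerConfig,
) -> tuple[np.ndarray | None, DistanceMatrix, SimilarityMatrix, NIWParams | None]:
    if D is None:
        if X is None:
            raise ValueError("supply a data matrix X or a distance matrix D")
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        D = compute_distance_matrix(X, metric=config.metric)
    elif X is not None:
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        if X.shape[0] != D.n:
            raise ValueError("X and D disagree on the number of subjects")
    L = similarity_matrix(D, estimate_tau(D))
    niw = None
    if config.use_likelihood:
        if X is None:
            raise ValueError("use_likelihood=True requires the data matrix X")
        niw = default_hyperparams(X)
    return X, D, L, niw


def run_sampler(
    X: np.ndarray | None = None,
    D: DistanceMatrix | None = None,
    config: SamplerConfig | None = None,
    niw: NIWParams | None = None,
) -> ChainRecord:
    """Run the TIP Gibbs sampler and record the post-burn-in draws.

    Either the subjects-by-features matrix ``X`` or a precomputed
    ``DistanceMatrix`` may be given (both, to use a custom metric with
    the likelihood).  Fully reproducible given ``config.seed``.
    """
    config = config or SamplerConfig()
    X, D, L, niw_default = _prepare_inputs(X, D, config)
    if niw is None:
        niw = niw_default
    n = D.n
    rng = np.random.default_rng(config.seed)
    state = initialize(n, config.init, rng, k=config.init_k)

    # binary segmentation is deterministic per host: precompute once
    cache = {
        r: ChangePointSet(
            binary_segmentation(
                sorted_row_distances(D, r), config.changepoint, n_subjects=n
            ).locations,
            source_subject=r,
        )
        for r in range(n)
    }

    total = config.burn_in + config.samples
    draws = np.empty((config.samples, n), dtype=np.int64)
    K_trace = np.empty(total, dtype=np.int64)
    log_info: list[dict] = []
    for t in range(total):
        state, info = gibbs_iteration(
            state, D, L, niw, X, config, rng, changepoint_cache=cache
        )
        K_trace[t] = info["K"]
        log_info.append(info)
        if t >= config.burn_in:
            draws[t - config.burn_in] = state.assignments
    return ChainRecord(draws=draws, K_trace=K_trace, log_info=log_info, config=config)
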