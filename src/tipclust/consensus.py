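"""Posterior similarity matrix and PEAR consensus partition.

Every posterior draw c_t is turned into a binary co-clustering
(proximity) matrix; their entrywise mean is the posterior similarity
matrix B-bar, whose (i, j) entry estimates the probability that subjects
i and j share a cluster.  A single consensus partition is chosen among
the sampled draws as the maximizer of the posterior expected adjusted
Rand index (PEAR) against B-bar.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "PosteriorSimilarityMatrix",
    "ConsensusResult",
    "proximity_matrix",
    "posterior_similarity",
    "pear",
    "select_consensus",
]


@dataclass(frozen=True)
class PosteriorSimilarityMatrix:
    values: np.ndarray
    draws_used: int

    @property
    def n(self) -> int:
        return self.values.shape[0]


@dataclass(frozen=True)
class ConsensusResult:
    assignment: np.ndarray
    pear_value: float
    argmax_index: int
    pear_trace: np.ndarray


def proximity_matrix(c: np.ndarray) -> np.ndarray:
    """Binary co-clustering indicator matrix of one partition."""
    c = np.asarray(c)
    return (c[:, None] == c[None, :]).astype(float)


def posterior_similarity(Bs) -> PosteriorSimilarityMatrix:
    """Entrywise mean of proximity matrices (or of an iterable of draws)."""
    Bs = list(Bs)
    if not Bs:
        raise ValueError("need at least one proximity matrix")
    stack = np.stack([np.asarray(B, dtype=float) for B in Bs])
    return PosteriorSimilarityMatrix(values=stack.mean(axis=0), draws_used=len(Bs))


def posterior_similarity_from_draws(draws: np.ndarray) -> PosteriorSimilarityMatrix:
    """B-bar computed directly from a (T, n) array of label draws."""
    draws = np.asarray(draws)
    T, n = draws.shape
    B = np.zeros((n, n))
    for t in range(T):
        B += proximity_matrix(draws[t])
    return PosteriorSimilarityMatrix(values=B / T, draws_used=T)


def _pair_sums(c: np.ndarray, Bbar: np.ndarray) -> tuple[float, float, float, float]:
    n = c.size
    iu = np.triu_indices(n, k=1)
    I = (c[:, None] == c[None, :])[iu].astype(float)
    b = Bbar[iu]
    return float((I * b).sum()), float(I.sum()), float(b.sum()), n * (n - 1) / 2


def pear(c: np.ndarray, Bbar: PosteriorSimilarityMatrix | np.ndarray) -> float:
    """Posterior expected adjusted Rand index of partition ``c`` vs B-bar.

    Linear in the pairwise co-clustering indicators: with
    I_ij = 1{c_i = c_j}, C = n(n-1)/2,

        PEAR = [sum I B - (sum I)(sum B)/C]
               / [(sum I + sum B)/2 - (sum I)(sum B)/C]

    (sums over i < j).  A degenerate 0/0 returns 0 by convention.
    """
    B = Bbar.values if isinstance(Bbar, PosteriorSimilarityMatrix) else np.asarray(Bbar)
    c = np.asarray(c)
    if c.size != B.shape[0]:
        raise ValueError("partition length does not match B-bar size")
    if c.size < 2:
        raise ValueError("need at least 2 subjects")
    sIB, sI, sB, C = _pair_sums(c, B)
    expected = sI * sB / C
    denom = 0.5 * (sI + sB) - expected
    if denom == 0:
        return 0.0
    return (sIB - expected) / denom


def select_consensus(draws: np.ndarray, Bbar: PosteriorSimilarityMatrix) -> ConsensusResult:
    """The sampled draw maximizing PEAR; ties go to the earliest draw."""
    draws = np.asarray(draws)
    if draws.ndim != 2 or draws.shape[0] == 0:
        raise ValueError("draws must be a nonempty (T, n) array")
    trace = np.array([pear(draws[t], Bbar) for t in range(draws.shape[0])])
    best = int(np.argmax(trace))  # argmax returns the first maximizer
    return ConsensusResult(
        assignment=draws[best].copy(),
        pear_value=float(trace[best]),
        argmax_index=best,
        pear_trace=trace,
    )
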