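"""The Table Invitation Prior: invitation, proposal, and seating weights.

A host subject r invites the ``n_tau - 1`` subjects most similar to it
(plus itself) to a brand-new table labelled K+1, producing a modified
partition c-tilde.  The prior probability that subject i sits at table k
is then proportional to the summed similarity between i and the current
occupants of table k under c-tilde.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .changepoint import InvitationSize
from .similarity import SimilarityMatrix

__all__ = [
    "InvitedSet",
    "ChainState",
    "ProposedPartition",
    "invited_set",
    "propose_partition",
    "tip_prior_probs",
    "tip_prior_weights",
]


@dataclass(frozen=True)
class InvitedSet:
    host: int
    members: tuple[int, ...]  # includes the host


@dataclass
class ChainState:
    """Cluster assignments (labels 1..K, all nonempty) at iteration t."""

    assignments: np.ndarray
    t: int = 0

    @property
    def n(self) -> int:
        return self.assignments.size

    @property
    def K(self) -> int:
        return int(self.assignments.max())

    def validate(self) -> None:
        labels = np.unique(self.assignments)
        if not np.array_equal(labels, np.arange(1, labels.size + 1)):
            raise ValueError("labels must be contiguous 1..K with none empty")


@dataclass(frozen=True)
class ProposedPartition:
    assignments: np.ndarray  # labels over {1..K+1}
    new_label: int
    invited: InvitedSet


def invited_set(L: SimilarityMatrix, r: int, size: InvitationSize | int) -> InvitedSet:
    """The host r plus its ``n_tau - 1`` most similar subjects.

    Ties in similarity are broken by ascending subject index so the
    invitation is deterministic.
    """
    n_tau = size.n_tau if isinstance(size, InvitationSize) else int(size)
    n = L.n
    if not 1 <= n_tau <= n - 1:
        raise ValueError(f"n_tau must be in [1, {n - 1}], got {n_tau}")
    if n_tau == 1:
        return InvitedSet(host=r, members=(r,))
    sims = L.values[r].copy()
    sims[r] = -np.inf  # host handled separately
    # stable argsort on (-similarity, index): descending similarity,
    # ties by ascending subject index
    order = np.lexsort((np.arange(n), -sims))
    members = tuple(sorted([r, *order[: n_tau - 1].tolist()]))
    return InvitedSet(host=r, members=members)


def propose_partition(state: ChainState, invited: InvitedSet) -> ProposedPartition:
    """Move every invited subject to the new table K+1; others keep their seat."""
    new_label = state.K + 1
    assignments = state.assignments.copy()
    assignments[list(invited.members)] = new_label
    return ProposedPartition(assignments=assignments, new_label=new_label, invited=invited)


def tip_prior_weights(
    L: SimilarityMatrix, proposal: ProposedPartition, exclude_self: bool = False
) -> np.ndarray:
    """Unnormalized seating weights for all subjects at once.

    Returns an (n, K+1) matrix whose (i, k-1) entry is the sum of
    lambda(i, j) over subjects j seated at table k under c-tilde.  By
    default the self-similarity term (j = i, lambda = 1) is included,
    following the literal sum; ``exclude_self=True`` gives the
    leave-self-out variant common in distance-dependent priors.
    """
    n = L.n
    K1 = proposal.new_label
    onehot = np.zeros((n, K1))
    onehot[np.arange(n), proposal.assignments - 1] = 1.0
    W = L.values @ onehot
    if exclude_self:
        W[np.arange(n), proposal.assignments - 1] -= 1.0  # lambda(i,i) == 1
        np.clip(W, 0.0, None, out=W)
    return W


def tip_prior_probs(
    L: SimilarityMatrix, proposal: ProposedPartition, i: int, exclude_self: bool = False
) -> np.ndarray:
    """Normalized prior probability of subject i over tables {1..K+1}."""
    w = tip_prior_weights(L, proposal, exclude_self=exclude_self)[i]
    total = w.sum()
    if total <= 0:
        raise RuntimeError("all seating weights are zero; similarity matrix is degenerate")
    return w / total
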