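"""Invitation-size estimation via change points in sorted distances.

For a randomly chosen host subject r, the distances from r to everyone
else are sorted ascending and a greedy binary-segmentation change-point
detector is run on the resulting monotone sequence.  The position of the
first detected change point counts how many near neighbours r has before
the first break in its distance profile; the number of invited subjects
is then drawn as ``Poisson(position)``, clamped into {1, ..., n-1}.

The segment cost is the Gaussian mean-change cost (sum of squared
deviations from the segment mean) and a split is accepted only when the
cost reduction exceeds a BIC-style penalty of ``log(len(y))`` per change
point.  Change-point positions are 1-based and denote the last index of
the left segment.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .similarity import DistanceMatrix

__all__ = [
    "ChangePointConfig",
    "ChangePointSet",
    "InvitationSize",
    "sorted_row_distances",
    "binary_segmentation",
    "estimate_invitation_size",
]


@dataclass(frozen=True)
class ChangePointConfig:
    """Binary-segmentation settings.

    ``Q`` is the maximum number of change points; when ``None`` it
    defaults per sequence to ``floor(n/2 + 1)`` where n is the subject
    count (sequence length + 1).
    """

    Q: int | None = None
    min_segment: int = 1
    penalty: float | None = None  # None -> log(len(y))

    def max_changepoints(self, n_subjects: int) -> int:
        if self.Q is not None:
            if self.Q < 1:
                raise ValueError("Q must be a positive integer")
            return self.Q
        return int(np.floor(n_subjects / 2 + 1))


@dataclass(frozen=True)
class ChangePointSet:
    """Sorted 1-based positions of detected change points for one host."""

    locations: tuple[int, ...]
    source_subject: int = -1


@dataclass(frozen=True)
class InvitationSize:
    n_tau: int
    mean_used: float


def sorted_row_distances(D: DistanceMatrix, r: int) -> np.ndarray:
    """Distances from subject ``r`` to the other n-1 subjects, ascending."""
    if not 0 <= r < D.n:
        raise IndexError(f"subject index {r} out of range for n={D.n}")
    row = np.delete(D.values[r], r)
    return np.sort(row)


def _sse(y: np.ndarray, csum: np.ndarray, csq: np.ndarray, a: int, b: int) -> float:
    """Sum of squared deviations from the mean of y[a:b] (half-open)."""
    m = b - a
    s = csum[b] - csum[a]
    return float(csq[b] - csq[a] - s * s / m)


def binary_segmentation(y: np.ndarray, config: ChangePointConfig | None = None,
                        n_subjects: int | None = None) -> ChangePointSet:
    """Greedy recursive mean-change segmentation of a 1-D sequence.

    At each step the admissible split with the largest penalized cost
    reduction is taken; splitting stops when ``Q`` change points have
    been placed or no split reduces the cost by more than the penalty.
    Returned positions are 1-based last-indices of left segments.
    """
    y = np.asarray(y, dtype=float)
    config = config or ChangePointConfig()
    m = y.size
    if n_subjects is None:
        n_subjects = m + 1
    if m < 2 * config.min_segment:
        return ChangePointSet(locations=())
    q_max = config.max_changepoints(n_subjects)
    penalty = config.penalty if config.penalty is not None else float(np.log(m))

    csum = np.concatenate(([0.0], np.cumsum(y)))
    csq = np.concatenate(([0.0], np.cumsum(y * y)))

    def best_split(a: int, b: int) -> tuple[float, int]:
        """Largest cost reduction over admissible splits of y[a:b]."""
        base = _sse(y, csum, csq, a, b)
        best_gain, best_pos = -np.inf, -1
        for s in range(a + config.min_segment, b - config.min_segment + 1):
            gain = base - _sse(y, csum, csq, a, s) - _sse(y, csum, csq, s, b)
            if gain > best_gain + 1e-12:
                best_gain, best_pos = gain, s
        return best_gain, best_pos

    # candidate segments as (a, b) half-open intervals
    locations: list[int] = []
    segments = [(0, m)]
    while len(locations) < q_max:
        best = None
        for seg in segments:
            a, b = seg
            if b - a < 2 * config.min_segment:
                continue
            gain, pos = best_split(a, b)
            if pos >= 0 and gain > penalty and (best is None or gain > best[0]):
                best = (gain, pos, seg)
        if best is None:
            break
        _, pos, seg = best
        segments.remove(seg)
        segments.extend([(seg[0], pos), (pos, seg[1])])
        locations.append(pos)  # 1-based: pos == last index of left segment
    return ChangePointSet(locations=tuple(sorted(locations)))


def estimate_invitation_size(
    D: DistanceMatrix,
    r: int,
    rng: np.random.Generator,
    config: ChangePointConfig | None = None,
    changepoints: ChangePointSet | None = None,
) -> InvitationSize:
    """Draw the invitation size for host ``r``.

    The Poisson mean is the position of the first change point in r's
    sorted distances; when no change point is found the neutral fallback
    ``max(1, floor((n-1)/2))`` is used.  The draw is clamped into
    {1, ..., n-1}.  A precomputed ``changepoints`` set may be supplied
    (binary segmentation is deterministic per host, so caching is exact).
    """
    n = D.n
    if changepoints is None:
        y = sorted_row_distances(D, r)
        changepoints = ChangePointSet(
            binary_segmentation(y, config, n_subjects=n).locations, source_subject=r
        )
    if changepoints.locations:
        mean_used = float(changepoints.locations[0])
    else:
        mean_used = float(max(1, (n - 1) // 2))
    draw = int(rng.poisson(mean_used))
    n_tau = int(np.clip(draw, 1, n - 1))
    return InvitationSize(n_tau=n_tau, mean_used=mean_used)
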