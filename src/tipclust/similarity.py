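"""Pairwise distances and the exponential-decay similarity kernel.

The Table Invitation Prior operates on attraction weights
``lambda(i, j) = exp(-tau * d_ij)`` derived from a pairwise distance
matrix.  The scale ``tau`` is estimated automatically as the reciprocal
of the median off-diagonal distance, so a pair at the median distance
has similarity ``exp(-1)``, coincident subjects have similarity 1, and
far-apart pairs decay towards 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import pdist, squareform

__all__ = [
    "DistanceMatrix",
    "SimilarityScale",
    "SimilarityMatrix",
    "compute_distance_matrix",
    "estimate_tau",
    "similarity_matrix",
]

_METRICS = {"euclidean": "euclidean", "manhattan": "cityblock", "correlation": "correlation"}


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric n x n nonnegative distances with a zero diagonal."""

    values: np.ndarray
    subject_ids: list[str] = field(default_factory=list)

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("distance matrix must be square")
        if not np.all(np.isfinite(v)):
            raise ValueError("distance matrix contains non-finite entries")
        if np.any(v < 0):
            raise ValueError("distances must be nonnegative")
        if not np.allclose(v, v.T, atol=1e-8):
            raise ValueError("distance matrix is not symmetric (tolerance 1e-8)")
        # symmetrize exactly so downstream code can rely on v == v.T
        v = 0.5 * (v + v.T)
        np.fill_diagonal(v, 0.0)
        object.__setattr__(self, "values", v)
        if not self.subject_ids:
            object.__setattr__(self, "subject_ids", [str(i) for i in range(v.shape[0])])
        elif len(self.subject_ids) != v.shape[0]:
            raise ValueError("subject_ids length does not match matrix size")


@dataclass(frozen=True)
class SimilarityScale:
    """The kernel scale tau together with the median distance it came from."""

    tau: float
    median_distance: float

    def __post_init__(self) -> None:
        if not self.tau > 0:
            raise ValueError("tau must be positive")


@dataclass(frozen=True)
class SimilarityMatrix:
    """Entrywise exp(-tau * d); symmetric, unit diagonal, values in (0, 1]."""

    values: np.ndarray

    @property
    def n(self) -> int:
        return self.values.shape[0]


def compute_distance_matrix(
    X: np.ndarray, metric: str = "euclidean", subject_ids: list[str] | None = None
) -> DistanceMatrix:
    """Compute all pairwise distances between the rows of ``X``.

    Parameters
    ----------
    X : (n, p) array
        One subject per row; must be finite.
    metric : str
        One of ``euclidean`` (default), ``manhattan``, ``correlation``.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if not np.all(np.isfinite(X)):
        raise ValueError("input matrix contains non-finite entries")
    if X.shape[0] < 2:
        raise ValueError("need at least 2 subjects")
    if metric not in _METRICS:
        raise ValueError(f"unknown metric {metric!r}; choose from {sorted(_METRICS)}")
    D = squareform(pdist(X, metric=_METRICS[metric]))
    return DistanceMatrix(D, subject_ids=list(subject_ids) if subject_ids else [])


def upper_triangle(D: DistanceMatrix) -> np.ndarray:
    """The strictly-upper-triangular distances as a flat vector."""
    i, j = np.triu_indices(D.n, k=1)
    return D.values[i, j]


def estimate_tau(D: DistanceMatrix) -> SimilarityScale:
    """Set tau to 1 over the median of the strictly-upper-triangular distances.

    Raises if every pairwise distance is zero (the kernel scale is then
    undefined).
    """
    tri = upper_triangle(D)
    if tri.size == 0:
        raise ValueError("need at least one pair of subjects")
    if not np.any(tri > 0):
        raise ValueError("all pairwise distances are zero; tau is undefined")
    med = float(np.median(tri))
    if med == 0:
        # more than half the pairs coincide; fall back to the smallest
        # positive distance so the kernel stays finite
        med = float(np.min(tri[tri > 0]))
    return SimilarityScale(tau=1.0 / med, median_distance=med)


def similarity_matrix(D: DistanceMatrix, scale: SimilarityScale) -> SimilarityMatrix:
    """Exponential-decay similarities ``exp(-tau * d_ij)``."""
    lam = np.exp(-scale.tau * D.values)
    np.fill_diagonal(lam, 1.0)
    return SimilarityMatrix(lam)
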