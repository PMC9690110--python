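"""Independent brute-force reference implementations used by the tests.

Everything here is deliberately naive: costs are recomputed from
scratch, searches are exhaustive, probabilities come from closed-form
products.  These routines must stay independent of the package's
optimized code paths.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np


def naive_binseg(y, q_max: int, penalty: float, min_segment: int = 1) -> list[int]:
    """Greedy binary segmentation with naive O(m^2) cost evaluation."""
    y = np.asarray(y, dtype=float)

    def sse(seg):
        return float(np.sum((seg - seg.mean()) ** 2)) if seg.size else 0.0

    def best_split(a, b):
        base = sse(y[a:b])
        best_gain, best_pos = -np.inf, -1
        for s in range(a + min_segment, b - min_segment + 1):
            gain = base - sse(y[a:s]) - sse(y[s:b])
            if gain > best_gain + 1e-12:
                best_gain, best_pos = gain, s
        return best_gain, best_pos

    locations: list[int] = []
    segments = [(0, y.size)]
    while len(locations) < q_max:
        best = None
        for seg in segments:
            a, b = seg
            if b - a < 2 * min_segment:
                continue
            gain, pos = best_split(a, b)
            if pos >= 0 and gain > penalty and (best is None or gain > best[0]):
                best = (gain, pos, seg)
        if best is None:
            break
        _, pos, seg = best
        segments.remove(seg)
        segments.extend([(seg[0], pos), (pos, seg[1])])
        locations.append(pos)
    return sorted(locations)


def pear_from_draws(c, draws) -> float:
    """PEAR via per-draw adjusted-Rand numerators/denominators averaged
    separately (the posterior-expectation construction)."""
    c = np.asarray(c)
    n = c.size
    iu = np.triu_indices(n, k=1)
    C = n * (n - 1) / 2
    I = (c[:, None] == c[None, :])[iu].astype(float)
    nums, dens = [], []
    for ct in np.asarray(draws):
        J = (ct[:, None] == ct[None, :])[iu].astype(float)
        exp = I.sum() * J.sum() / C
        nums.append(float((I * J).sum() - exp))
        dens.append(float(0.5 * (I.sum() + J.sum()) - exp))
    den = np.mean(dens)
    return 0.0 if den == 0 else float(np.mean(nums) / den)


def ari_contingency(c1, c2) -> float:
    """Adjusted Rand index from the pair-count contingency table."""
    c1, c2 = np.asarray(c1), np.asarray(c2)
    n = c1.size
    labels1, labels2 = np.unique(c1), np.unique(c2)
    table = np.array(
        [[np.sum((c1 == a) & (c2 == b)) for b in labels2] for a in labels1]
    )

    def comb2(x):
        return x * (x - 1) / 2

    sum_ij = comb2(table).sum()
    sum_a = comb2(table.sum(axis=1)).sum()
    sum_b = comb2(table.sum(axis=0)).sum()
    C = comb2(n)
    expected = sum_a * sum_b / C
    denom = 0.5 * (sum_a + sum_b) - expected
    if denom == 0:
        return 1.0 if np.array_equal(np.searchsorted(labels1, c1),
                                     np.searchsorted(labels2, c2)) else 0.0
    return float((sum_ij - expected) / denom)


def crp_seating_probs(partial_labels, alpha: float) -> dict:
    """CRP conditional for the next customer given seated labels:
    existing table k gets |k|/(alpha + i - 1), a new table alpha/(alpha + i - 1)."""
    partial_labels = np.asarray(partial_labels)
    i1 = partial_labels.size
    out = {}
    for k in np.unique(partial_labels):
        out[int(k)] = float(np.sum(partial_labels == k) / (alpha + i1))
    out["new"] = float(alpha / (alpha + i1))
    return out


def crp_partition_prob(labels, alpha: float) -> float:
    """Probability of a labelled-in-order-of-appearance partition under
    sequential CRP seating."""
    labels = np.asarray(labels)
    prob = 1.0
    for i in range(1, labels.size):
        probs = crp_seating_probs(labels[:i], alpha)
        key = int(labels[i]) if labels[i] in labels[:i] else "new"
        prob *= probs[key]
    return prob


def all_spanning_trees_max_weight(W: np.ndarray) -> float:
    """Maximum spanning-tree weight by exhaustive enumeration (n <= 7)."""
    n = W.shape[0]
    edges = [(i, j, W[i, j]) for i in range(n) for j in range(i + 1, n) if W[i, j] > 0]
    best = -np.inf
    for subset in combinations(edges, n - 1):
        parent = list(range(n))

        def find(x):
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        ok = True
        for i, j, _ in subset:
            ri, rj = find(i), find(j)
            if ri == rj:
                ok = False
                break
            parent[ri] = rj
        if ok:
            best = max(best, sum(w for _, _, w in subset))
    return best


def set_partitions(items):
    """All set partitions of a list (Bell-number enumeration)."""
    items = list(items)
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for smaller in set_partitions(rest):
        for k in range(len(smaller)):
            yield smaller[:k] + [[first] + smaller[k]] + smaller[k + 1:]
        yield [[first]] + smaller
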