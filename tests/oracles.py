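"""Independent brute-force reference implementations used as test oracles.

These deliberately avoid the package's own algorithms: partitions are
enumerated exhaustively, silhouettes use explicit O(n^2) loops, and the
goodness-of-fit statistic is summed term by term.
"""

from itertools import combinations

import numpy as np


def brute_kmeans_1d(values, k):
    """Globally optimal 1-D k-means by exhaustive contiguous-partition search.

    Returns (within_ss, centers_decreasing). Optimal 1-D partitions are
    contiguous in sorted order, so enumerating boundary placements covers
    the full optimum.
    """
    v = np.sort(np.asarray(values, dtype=float))
    n = v.size
    best = (np.inf, None)
    for bounds in combinations(range(1, n), k - 1):
        edges = (0,) + bounds + (n,)
        ss = 0.0
        centers = []
        for lo, hi in zip(edges[:-1], edges[1:]):
            seg = v[lo:hi]
            c = seg.mean()
            centers.append(c)
            ss += float(np.sum((seg - c) ** 2))
        if ss < best[0] - 1e-12:
            best = (ss, centers)
    return best[0], np.array(sorted(best[1], reverse=True))


def brute_silhouette(values, labels):
    """Textbook per-point silhouette widths with explicit loops."""
    v = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    out = np.zeros(v.size)
    for i in range(v.size):
        own = labels == labels[i]
        if own.sum() == 1:
            out[i] = 0.0
            continue
        w = np.mean([abs(v[i] - v[j]) for j in range(v.size) if own[j] and j != i])
        b = np.inf
        for c in np.unique(labels):
            if c == labels[i]:
                continue
            members = labels == c
            if members.sum() == 0:
                continue
            b = min(b, np.mean([abs(v[i] - v[j]) for j in range(v.size) if members[j]]))
        mx = max(w, b)
        out[i] = 0.0 if mx == 0 else (b - w) / mx
    return out


def brute_hardy_weinberg(N):
    """Chi-square goodness-of-fit against HWE proportions, term by term."""
    N = np.asarray(N, dtype=float)
    n = N.sum()
    p = (2 * N[0] + N[1]) / (2 * n)
    expected = n * np.array([p**2, 2 * p * (1 - p), (1 - p) ** 2])
    total = 0.0
    for obs, exp in zip(N, expected):
        if exp < 1e-12:
            if obs > 0:
                total += obs * obs / max(exp, 1e-12)
        else:
            total += (obs - exp) ** 2 / exp
    return total


def brute_mahalanobis(x, mu, V):
    """Quadratic form with an explicit matrix inverse."""
    d = np.asarray(x, dtype=float) - np.asarray(mu, dtype=float)
    return float(d @ np.linalg.inv(V) @ d)
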