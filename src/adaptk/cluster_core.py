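"""One-dimensional clustering primitives and per-SNP cluster-quality features.

This module contains the numerical heart of the caller: an exact
dynamic-programming 1-D k-means (optimal partitions of sorted values are
contiguous, so the global optimum is computable and deterministic), the
dataset-wide consensus model of genotype-class centers, the three feature
families used to predict the number of clusters per SNP (residual sum of
squares R, Mahalanobis distance to the consensus D, and a Hardy-Weinberg
goodness-of-fit statistic H), and silhouette-width call confidences.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import EstimationError, ParameterError

GENOTYPE_CLASSES = ("AA", "AB", "BB")

#: Order-preserving injections of k decreasing cluster centers into the three
#: genotype classes (0=AA, 1=AB, 2=BB), for k = 1, 2, 3.
_INJECTIONS = {
    1: ((0,), (1,), (2,)),
    2: ((0, 1), (1, 2), (0, 2)),
    3: ((0, 1, 2),),
}

_EXPECTED_GUARD = 1e-12


@dataclass(frozen=True)
class ConsensusModel:
    """Dataset-wide genotype-class centers on the M scale and their spread.

    Attributes
    ----------
    mu : ndarray, shape (3,)
        Consensus centers for (AA, AB, BB), strictly decreasing.
    V : ndarray, shape (3, 3)
        Variance-covariance matrix of per-SNP center vectors.
    """

    mu: np.ndarray
    V: np.ndarray

    def __post_init__(self) -> None:
        mu = np.asarray(self.mu, dtype=float)
        V = np.asarray(self.V, dtype=float)
        object.__setattr__(self, "mu", mu)
        object.__setattr__(self, "V", V)
        if mu.shape != (3,) or not (mu[0] > mu[1] > mu[2]):
            raise EstimationError(f"consensus centers must be strictly decreasing, got {mu}")
        if V.shape != (3, 3) or not np.allclose(V, V.T, atol=1e-8):
            raise EstimationError("consensus variance-covariance matrix must be 3x3 symmetric")
        if np.linalg.eigvalsh((V + V.T) / 2.0).min() < -1e-9:
            raise EstimationError("consensus variance-covariance matrix must be PSD")


@dataclass
class ClusterFit:
    """Result of clustering one SNP's values into k groups.

    ``centers`` are reported in decreasing order; ``assignments[i]`` indexes
    into ``centers``. ``genotype_map`` (filled by
    :func:`map_clusters_to_genotypes`) gives, per cluster, the genotype class
    index (0=AA, 1=AB, 2=BB). ``degenerate`` flags fits where fewer than k
    distinct values forced duplicated centers; only the first ``k_eff``
    clusters are populated then.
    """

    k: int
    centers: np.ndarray
    assignments: np.ndarray
    within_ss: float
    genotype_map: tuple[int, ...] | None = None
    degenerate: bool = False
    k_eff: int = field(default=0)

    def __post_init__(self) -> None:
        if self.k_eff == 0:
            self.k_eff = self.k

    def cluster_sizes(self) -> np.ndarray:
        return np.bincount(self.assignments, minlength=self.k)


def _interval_cost(p1: np.ndarray, p2: np.ndarray, i, j):
    """Within-SS of sorted values v[i:j] from prefix sums p1, p2."""
    cnt = np.asarray(j) - np.asarray(i)
    cnt_safe = np.where(cnt > 0, cnt, 1)
    s = p1[j] - p1[i]
    return p2[j] - p2[i] - s * s / cnt_safe


def _optimal_boundaries(v_sorted: np.ndarray, k: int) -> list[int]:
    """Boundaries [0, b1, ..., n] of the globally optimal contiguous k-partition."""
    n = v_sorted.size
    p1 = np.concatenate(([0.0], np.cumsum(v_sorted)))
    p2 = np.concatenate(([0.0], np.cumsum(v_sorted * v_sorted)))
    if k == 1:
        return [0, n]
    if k == 2:
        s = np.arange(1, n)
        tot = _interval_cost(p1, p2, 0, s) + _interval_cost(p1, p2, s, n)
        return [0, int(s[np.argmin(tot)]), n]
    if k != 3:
        raise ParameterError(f"k must be in 1..3, got {k}")
    a = np.arange(1, n - 1)
    b = np.arange(2, n)
    if n <= 1500:
        A, B = np.meshgrid(a, b, indexing="ij")
        valid = A < B
        tot = np.where(
            valid,
            _interval_cost(p1, p2, 0, A)
            + _interval_cost(p1, p2, A, B)
            + _interval_cost(p1, p2, B, n),
            np.inf,
        )
        flat = int(np.argmin(tot))
        ai, bi = divmod(flat, tot.shape[1])
        return [0, int(a[ai]), int(b[bi]), n]
    # memory-bounded path for very wide datasets
    best = (np.inf, 1, 2)
    c0a = _interval_cost(p1, p2, 0, a)
    for bb in b:
        aa = a[a < bb]
        tot = c0a[: aa.size] + _interval_cost(p1, p2, aa, bb) + _interval_cost(p1, p2, bb, n)
        i = int(np.argmin(tot))
        if tot[i] < best[0]:
            best = (float(tot[i]), int(aa[i]), int(bb))
    return [0, best[1], best[2], n]


def kmeans_1d(values, k: int) -> ClusterFit:
    """Globally optimal 1-D k-means by contiguous partition of sorted values.

    Deterministic; centers returned in decreasing order. If fewer than k
    distinct values exist, a degenerate fit on the distinct count is returned
    with the last center duplicated and ``degenerate=True``.
    """
    v = np.asarray(values, dtype=float).ravel()
    if v.size == 0:
        raise ParameterError("kmeans_1d requires at least one value")
    if not (1 <= k <= 3):
        raise ParameterError(f"k must be in 1..3, got {k}")
    if not np.all(np.isfinite(v)):
        raise ParameterError("kmeans_1d requires finite values")

    n_distinct = np.unique(v).size
    k_eff = min(k, n_distinct)
    order = np.argsort(v, kind="stable")
    vs = v[order]
    bounds = _optimal_boundaries(vs, k_eff)

    centers = np.empty(k, dtype=float)
    assign_sorted = np.empty(v.size, dtype=np.int64)
    wss = 0.0
    # segment s (left to right, increasing mean) becomes cluster k_eff-1-s
    for s in range(k_eff):
        lo, hi = bounds[s], bounds[s + 1]
        seg = vs[lo:hi]
        c = float(seg.mean())
        centers[k_eff - 1 - s] = c
        assign_sorted[lo:hi] = k_eff - 1 - s
        wss += float(np.sum((seg - c) ** 2))
    if k_eff < k:
        centers[k_eff:] = centers[k_eff - 1]  # duplicated-center report
    assignments = np.empty(v.size, dtype=np.int64)
    assignments[order] = assign_sorted
    return ClusterFit(
        k=k,
        centers=centers,
        assignments=assignments,
        within_ss=wss,
        degenerate=k_eff < k,
        k_eff=k_eff,
    )


def kmeans_1d_seeded(values, init_centers) -> ClusterFit | None:
    """Lloyd's k-means from fixed starting centers (deterministic).

    Used for the final call assignment, seeded at the consensus class
    centers: unlike the globally SS-optimal partition, this respects the
    expected genotype-cluster geometry when cluster occupancies are very
    unbalanced. Returns None if any cluster is empty at an assignment step
    (the caller falls back to a smaller k).
    """
    v = np.asarray(values, dtype=float).ravel()
    centers = np.sort(np.asarray(init_centers, dtype=float))[::-1].copy()
    k = centers.size
    if k == 1:
        c = float(v.mean())
        return ClusterFit(
            k=1, centers=np.array([c]), assignments=np.zeros(v.size, dtype=np.int64),
            within_ss=float(np.sum((v - c) ** 2)),
        )
    asc = centers[::-1]
    assignments = None
    for _ in range(100):
        mid = (asc[:-1] + asc[1:]) / 2.0
        idx = np.searchsorted(mid, v)  # nearest center, ties to the lower
        sizes = np.bincount(idx, minlength=k)
        if (sizes == 0).any():
            return None
        new_asc = np.array([v[idx == c].mean() for c in range(k)])
        done = assignments is not None and np.array_equal(idx, assignments)
        assignments = idx
        asc = new_asc
        if done:
            break
    centers = asc[::-1].copy()
    labels = (k - 1 - assignments).astype(np.int64)
    wss = float(np.sum((v - centers[labels]) ** 2))
    return ClusterFit(k=k, centers=centers, assignments=labels, within_ss=wss)


def estimate_consensus(
    M: np.ndarray,
    mask: np.ndarray | None = None,
    snp_subset=None,
    max_snps: int = 20000,
    seed: int = 0,
) -> ConsensusModel:
    """Estimate consensus centers mu and their covariance V from k=3 fits.

    k-means with k=3 is run on each SNP's log-ratios separately; mu is the
    elementwise median of the per-SNP (AA, AB, BB) center vectors and V their
    sample variance-covariance. Degenerate SNPs are skipped. At most
    ``max_snps`` SNPs are used (seeded subsample) for speed.
    """
    M = np.asarray(M, dtype=float)
    if M.ndim != 2:
        raise ParameterError("M must be a SNP x sample matrix")
    idx = np.arange(M.shape[0]) if snp_subset is None else np.asarray(snp_subset, dtype=int)
    if idx.size == 0:
        raise ParameterError("snp_subset must be nonempty")
    if idx.size > max_snps:
        rng = np.random.default_rng(seed)
        idx = idx[np.sort(rng.choice(idx.size, size=max_snps, replace=False))]

    centers = []
    for i in idx:
        row = M[i]
        if mask is not None:
            row = row[~mask[i]]
        row = row[np.isfinite(row)]
        if row.size < 3 or np.unique(row).size < 3:
            continue
        fit = kmeans_1d(row, 3)
        if not fit.degenerate:
            centers.append(fit.centers)
    if not centers:
        raise EstimationError("no SNP yielded a non-degenerate 3-cluster fit")
    C = np.asarray(centers)
    mu = np.median(C, axis=0)
    V = np.cov(C, rowvar=False, ddof=1) if C.shape[0] > 1 else np.zeros((3, 3))
    V = np.atleast_2d(V)
    return ConsensusModel(mu=mu, V=V)


def map_clusters_to_genotypes(
    fit: ClusterFit,
    consensus: ConsensusModel,
    allowed_classes: tuple[int, ...] = (0, 1, 2),
) -> ClusterFit:
    """Assign genotype classes to clusters by nearest order-preserving injection.

    Chooses, among the order-preserving injections of the k_eff observed
    centers into the allowed genotype classes, the one minimizing the summed
    squared distance to the consensus centers. ``allowed_classes`` restricts
    the target classes (e.g. homozygotes only for hemizygous samples).
    """
    k = fit.k_eff
    best_map, best_cost = None, np.inf
    for inj in _INJECTIONS[k]:
        if any(c not in allowed_classes for c in inj):
            continue
        cost = float(np.sum((fit.centers[:k] - consensus.mu[list(inj)]) ** 2))
        if cost < best_cost:
            best_cost, best_map = cost, inj
    if best_map is None:
        raise ParameterError(
            f"no order-preserving injection of {k} clusters into classes {allowed_classes}"
        )
    fit.genotype_map = best_map
    return fit


@dataclass
class GenotypeCounts:
    """Genotype call counts and Hardy-Weinberg expected proportions.

    N holds counts for (AA, AB, BB); p is the empirical major-allele
    frequency (2*N_AA + N_AB) / (2n); r the HWE proportions
    (p^2, 2p(1-p), (1-p)^2).
    """

    N: np.ndarray
    n: int
    p: float
    r: np.ndarray

    @classmethod
    def from_counts(cls, N) -> "GenotypeCounts":
        N = np.asarray(N, dtype=float)
        n = int(N.sum())
        if n == 0:
            raise ParameterError("cannot form genotype counts from zero calls")
        p = (2.0 * N[0] + N[1]) / (2.0 * n)
        r = np.array([p * p, 2.0 * p * (1.0 - p), (1.0 - p) * (1.0 - p)])
        return cls(N=N, n=n, p=p, r=r)

    @classmethod
    def from_fit(cls, fit: ClusterFit) -> "GenotypeCounts":
        if fit.genotype_map is None:
            raise ParameterError("genotype_map must be populated before counting")
        N = np.zeros(3, dtype=float)
        sizes = fit.cluster_sizes()
        for cluster, cls_idx in enumerate(fit.genotype_map):
            N[cls_idx] += sizes[cluster]
        n = int(N.sum())
        if n == 0:
            raise ParameterError("cannot form genotype counts from an empty fit")
        p = (2.0 * N[0] + N[1]) / (2.0 * n)
        r = np.array([p * p, 2.0 * p * (1.0 - p), (1.0 - p) * (1.0 - p)])
        return cls(N=N, n=n, p=p, r=r)


def feature_R(values, fit: ClusterFit) -> float:
    """Residual sum of squares of a fit (clustering tightness)."""
    return float(fit.within_ss)


def feature_D(fit: ClusterFit, consensus: ConsensusModel) -> float:
    """Mahalanobis distance of cluster centers from the consensus centers.

    Uses the consensus subvector/submatrix of the mapped genotype classes;
    a pseudo-inverse handles singular submatrices.
    """
    if fit.genotype_map is None:
        raise ParameterError("genotype_map must be populated before computing D")
    cls = list(fit.genotype_map)
    d = fit.centers[: fit.k_eff] - consensus.mu[cls]
    V_sub = consensus.V[np.ix_(cls, cls)]
    D = float(d @ np.linalg.pinv(V_sub) @ d)
    return max(D, 0.0)


def feature_H(counts: GenotypeCounts) -> float:
    """Chi-square-style Hardy-Weinberg goodness-of-fit over the three classes.

    Expected counts are n*r_l. Classes with expected count ~0 contribute 0
    when the observed count is also 0; otherwise the guarded quotient
    N^2 / max(expected, 1e-12) is used.
    """
    expected = counts.n * counts.r
    H = 0.0
    for N_l, e_l in zip(counts.N, expected):
        if e_l < _EXPECTED_GUARD:
            if N_l > 0:
                H += N_l * N_l / max(e_l, _EXPECTED_GUARD)
        else:
            H += (N_l - e_l) ** 2 / e_l
    return float(H)


@dataclass
class SNPFeatures:
    """The 8 per-SNP predictors of the cluster count k.

    R[k-1], D[k-1] for k=1..3 and H[0], H[1] for k=2, 3 hold the raw
    statistics. ``as_vector`` — the regression interface — divides R and H
    by the observation count so a predictor trained on one cohort stays
    calibrated on groups of a different size (both statistics grow linearly
    with n at a fixed misfit level; D is already scale-free). The fits used
    are retained so callers can reuse the clustering at the chosen k.
    """

    R: np.ndarray
    D: np.ndarray
    H: np.ndarray
    fits: dict[int, ClusterFit]
    n_obs: int = 0
    degenerate_k: tuple[int, ...] = ()

    def as_vector(self) -> np.ndarray:
        n = max(self.n_obs, 1)
        return np.concatenate([self.R / n, self.D, self.H / n])


FEATURE_NAMES = ("R1", "R2", "R3", "D1", "D2", "D3", "H2", "H3")


def compute_features(
    values,
    consensus: ConsensusModel,
    allowed_classes: tuple[int, ...] = (0, 1, 2),
) -> SNPFeatures:
    """Run k-means for k=1,2,3 on one SNP and compute (R, D, H) features.

    H is not computed for k=1 (uninformative). Degenerate k values inherit
    the features of the largest non-degenerate fit and are flagged. With
    ``allowed_classes`` restricted to the homozygotes (hemizygous samples),
    H is left at 0 for all k: under the matching one-allele expectation the
    statistic is identically zero, so it carries no information.
    """
    v = np.asarray(values, dtype=float).ravel()
    v = v[np.isfinite(v)]
    if v.size < 3:
        raise ParameterError("compute_features requires at least 3 values")
    hemizygous = len(allowed_classes) < 3
    R = np.zeros(3)
    D = np.zeros(3)
    H = np.zeros(2)
    fits: dict[int, ClusterFit] = {}
    degenerate = []
    for k in (1, 2, 3):
        fit = kmeans_1d(v, k)
        if k == 3 and hemizygous:
            map_clusters_to_genotypes(fit, consensus)  # no 3-injection into 2 classes
        else:
            map_clusters_to_genotypes(fit, consensus, allowed_classes=allowed_classes)
        fits[k] = fit
        if fit.degenerate:
            degenerate.append(k)
        R[k - 1] = feature_R(v, fit)
        D[k - 1] = feature_D(fit, consensus)
        if k >= 2 and not hemizygous:
            H[k - 2] = feature_H(GenotypeCounts.from_fit(fit))
    return SNPFeatures(
        R=R, D=D, H=H, fits=fits, n_obs=v.size, degenerate_k=tuple(degenerate)
    )


def silhouette_widths(values, fit: ClusterFit) -> np.ndarray:
    """Per-point silhouette width SW = (b - w) / max(w, b) in [-1, 1].

    w is the mean absolute distance to the other members of the point's own
    cluster; b the smallest mean absolute distance to any other cluster.
    Points in singleton clusters get SW = 0 (PAM convention).
    """
    v = np.asarray(values, dtype=float).ravel()
    labels = np.asarray(fit.assignments)
    if v.size != labels.size:
        raise ParameterError("values and fit assignments differ in length")
    sizes = np.bincount(labels, minlength=fit.k)
    populated = np.flatnonzero(sizes > 0)
    if populated.size < 2:
        raise ParameterError("silhouette requires at least 2 populated clusters")
    dist = np.abs(v[:, None] - v[None, :])
    sums = np.stack([dist[:, labels == c].sum(axis=1) for c in populated], axis=1)
    own_col = np.searchsorted(populated, labels)
    own_size = sizes[populated][own_col]
    rows = np.arange(v.size)
    with np.errstate(invalid="ignore", divide="ignore"):
        w = np.where(own_size > 1, sums[rows, own_col] / np.maximum(own_size - 1, 1), 0.0)
    other = sums / sizes[populated][None, :].astype(float)
    other[rows, own_col] = np.inf
    b = other.min(axis=1)
    mx = np.maximum(w, b)
    sw = np.where(mx > 0, (b - w) / mx, 0.0)
    sw[own_size == 1] = 0.0
    return sw


def k1_confidence(values, center: float) -> np.ndarray:
    """Confidence in (0, 1] for single-cluster fits, where silhouette is undefined.

    Uses 1 / (1 + |v - center| / mad): a monotone within-cluster-tightness
    score (mad = median absolute deviation from the center).
    """
    v = np.asarray(values, dtype=float).ravel()
    dev = np.abs(v - center)
    mad = float(np.median(dev))
    if mad <= 0:
        mad = float(np.mean(dev))
    if mad <= 0:
        return np.ones_like(v)
    return 1.0 / (1.0 + dev / mad)


def confidence_scores(values, fit: ClusterFit) -> np.ndarray:
    """Silhouette widths when >=2 clusters are populated, else the k=1 score."""
    sizes = fit.cluster_sizes()
    if np.count_nonzero(sizes) >= 2:
        return silhouette_widths(values, fit)
    top = int(np.flatnonzero(sizes)[0])
    return k1_confidence(values, float(fit.centers[top]))
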