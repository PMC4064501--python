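"""Between-sample normalization and the log-ratio / average-signal transform.

The default pipeline quantile-normalizes each channel separately across
samples and works on M = log2(X*) - log2(Y*) and S = (log2(X*) + log2(Y*))/2.
An optional per-cluster loess correction removes intensity-dependent
curvature of the log-ratios; it is off by default because quantile
normalization alone gives the more accurate calls downstream.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from statsmodels.nonparametric.smoothers_lowess import lowess

from .cluster_core import ConsensusModel, ClusterFit, kmeans_1d
from .errors import DataError, ParameterError

logger = logging.getLogger(__name__)

_LOESS_MIN_POINTS = 10


@dataclass
class NormalizedSignal:
    """Normalized channels and the derived M (log-ratio) / S (average signal).

    Invariants: M + 2S = 2*log2(X*) and 2S - M = 2*log2(Y*) hold exactly
    wherever ``mask`` is unset.
    """

    Xstar: np.ndarray
    Ystar: np.ndarray
    M: np.ndarray
    S: np.ndarray
    mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.mask is None:
            self.mask = np.zeros(np.shape(self.M), dtype=bool)
        self.mask = np.asarray(self.mask, dtype=bool)

    def snp_values(self, i: int) -> tuple[np.ndarray, np.ndarray]:
        """Unmasked M values for SNP row i and their column indices."""
        cols = np.flatnonzero(~self.mask[i])
        return self.M[i, cols], cols


def quantile_normalize(
    channel: np.ndarray,
    reference: np.ndarray | None = None,
    mask: np.ndarray | None = None,
    sample_ids: list[str] | None = None,
) -> np.ndarray:
    """Between-sample quantile normalization of one channel.

    Without a reference, each column's sorted values are replaced by the
    across-column mean of order statistics, so all columns share the same
    empirical distribution afterwards. With a reference vector, each column
    is mapped onto the reference distribution (interpolating when lengths
    differ). Ties receive the mean of the reference quantiles they span.
    Masked cells are excluded and returned as NaN.
    """
    channel = np.asarray(channel, dtype=float)
    if channel.ndim != 2 or channel.shape[1] < 1:
        raise ParameterError("channel must be a SNP x sample matrix with >= 1 column")
    n_rows, n_cols = channel.shape
    if mask is None:
        mask = np.isnan(channel)
    else:
        mask = np.asarray(mask, dtype=bool) | np.isnan(channel)

    counts = (~mask).sum(axis=0)
    if (counts == 0).any():
        j = int(np.argmin(counts))
        name = sample_ids[j] if sample_ids else str(j)
        raise DataError(f"sample {name!r} has no unmasked values to normalize")

    grid = (np.arange(n_rows) + 0.5) / n_rows
    if reference is None:
        # mean quantile function across columns, evaluated on a common grid
        ref = np.zeros(n_rows)
        for j in range(n_cols):
            col = np.sort(channel[~mask[:, j], j])
            if col.size == n_rows:
                ref += col
            else:
                p = (np.arange(col.size) + 0.5) / col.size
                ref += np.interp(grid, p, col)
        ref /= n_cols
    else:
        ref = np.sort(np.asarray(reference, dtype=float).ravel())
        if ref.size != n_rows:
            p = (np.arange(ref.size) + 0.5) / ref.size
            ref = np.interp(grid, p, ref)

    out = np.full_like(channel, np.nan)
    ranks_ref = np.arange(1, n_rows + 1, dtype=float)
    for j in range(n_cols):
        keep = ~mask[:, j]
        col = channel[keep, j]
        n_j = col.size
        # average fractional ranks (ties get the mean of spanned quantiles)
        order = np.argsort(col, kind="stable")
        r = np.empty(n_j)
        r[order] = np.arange(1, n_j + 1, dtype=float)
        uniq, inv = np.unique(col, return_inverse=True)
        sums = np.bincount(inv, weights=r)
        cnts = np.bincount(inv)
        r = (sums / cnts)[inv]
        if n_j == n_rows:
            out[keep, j] = np.interp(r, ranks_ref, ref)
        else:
            p = (r - 0.5) / n_j
            out[keep, j] = np.interp(p, grid, ref)
    return out


def compute_MS(
    Xstar: np.ndarray,
    Ystar: np.ndarray,
    floor: float = 1.0,
    mask: np.ndarray | None = None,
) -> NormalizedSignal:
    """Clamp intensities at ``floor`` and compute M and S elementwise."""
    if floor <= 0:
        raise ParameterError(f"floor must be positive, got {floor}")
    Xstar = np.asarray(Xstar, dtype=float)
    Ystar = np.asarray(Ystar, dtype=float)
    if Xstar.shape != Ystar.shape:
        raise ParameterError("Xstar and Ystar must have the same shape")
    if mask is None:
        mask = np.isnan(Xstar) | np.isnan(Ystar)
    Xc = np.where(mask, np.nan, np.maximum(Xstar, floor))
    Yc = np.where(mask, np.nan, np.maximum(Ystar, floor))
    with np.errstate(invalid="ignore"):
        lx = np.log2(Xc)
        ly = np.log2(Yc)
    return NormalizedSignal(Xstar=Xc, Ystar=Yc, M=lx - ly, S=0.5 * (lx + ly), mask=mask)


def provisional_three_cluster_fits(signal: NormalizedSignal) -> list[ClusterFit | None]:
    """Per-SNP k=3 fits used for the loess correction and consensus add-back."""
    fits: list[ClusterFit | None] = []
    for i in range(signal.M.shape[0]):
        vals, _ = signal.snp_values(i)
        if vals.size < 3 or np.unique(vals).size < 3:
            fits.append(None)
            continue
        fits.append(kmeans_1d(vals, 3))
    return fits


def loess_correct(
    signal: NormalizedSignal,
    provisional_fits: list[ClusterFit | None],
    consensus: ConsensusModel,
    span: float = 0.3,
    subsample_cap: int = 50000,
    seed: int = 0,
) -> NormalizedSignal:
    """Remove intensity-dependent curvature of M within each major cluster.

    For each provisional genotype cluster (pooled across SNPs), a loess curve
    of M on S is fitted and subtracted; the consensus center is added back to
    the AA and BB clusters and the AB cluster is re-centered at 0. Clusters
    with too few points pass through uncorrected with a warning. X*/Y* are
    recomputed from the corrected M so the algebraic identities still hold.
    """
    if not (0 < span <= 1):
        raise ParameterError(f"span must be in (0, 1], got {span}")
    n_snps, n_samples = signal.M.shape
    classes = np.full((n_snps, n_samples), -1, dtype=np.int64)
    for i, fit in enumerate(provisional_fits):
        if fit is None:
            continue
        _, cols = signal.snp_values(i)
        # cluster index == class index for a k=3 fit (decreasing centers)
        classes[i, cols] = fit.assignments

    rng = np.random.default_rng(seed)
    M_new = signal.M.copy()
    addback = (consensus.mu[0], 0.0, consensus.mu[2])
    for cls in (0, 1, 2):
        pts = np.nonzero(classes == cls)
        s = signal.S[pts]
        m = signal.M[pts]
        if s.size < _LOESS_MIN_POINTS:
            warnings.warn(
                f"cluster {cls} has {s.size} points (<{_LOESS_MIN_POINTS}); "
                "loess correction skipped for it"
            )
            continue
        if s.size > subsample_cap:
            sel = rng.choice(s.size, size=subsample_cap, replace=False)
            fit_s, fit_m = s[sel], m[sel]
        else:
            fit_s, fit_m = s, m
        # it=0: robustness reweighting would discount genuine trend tails
        smooth = lowess(fit_m, fit_s, frac=span, it=0, return_sorted=True)
        xs, ys = smooth[:, 0], smooth[:, 1]
        xs, keep = np.unique(xs, return_index=True)
        ys = ys[keep]
        trend = np.interp(s, xs, ys)
        resid = m - trend
        resid -= np.median(resid)  # exact re-centering within the cluster
        M_new[pts] = resid + addback[cls]

    S = signal.S
    with np.errstate(invalid="ignore"):
        Xstar = np.exp2(S + M_new / 2.0)
        Ystar = np.exp2(S - M_new / 2.0)
    return NormalizedSignal(Xstar=Xstar, Ystar=Ystar, M=M_new, S=S, mask=signal.mask)


def normalize_dataset(
    dataset,
    method: str = "quantile",
    floor: float = 1.0,
    reference_x: np.ndarray | None = None,
    reference_y: np.ndarray | None = None,
    loess_span: float = 0.3,
    subsample_cap: int = 50000,
    seed: int = 0,
    consensus_out: list | None = None,
) -> NormalizedSignal:
    """Run the configured normalization pipeline on an IntensityDataset.

    method is one of {"quantile", "quantile_loess", "none"}. When loess is
    requested, the consensus model estimated from the pre-loess signal (used
    for the add-back) is appended to ``consensus_out`` if provided.
    """
    from .cluster_core import estimate_consensus

    if method not in ("quantile", "quantile_loess", "none"):
        raise ParameterError(f"unknown normalization method {method!r}")
    if method == "none":
        Xn, Yn = dataset.X, dataset.Y
    else:
        Xn = quantile_normalize(dataset.X, reference_x, dataset.mask, dataset.samples)
        Yn = quantile_normalize(dataset.Y, reference_y, dataset.mask, dataset.samples)
    signal = compute_MS(Xn, Yn, floor=floor, mask=dataset.mask)
    if method == "quantile_loess":
        fits = provisional_three_cluster_fits(signal)
        consensus = estimate_consensus(signal.M, mask=signal.mask, seed=seed)
        if consensus_out is not None:
            consensus_out.append(consensus)
        signal = loess_correct(
            signal, fits, consensus,
            span=loess_span, subsample_cap=subsample_cap, seed=seed,
        )
    return signal
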