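"""Predicting the per-SNP cluster count k and producing genotype calls.

A logistic regression on the 8 cluster-quality features (R1..R3, D1..D3,
H2, H3) predicts k in {1, 2, 3} for each SNP; k-means is then re-run at the
predicted k to obtain calls, scored by silhouette width. The regular
(multinomial) family is the default; proportional-odds ordered logistic is
retained as an option. Features are standardized internally and the
transform stored so saved predictors are portable.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit, softmax

from .cluster_core import (
    FEATURE_NAMES,
    ConsensusModel,
    compute_features,
    confidence_scores,
    kmeans_1d_seeded,
    map_clusters_to_genotypes,
)
from .errors import ConvergenceError, EstimationError, ParameterError
from .preprocess import NormalizedSignal

logger = logging.getLogger(__name__)

FAMILIES = ("regular_logistic", "ordered_logistic")

_PREDICTOR_MAGIC = "# adaptk-predictor v1"
_RIDGE_PENALTY = 1e-4


@dataclass
class KPredictor:
    """A fitted k-predictor with its feature standardization transform.

    For the regular family, ``coef`` is (n_classes, 8) and ``intercept``
    (n_classes,), producing softmax class scores. For the ordered family,
    ``coef`` is (8,) and ``intercept`` holds the n_classes-1 increasing
    thresholds of the proportional-odds model.
    """

    family: str
    classes: np.ndarray
    coef: np.ndarray
    intercept: np.ndarray
    feature_means: np.ndarray
    feature_sds: np.ndarray
    feature_names: tuple[str, ...] = FEATURE_NAMES
    training_meta: dict = field(default_factory=dict)

    def predict_proba(self, features: np.ndarray) -> np.ndarray:
        """Class probabilities over k = 1, 2, 3 (absent classes get 0)."""
        x = np.atleast_2d(np.asarray(features, dtype=float))
        if x.shape[1] != len(self.feature_names):
            raise ParameterError(
                f"expected {len(self.feature_names)} features, got {x.shape[1]}"
            )
        if not np.all(np.isfinite(x)):
            raise ParameterError("features must be finite")
        z = (x - self.feature_means) / self.feature_sds
        if self.family == "regular_logistic":
            scores = z @ self.coef.T + self.intercept
            if self.classes.size == 2:
                # sklearn stores one score row for binary problems
                scores = np.column_stack([-scores[:, 0], scores[:, 0]])
            p = softmax(scores, axis=1)
        else:
            xb = z @ self.coef
            cum = expit(self.intercept[None, :] - xb[:, None])
            cum = np.column_stack([np.zeros(len(xb)), cum, np.ones(len(xb))])
            p = np.diff(cum, axis=1)
            p = np.clip(p, 0.0, None)
            p /= p.sum(axis=1, keepdims=True)
        out = np.zeros((x.shape[0], 3))
        for idx, cls in enumerate(self.classes):
            out[:, int(cls) - 1] = p[:, idx]
        return out


def train_k_predictor(
    features: np.ndarray,
    true_k: np.ndarray,
    family: str = "regular_logistic",
    seed: int = 0,
) -> KPredictor:
    """Maximum-likelihood fit of the k-predictor on labelled SNP features.

    Features are standardized (mean 0, sd 1) before fitting. A near-separable
    or non-convergent regular fit falls back to a ridge-stabilized refit
    (penalty 1e-4) with a warning.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(true_k, dtype=int)
    if X.ndim != 2 or X.shape[1] != len(FEATURE_NAMES):
        raise ParameterError(f"features must be n x {len(FEATURE_NAMES)}")
    if X.shape[0] != y.size:
        raise ParameterError("features and labels differ in length")
    if not np.all(np.isfinite(X)):
        raise ParameterError("features must be finite")
    classes = np.unique(y)
    if classes.size < 2:
        raise EstimationError("training labels contain a single class")
    if not np.all(np.isin(classes, (1, 2, 3))):
        raise ParameterError("labels must be in {1, 2, 3}")
    if family not in FAMILIES:
        raise ParameterError(f"family must be one of {FAMILIES}")

    means = X.mean(axis=0)
    sds = X.std(axis=0, ddof=0)
    sds = np.where(sds > 0, sds, 1.0)
    Z = (X - means) / sds
    meta = {"n_train": int(X.shape[0]), "seed": int(seed), "family": family}

    if family == "regular_logistic":
        from sklearn.exceptions import ConvergenceWarning
        from sklearn.linear_model import LogisticRegression

        def _fit(C, max_iter=2000):
            model = LogisticRegression(
                C=C, solver="lbfgs", max_iter=max_iter, tol=1e-7, random_state=seed
            )
            with warnings.catch_warnings(record=True) as caught:
                warnings.simplefilter("always", ConvergenceWarning)
                model.fit(Z, y)
                converged = not any(
                    issubclass(w.category, ConvergenceWarning) for w in caught
                )
            return model, converged

        model, converged = _fit(C=1e6)  # ~unpenalized maximum likelihood
        if not converged:
            warnings.warn(
                "maximum-likelihood logistic fit did not converge (likely "
                "separation); refitting with ridge stabilization"
            )
            model, converged = _fit(C=1.0 / _RIDGE_PENALTY, max_iter=20000)
            meta["ridge_stabilized"] = True
            if not converged:
                raise ConvergenceError(
                    "multinomial logistic regression failed to converge even "
                    f"with ridge penalty {_RIDGE_PENALTY}"
                )
        meta["converged"] = True
        coef = np.asarray(model.coef_, dtype=float)
        intercept = np.asarray(model.intercept_, dtype=float)
        pred = KPredictor(
            family=family, classes=classes, coef=coef, intercept=intercept,
            feature_means=means, feature_sds=sds, training_meta=meta,
        )
    else:
        from statsmodels.miscmodels.ordinal_model import OrderedModel

        model = OrderedModel(y, Z, distr="logit")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = model.fit(method="lbfgs", maxiter=1000, disp=False)
        if not res.mle_retvals.get("converged", True):
            raise ConvergenceError(
                f"ordered logistic regression failed to converge: {res.mle_retvals}"
            )
        meta["converged"] = True
        beta = np.asarray(res.params[: Z.shape[1]], dtype=float)
        thresholds = model.transform_threshold_params(res.params)[1:-1]
        pred = KPredictor(
            family=family, classes=classes, coef=beta,
            intercept=np.asarray(thresholds, dtype=float),
            feature_means=means, feature_sds=sds, training_meta=meta,
        )
    acc = float(np.mean(predict_k_batch(X, pred)[0] == y))
    pred.training_meta["training_accuracy"] = acc
    logger.info("trained %s k-predictor on %d SNPs (accuracy %.4f)", family, y.size, acc)
    return pred


def predict_k(features: np.ndarray, predictor: KPredictor) -> tuple[int, np.ndarray]:
    """Predicted k (argmax probability; ties broken toward larger k)."""
    p = predictor.predict_proba(np.atleast_2d(features))[0]
    k = 3 - int(np.argmax(p[::-1]))
    return k, p


def predict_k_batch(features: np.ndarray, predictor: KPredictor):
    p = predictor.predict_proba(features)
    k = 3 - np.argmax(p[:, ::-1], axis=1)
    return k.astype(np.int64), p


@dataclass
class GenotypeCalls:
    """Genotype codes, confidences and predicted k for a set of SNPs.

    Codes are {0: NC, 1: AA, 2: AB, 3: BB}. NC entries keep their
    confidence recorded but are excluded from accuracy downstream.
    """

    calls: np.ndarray
    confidence: np.ndarray
    predicted_k: np.ndarray
    k_probabilities: np.ndarray
    snp_ids: list[str]
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int64)
        if not np.all(np.isin(self.calls, (0, 1, 2, 3))):
            raise ParameterError("genotype codes must be in {0, 1, 2, 3}")

    def n_called(self) -> int:
        return int(np.count_nonzero(self.calls))


def _restricted_k(probs: np.ndarray, allowed_k: tuple[int, ...]) -> tuple[int, np.ndarray]:
    """Zero out disallowed k, renormalize, and take argmax (ties -> larger k)."""
    p = probs.copy()
    for k in (1, 2, 3):
        if k not in allowed_k:
            p[k - 1] = 0.0
    total = p.sum()
    if total <= 0:
        p = np.array([1.0 if k in allowed_k else 0.0 for k in (1, 2, 3)])
        p /= p.sum()
    else:
        p /= total
    k = 3 - int(np.argmax(p[::-1]))
    return k, p


def _seeded_fit_is_stable(fit, consensus: ConsensusModel) -> bool:
    """Reject seeded fits whose centers drifted away from their classes.

    Each fitted center must lie nearest the consensus center of its own
    mapped class; Lloyd iterations on data that truly hold fewer clusters
    can otherwise walk a spare center into a real cluster and split it.
    """
    classes = list(fit.genotype_map)
    centers = fit.centers[: fit.k_eff]
    mus = consensus.mu[classes]
    nearest = np.argmin(np.abs(centers[:, None] - mus[None, :]), axis=1)
    if not np.array_equal(nearest, np.arange(len(classes))):
        return False
    # adjacent fitted centers much closer than their consensus classes
    # indicate one real cluster split in two
    for i in range(len(classes) - 1):
        gap = centers[i] - centers[i + 1]
        prior_gap = mus[i] - mus[i + 1]
        if prior_gap > 0 and gap / prior_gap < 0.5:
            return False
    return True


def _mapped_center_ssd(fit, consensus: ConsensusModel) -> float:
    classes = list(fit.genotype_map)
    return float(np.sum((fit.centers[: fit.k_eff] - consensus.mu[classes]) ** 2))


def _call_fit(values, feats, consensus, k: int, allowed_classes):
    """Best stable clustering at cluster count k, or None to fall back.

    Two candidates are considered: the exact (globally SS-optimal) fit and
    Lloyd's k-means seeded at the consensus class centers. They fail in
    complementary regimes — the exact fit splits a large cluster rather than
    isolating a near-singleton minor cluster; the seeded fit can bisect a
    skewed cluster that straddles a consensus midpoint — so both are vetted
    for stability and the one with mapped centers closest to the consensus
    wins. k=1 never fails.
    """
    dp = map_clusters_to_genotypes(feats.fits[k], consensus, allowed_classes=allowed_classes)
    if k == 1 or dp.k_eff == 1:
        return dp
    candidates = []
    if _seeded_fit_is_stable(dp, consensus):
        candidates.append(dp)
    seeded = kmeans_1d_seeded(values, consensus.mu[list(dp.genotype_map)])
    if seeded is not None:
        seeded = map_clusters_to_genotypes(seeded, consensus, allowed_classes=allowed_classes)
        if _seeded_fit_is_stable(seeded, consensus):
            candidates.append(seeded)
    if not candidates:
        return None
    return min(candidates, key=lambda f: _mapped_center_ssd(f, consensus))


def call_single_snp(
    values: np.ndarray,
    consensus: ConsensusModel,
    predictor: KPredictor,
    allowed_k: tuple[int, ...] = (1, 2, 3),
    allowed_classes: tuple[int, ...] = (0, 1, 2),
    force_fit: bool = False,
):
    """Features -> k prediction -> refit at k -> genotype codes + confidences.

    The final assignment refits Lloyd's k-means seeded at the consensus
    centers of the target genotype classes (the globally SS-optimal partition
    used for features can split a large homozygote cluster instead of
    isolating a near-singleton minor cluster); an empty seeded cluster falls
    back to the next smaller k. Returns (codes, confidences, k,
    probabilities) over the supplied values.
    """
    feats = compute_features(values, consensus, allowed_classes=allowed_classes)
    _, probs = predict_k(feats.as_vector(), predictor)
    k, probs = _restricted_k(probs, allowed_k)

    if force_fit:
        # naive baseline: the exact fit at k, consensus-mapped, no rescue
        fit = map_clusters_to_genotypes(
            feats.fits[k], consensus, allowed_classes=allowed_classes
        )
        codes = np.array(
            [fit.genotype_map[c] + 1 for c in fit.assignments], dtype=np.int64
        )
        return codes, confidence_scores(values, fit), k, probs

    fit = None
    k_try = k
    if k == 1 and 2 in allowed_k and len(allowed_classes) == 2:
        # hemizygous groups sit outside the predictor's training
        # distribution; a stable homozygote/homozygote split overrides a
        # k=1 proposal (the stability guard rejects split single clusters)
        cand = _call_fit(values, feats, consensus, 2, allowed_classes)
        if cand is not None:
            fit = cand
            k_try = 2
    if fit is None and k == 2 and 3 in allowed_k and len(allowed_classes) == 3:
        # a stable seeded 3-cluster fit rescues a near-singleton minor
        # homozygote cluster that the k=2 fit would merge into the
        # heterozygotes; without one, stay at the predicted k
        seeded3 = kmeans_1d_seeded(values, consensus.mu)
        if seeded3 is not None:
            seeded3 = map_clusters_to_genotypes(seeded3, consensus)
            if _seeded_fit_is_stable(seeded3, consensus):
                fit = seeded3
                k_try = 3
    while fit is None:
        fit = _call_fit(values, feats, consensus, k_try, allowed_classes)
        if fit is None:
            k_try -= 1
    codes = np.array([fit.genotype_map[c] + 1 for c in fit.assignments], dtype=np.int64)
    conf = confidence_scores(values, fit)
    return codes, conf, k_try, probs


def call_genotypes(
    signal: NormalizedSignal,
    consensus: ConsensusModel,
    predictor: KPredictor,
    snp_ids: list[str],
    sample_ids: list[str],
    snp_indices: np.ndarray | None = None,
    allowed_k: tuple[int, ...] = (1, 2, 3),
    force_fit: bool = False,
) -> GenotypeCalls:
    """Call genotypes for the given SNP rows (autosomal + PAR scope).

    SNPs with fewer than 3 unmasked samples are emitted as all no-call.
    Rows outside ``snp_indices`` are left as NC with k = 0. ``allowed_k``
    restricts the candidate cluster counts; with ``force_fit`` the exact
    fit at the chosen k is used verbatim (e.g. ``allowed_k=(3,),
    force_fit=True`` reproduces an always-3-clusters baseline).
    """
    n_snps, n_samples = signal.M.shape
    rows = np.arange(n_snps) if snp_indices is None else np.asarray(snp_indices)
    codes = np.zeros((n_snps, n_samples), dtype=np.int64)
    conf = np.full((n_snps, n_samples), np.nan)
    pred_k = np.zeros(n_snps, dtype=np.int64)
    probs = np.full((n_snps, 3), np.nan)
    for i in rows:
        vals, cols = signal.snp_values(i)
        if vals.size < 3:
            logger.warning("SNP %s has %d unmasked samples; all no-call", snp_ids[i], vals.size)
            continue
        c, s, k, p = call_single_snp(
            vals, consensus, predictor, allowed_k=allowed_k, force_fit=force_fit
        )
        codes[i, cols] = c
        conf[i, cols] = s
        pred_k[i] = k
        probs[i] = p
    return GenotypeCalls(
        calls=codes, confidence=conf, predicted_k=pred_k,
        k_probabilities=probs, snp_ids=list(snp_ids), sample_ids=list(sample_ids),
    )


def apply_drop_rate(calls: GenotypeCalls, rate: float) -> GenotypeCalls:
    """Mask the lowest-confidence fraction ``rate`` of non-NC calls to NC.

    The threshold is a global confidence quantile over all calls; ties are
    broken deterministically by (SNP, sample) position, so masked sets nest
    as the rate grows.
    """
    if not (0 <= rate < 1):
        raise ParameterError(f"drop rate must be in [0, 1), got {rate}")
    new = GenotypeCalls(
        calls=calls.calls.copy(),
        confidence=calls.confidence,
        predicted_k=calls.predicted_k,
        k_probabilities=calls.k_probabilities,
        snp_ids=calls.snp_ids,
        sample_ids=calls.sample_ids,
    )
    if rate == 0:
        return new
    ii, jj = np.nonzero(calls.calls)
    if ii.size == 0:
        return new
    c = calls.confidence[ii, jj]
    m = int(round(rate * ii.size))
    if m == 0:
        return new
    order = np.lexsort((jj, ii, c))
    drop = order[:m]
    new.calls[ii[drop], jj[drop]] = 0
    return new


def concordance_curve(
    calls: GenotypeCalls,
    truth: np.ndarray,
    rates,
    maf: np.ndarray | None = None,
    maf_bins=(0.0, 0.01, 0.05, 0.5),
):
    """Accuracy vs drop rate, overall and stratified by MAF and allele class.

    ``truth`` is a SNP x sample matrix in {0 (missing), 1, 2, 3}. A call
    "involves the minor allele" when the true genotype is the heterozygote
    or the minor homozygote. Returns a pandas DataFrame with columns
    (rate, stratum, n_compared, accuracy); undefined accuracies are NaN.
    """
    import pandas as pd

    truth = np.asarray(truth, dtype=np.int64)
    if truth.shape != calls.calls.shape:
        raise ParameterError("truth matrix shape does not match calls")

    n1 = (truth == 1).sum(axis=1)
    n2 = (truth == 2).sum(axis=1)
    n3 = (truth == 3).sum(axis=1)
    tot = np.maximum(n1 + n2 + n3, 1)
    p_a = (2 * n1 + n2) / (2.0 * tot)
    if maf is None:
        maf = np.minimum(p_a, 1.0 - p_a)
    minor_hom = np.where(p_a >= 0.5, 3, 1)  # homozygote of the rarer allele

    minor_cell = (truth == 2) | (truth == minor_hom[:, None])
    rows = []
    for rate in rates:
        masked = apply_drop_rate(calls, float(rate))
        comparable = (masked.calls > 0) & (truth > 0)
        match = masked.calls == truth

        def _acc(sel):
            n = int(np.count_nonzero(sel))
            return n, (float(match[sel].mean()) if n else np.nan)

        n, acc = _acc(comparable)
        rows.append({"rate": rate, "stratum": "overall", "n_compared": n, "accuracy": acc})
        for lo, hi in zip(maf_bins[:-1], maf_bins[1:]):
            sel = comparable & ((maf >= lo) & (maf < hi))[:, None]
            n, acc = _acc(sel)
            rows.append({
                "rate": rate, "stratum": f"maf[{lo:g},{hi:g})",
                "n_compared": n, "accuracy": acc,
            })
        for name, sel in (("major", comparable & ~minor_cell),
                          ("minor", comparable & minor_cell)):
            n, acc = _acc(sel)
            rows.append({"rate": rate, "stratum": name, "n_compared": n, "accuracy": acc})
    return pd.DataFrame(rows)


def save_predictor(predictor: KPredictor, path: str) -> None:
    """Serialize a predictor to a self-describing versioned text file."""
    with open(path, "w") as fh:
        fh.write(_PREDICTOR_MAGIC + "\n")
        fh.write(f"family\t{predictor.family}\n")
        fh.write("features\t" + ",".join(predictor.feature_names) + "\n")
        fh.write("classes\t" + ",".join(str(int(c)) for c in predictor.classes) + "\n")
        for key, arr in (
            ("mean", predictor.feature_means),
            ("sd", predictor.feature_sds),
            ("intercept", np.atleast_1d(predictor.intercept).ravel()),
        ):
            fh.write(key + "\t" + ",".join(repr(float(v)) for v in arr) + "\n")
        coef = np.atleast_2d(predictor.coef)
        for row in coef:
            fh.write("coef\t" + ",".join(repr(float(v)) for v in row) + "\n")
        for key, val in sorted(predictor.training_meta.items()):
            fh.write(f"meta:{key}\t{val}\n")


def load_predictor(path: str) -> KPredictor:
    """Read a predictor file written by :func:`save_predictor`."""
    from .errors import FormatError

    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    if not lines or lines[0] != _PREDICTOR_MAGIC:
        raise FormatError(f"{path!r} is not a v1 predictor file")
    fields: dict[str, str] = {}
    coef_rows = []
    meta: dict[str, str] = {}
    for ln in lines[1:]:
        if not ln.strip():
            continue
        key, _, val = ln.partition("\t")
        if key == "coef":
            coef_rows.append([float(v) for v in val.split(",")])
        elif key.startswith("meta:"):
            meta[key[5:]] = val
        else:
            fields[key] = val
    try:
        family = fields["family"]
        names = tuple(fields["features"].split(","))
        classes = np.array([int(c) for c in fields["classes"].split(",")])
        means = np.array([float(v) for v in fields["mean"].split(",")])
        sds = np.array([float(v) for v in fields["sd"].split(",")])
        intercept = np.array([float(v) for v in fields["intercept"].split(",")])
    except KeyError as exc:
        raise FormatError(f"predictor file {path!r} lacks field {exc}") from exc
    coef = np.asarray(coef_rows, dtype=float)
    if family == "ordered_logistic":
        coef = coef.ravel()
    return KPredictor(
        family=family, classes=classes, coef=coef, intercept=intercept,
        feature_means=means, feature_sds=sds, feature_names=names,
        training_meta=meta,
    )
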