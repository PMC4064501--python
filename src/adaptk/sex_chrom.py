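"""Sex imputation from chromosome-Y signal and sex-restricted X/Y calling.

Females carry no Y chromosome, so their chrY probes show background-level
average signal (S); 2-means on the per-sample median chrY S separates the
sexes (low cluster = female). X and Y SNPs outside the pseudo-autosomal
region are then called per sex group with a restricted set of allowed
cluster counts; hemizygous male clusters are mapped onto the nearest
consensus homozygote class, so males are never called AB there.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from .cluster_core import ConsensusModel, kmeans_1d
from .errors import DataError, ParameterError
from .k_model import GenotypeCalls, KPredictor, call_single_snp
from .preprocess import NormalizedSignal

logger = logging.getLogger(__name__)

FEMALE, MALE = "F", "M"


@dataclass
class SampleSex:
    """Per-sample sex labels with provenance and imputation margins."""

    labels: np.ndarray  # array of "F"/"M"
    source: str  # "provided" or "imputed"
    margins: np.ndarray  # |median S - nearer cluster median| per sample

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=object)
        self.margins = np.asarray(self.margins, dtype=float)
        if not np.all(np.isin(self.labels, (FEMALE, MALE))):
            raise ParameterError("sex labels must be 'F' or 'M'")
        if np.any(self.margins < 0):
            raise ParameterError("imputation margins must be >= 0")


def _chromosome_rows(annotations, chromosome: str) -> np.ndarray:
    return np.array(
        [i for i, a in enumerate(annotations) if a.chromosome == chromosome],
        dtype=np.int64,
    )


def impute_gender(signal: NormalizedSignal, annotations) -> SampleSex:
    """Impute sample sex by 2-means on per-sample median chrY average signal."""
    y_rows = _chromosome_rows(annotations, "Y")
    if y_rows.size == 0:
        raise DataError(
            "no chromosome-Y SNPs available; provide explicit sex labels instead"
        )
    n_samples = signal.S.shape[1]
    if n_samples < 2:
        raise DataError("sex imputation requires at least 2 samples")
    S = np.where(signal.mask[y_rows], np.nan, signal.S[y_rows])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        medians = np.nanmedian(S, axis=0)
    if np.any(np.isnan(medians)):
        j = int(np.flatnonzero(np.isnan(medians))[0])
        raise DataError(f"sample column {j} has no unmasked chrY values")

    fit = kmeans_1d(medians, 2)
    if fit.degenerate:
        warnings.warn("chrY signal identical across samples; assigning all female")
        return SampleSex(
            labels=np.array([FEMALE] * n_samples, dtype=object),
            source="imputed",
            margins=np.zeros(n_samples),
        )
    high, low = fit.centers  # decreasing order: high = male cluster
    sizes = fit.cluster_sizes()
    pooled_var = fit.within_ss / max(medians.size - 2, 1)
    if (high - low) < 2.0 * np.sqrt(max(pooled_var, 0.0)):
        warnings.warn(
            "chrY cluster separation is below 2 pooled within-cluster sds; "
            "imputed sexes are low-confidence"
        )
    labels = np.where(fit.assignments == 0, MALE, FEMALE).astype(object)
    margins = np.abs(medians - fit.centers[fit.assignments])
    logger.info(
        "imputed sex: %d male, %d female (separation %.3f)",
        int(sizes[0]), int(sizes[1]), high - low,
    )
    return SampleSex(labels=labels, source="imputed", margins=margins)


def read_sex_file(path: str, sample_ids: list[str]) -> SampleSex:
    """Read a two-column (sample_id, F/M) file; must cover every sample."""
    provided: dict[str, str] = {}
    with open(path) as fh:
        for ln in fh:
            parts = ln.split()
            if not parts or parts[0].lower() == "sample_id":
                continue
            if len(parts) < 2:
                raise DataError(f"malformed sex-file line: {ln.rstrip()!r}")
            provided[parts[0]] = parts[1].upper()
    missing = [s for s in sample_ids if s not in provided]
    if missing:
        raise DataError(f"sex file lacks labels for samples: {', '.join(missing[:10])}")
    labels = np.array([provided[s] for s in sample_ids], dtype=object)
    return SampleSex(labels=labels, source="provided", margins=np.zeros(len(sample_ids)))


def call_sex_chromosomes(
    signal: NormalizedSignal,
    annotations,
    sex: SampleSex,
    consensus: ConsensusModel,
    predictor: KPredictor,
    sample_ids: list[str] | None = None,
) -> GenotypeCalls:
    """Call non-PAR X and Y SNPs with sex-restricted cluster counts.

    chrY: females are no-call; males allow k in {1, 2}. chrX: females allow
    k in {1, 2, 3}; males allow k in {1, 2}. Hemizygous male clusters map to
    the homozygote classes only. Sex groups with fewer than 3 samples are
    no-call. Rows on other chromosomes are left NC with k = 0.
    """
    n_snps, n_samples = signal.M.shape
    codes = np.zeros((n_snps, n_samples), dtype=np.int64)
    conf = np.full((n_snps, n_samples), np.nan)
    pred_k = np.zeros(n_snps, dtype=np.int64)
    probs = np.full((n_snps, 3), np.nan)

    male_cols = np.flatnonzero(sex.labels == MALE)
    female_cols = np.flatnonzero(sex.labels == FEMALE)

    def _call_group(i: int, cols: np.ndarray, allowed_k, allowed_classes) -> None:
        keep = cols[~signal.mask[i, cols]]
        vals = signal.M[i, keep]
        if vals.size < 3:
            logger.warning(
                "SNP %s: sex group with %d samples; no-call", annotations[i].snp_id, vals.size
            )
            return
        c, s, k, p = call_single_snp(
            vals, consensus, predictor,
            allowed_k=allowed_k, allowed_classes=allowed_classes,
        )
        codes[i, keep] = c
        conf[i, keep] = s
        # report the k used for the larger group deterministically: keep max
        if k > pred_k[i]:
            pred_k[i] = k
            probs[i] = p

    for i in _chromosome_rows(annotations, "Y"):
        _call_group(i, male_cols, allowed_k=(1, 2), allowed_classes=(0, 2))
    for i in _chromosome_rows(annotations, "X"):
        _call_group(i, female_cols, allowed_k=(1, 2, 3), allowed_classes=(0, 1, 2))
        _call_group(i, male_cols, allowed_k=(1, 2), allowed_classes=(0, 2))

    if sample_ids is None:
        sample_ids = [str(j) for j in range(n_samples)]
    return GenotypeCalls(
        calls=codes, confidence=conf, predicted_k=pred_k, k_probabilities=probs,
        snp_ids=[a.snp_id for a in annotations], sample_ids=list(sample_ids),
    )
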