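"""Synthetic two-channel intensity data with known genotypes and cluster counts.

Genotype clusters are generated on the log-ratio (M) scale under
Hardy-Weinberg proportions, with per-SNP center jitter, optional skew of a
homozygote cluster toward the heterozygote, intensity-dependent curvature
of M versus average signal S, and per-array multiplicative scale factors.
M/S are inverted to raw channels via X = 2^(S + M/2), Y = 2^(S - M/2) — the
exact identities the preprocessing module uses — so the simulator and the
transform are mutually consistent oracles.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .errors import ParameterError
from .io import IntensityDataset, SNPAnnotation


@dataclass
class SimConfig:
    """Knobs of the intensity simulator; every default is overridable."""

    n_snps: int = 100
    n_samples: int = 100
    maf_spectrum: tuple = ("uniform", 0.005, 0.5)  # or ("fixed", [m1, m2, ...])
    center_base: tuple = (2.0, 0.0, -2.0)
    center_jitter_sd: float = 0.1
    skew_fraction: float = 0.1
    skew_magnitude: float = 0.5
    within_cluster_sd: float = 0.3
    array_scale_sd: float = 0.0
    curvature_coeff: float = 0.0
    mean_S: float = 10.0
    S_sd: float = 0.5
    sex_mix: float = 0.5
    y_signal_shift: float = 2.0  # S shift of male over female chrY background
    seed: int = 0

    def validate(self) -> None:
        if self.n_snps < 1 or self.n_samples < 1:
            raise ParameterError("n_snps and n_samples must be >= 1")
        for name in ("center_jitter_sd", "skew_fraction", "skew_magnitude",
                     "within_cluster_sd", "array_scale_sd", "S_sd"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be >= 0")
        kind = self.maf_spectrum[0]
        if kind == "uniform":
            lo, hi = self.maf_spectrum[1], self.maf_spectrum[2]
            if not (0 < lo <= hi <= 0.5):
                raise ParameterError("uniform MAF bounds must satisfy 0 < lo <= hi <= 0.5")
        elif kind == "fixed":
            vals = np.asarray(self.maf_spectrum[1], dtype=float)
            if vals.size == 0 or np.any(vals <= 0) or np.any(vals > 0.5):
                raise ParameterError("fixed MAF values must be in (0, 0.5]")
        else:
            raise ParameterError(f"unknown maf_spectrum kind {kind!r}")
        b = self.center_base
        if not (b[0] > b[1] > b[2]):
            raise ParameterError("center_base must be strictly decreasing (AA > AB > BB)")


@dataclass
class SimTruth:
    """Ground truth of a simulated dataset.

    genotypes uses codes {1: AA, 2: AB, 3: BB}; 0 marks cells with no true
    genotype (female chrY). true_k counts the distinct genotype codes
    realized at each SNP.
    """

    genotypes: np.ndarray
    true_k: np.ndarray
    maf: np.ndarray
    sex: np.ndarray | None = None


def _draw_mafs(config: SimConfig, rng: np.random.Generator) -> np.ndarray:
    kind = config.maf_spectrum[0]
    if kind == "uniform":
        lo, hi = config.maf_spectrum[1], config.maf_spectrum[2]
        return rng.uniform(lo, hi, size=config.n_snps)
    vals = np.asarray(config.maf_spectrum[1], dtype=float)
    return vals[rng.integers(0, vals.size, size=config.n_snps)]


def _snp_centers(config: SimConfig, rng: np.random.Generator) -> np.ndarray:
    centers = np.asarray(config.center_base, dtype=float) + rng.normal(
        0.0, config.center_jitter_sd, size=3
    )
    if rng.random() < config.skew_fraction:
        side = int(rng.choice([0, 2]))  # shift one homozygote toward AB
        shift = config.skew_magnitude if side == 0 else -config.skew_magnitude
        centers[side] -= shift
    return centers


def _emit_channels(M: np.ndarray, S: np.ndarray, scale: np.ndarray):
    X = np.exp2(S + M / 2.0) * scale[None, :]
    Y = np.exp2(S - M / 2.0) * scale[None, :]
    return X, Y


def _realized_maf(genotypes_row: np.ndarray) -> float:
    called = genotypes_row[genotypes_row > 0]
    if called.size == 0:
        return 0.0
    n1 = int(np.sum(called == 1))
    n2 = int(np.sum(called == 2))
    p = (2 * n1 + n2) / (2.0 * called.size)
    return float(min(p, 1.0 - p))


def simulate_dataset(config: SimConfig) -> tuple[IntensityDataset, SimTruth]:
    """Simulate autosomal SNP intensities with known genotypes and k."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n, m = config.n_snps, config.n_samples
    mafs = _draw_mafs(config, rng)
    genotypes = np.empty((n, m), dtype=np.int64)
    M = np.empty((n, m))
    S = rng.normal(config.mean_S, config.S_sd, size=(n, m))
    for i in range(n):
        q = mafs[i]
        probs = np.array([(1 - q) ** 2, 2 * q * (1 - q), q * q])
        g = rng.choice([1, 2, 3], size=m, p=probs)
        centers = _snp_centers(config, rng)
        M[i] = centers[g - 1] + rng.normal(0.0, config.within_cluster_sd, size=m)
        genotypes[i] = g
    M += config.curvature_coeff * (S - config.mean_S) ** 2
    scale = np.exp(rng.normal(0.0, config.array_scale_sd, size=m))
    X, Y = _emit_channels(M, S, scale)

    snps = [
        SNPAnnotation(snp_id=f"snp{i:06d}", chromosome="1", position=i)
        for i in range(n)
    ]
    samples = [f"sample{j:04d}" for j in range(m)]
    dataset = IntensityDataset(X=X, Y=Y, snps=snps, samples=samples)
    true_k = np.array([np.unique(genotypes[i]).size for i in range(n)], dtype=np.int64)
    realized = np.array([_realized_maf(genotypes[i]) for i in range(n)])
    return dataset, SimTruth(genotypes=genotypes, true_k=true_k, maf=realized)


def simulate_sex_dataset(config: SimConfig) -> tuple[IntensityDataset, SimTruth]:
    """Simulate chrX and chrY SNPs with hemizygous male signal.

    Half the SNPs are placed on X, half on Y. Males draw a single allele at
    each SNP (homozygote-like clusters only); female chrY probes show only
    background: S shifted down by ``y_signal_shift`` and M noise around 0.
    """
    config.validate()
    if not (0 < config.sex_mix < 1):
        raise ParameterError("sex_mix must be in (0, 1)")
    rng = np.random.default_rng(config.seed)
    n, m = config.n_snps, config.n_samples
    n_male = int(round(config.sex_mix * m))
    n_male = min(max(n_male, 1), m - 1)
    sex = np.array(["M"] * n_male + ["F"] * (m - n_male), dtype=object)
    rng.shuffle(sex)
    is_male = sex == "M"

    n_x = n // 2
    mafs = _draw_mafs(config, rng)
    genotypes = np.zeros((n, m), dtype=np.int64)
    M = np.empty((n, m))
    S = rng.normal(config.mean_S, config.S_sd, size=(n, m))
    chroms = []
    for i in range(n):
        q = mafs[i]
        centers = _snp_centers(config, rng)
        hemi = np.where(rng.random(m) < 1 - q, 1, 3)  # single allele draw
        noise = rng.normal(0.0, config.within_cluster_sd, size=m)
        if i < n_x:
            chroms.append("X")
            probs = np.array([(1 - q) ** 2, 2 * q * (1 - q), q * q])
            g = rng.choice([1, 2, 3], size=m, p=probs)
            g[is_male] = hemi[is_male]
            genotypes[i] = g
            M[i] = centers[g - 1] + noise
        else:
            chroms.append("Y")
            g = np.where(is_male, hemi, 0)
            genotypes[i] = g
            M[i] = np.where(is_male, centers[np.maximum(g, 1) - 1], 0.0) + noise
            S[i, ~is_male] -= config.y_signal_shift  # background only
    M += config.curvature_coeff * (S - config.mean_S) ** 2
    scale = np.exp(rng.normal(0.0, config.array_scale_sd, size=m))
    X, Y = _emit_channels(M, S, scale)

    snps = [
        SNPAnnotation(snp_id=f"snp{i:06d}", chromosome=chroms[i], position=i)
        for i in range(n)
    ]
    samples = [f"sample{j:04d}" for j in range(m)]
    dataset = IntensityDataset(X=X, Y=Y, snps=snps, samples=samples)
    true_k = np.array(
        [np.unique(genotypes[i][genotypes[i] > 0]).size for i in range(n)],
        dtype=np.int64,
    )
    realized = np.array([_realized_maf(genotypes[i]) for i in range(n)])
    return dataset, SimTruth(genotypes=genotypes, true_k=true_k, maf=realized, sex=sex)


def config_to_dict(config: SimConfig) -> dict:
    return asdict(config)
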