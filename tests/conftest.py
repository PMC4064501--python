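import numpy as np
import pytest

from adaptk import (
    ConsensusModel,
    SimConfig,
    compute_features,
    estimate_consensus,
    normalize_dataset,
    simulate_dataset,
    train_k_predictor,
)


@pytest.fixture
def consensus():
    """A clean consensus model at the canonical class centers."""
    return ConsensusModel(mu=np.array([2.0, 0.0, -2.0]), V=np.eye(3) * 0.01)


@pytest.fixture(scope="session")
def trained_bundle():
    """A modest end-to-end pipeline shared by unit tests.

    600 SNPs x 120 samples, uniform MAF, default separation; returns the
    dataset, truth, normalized signal, consensus, feature matrix and a
    predictor trained on the first half.
    """
    from adaptk import IntensityDataset
    from adaptk.io import SNPAnnotation
    from adaptk.simulate import SimTruth

    config = SimConfig(
        n_snps=480, n_samples=120, maf_spectrum=("uniform", 0.01, 0.5),
        array_scale_sd=0.2, seed=7,
    )
    dataset, truth = simulate_dataset(config)
    low = SimConfig(
        n_snps=120, n_samples=120, maf_spectrum=("fixed", [0.005, 0.02]),
        array_scale_sd=0.2, seed=8,
    )
    d2, t2 = simulate_dataset(low)
    # interleave very-low-MAF SNPs so all three k classes are trainable
    snps = dataset.snps + [
        SNPAnnotation(snp_id="lo_" + a.snp_id, chromosome=a.chromosome,
                      position=a.position + 10**6)
        for a in d2.snps
    ]
    dataset = IntensityDataset(
        X=np.vstack([dataset.X, d2.X]), Y=np.vstack([dataset.Y, d2.Y]),
        snps=snps, samples=dataset.samples,
    )
    truth = SimTruth(
        genotypes=np.vstack([truth.genotypes, t2.genotypes]),
        true_k=np.concatenate([truth.true_k, t2.true_k]),
        maf=np.concatenate([truth.maf, t2.maf]),
    )
    config = SimConfig(n_snps=600, n_samples=120, seed=7)
    signal = normalize_dataset(dataset)
    cons = estimate_consensus(signal.M, mask=signal.mask, seed=7)
    features = np.array([
        compute_features(signal.M[i][~signal.mask[i]], cons).as_vector()
        for i in range(config.n_snps)
    ])
    train_idx = np.arange(0, 600, 2)  # covers both MAF blocks
    predictor = train_k_predictor(features[train_idx], truth.true_k[train_idx], seed=7)
    return {
        "config": config, "dataset": dataset, "truth": truth, "signal": signal,
        "consensus": cons, "features": features, "predictor": predictor,
    }
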