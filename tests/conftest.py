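import numpy as np
import pandas as pd
import pytest

from hntgwas.config import PipelineConfig
from hntgwas.containers import GenotypeMatrix
from hntgwas.simulate import SimConfig, generate_genotypes


@pytest.fixture
def cfg() -> PipelineConfig:
    return PipelineConfig()


@pytest.fixture
def small_geno() -> GenotypeMatrix:
    """Deterministic 40-sample, 60-marker structured panel."""
    return generate_genotypes(SimConfig(n_samples=40, n_markers=60,
                                        n_chromosomes=2, n_subpops=2,
                                        fst_like_divergence=0.1, seed=7))


@pytest.fixture
def tiny_geno() -> GenotypeMatrix:
    """Hand-written 5 x 8 dosage matrix for direct-formula oracles."""
    rng = np.random.default_rng(11)
    dos = rng.integers(0, 3, size=(5, 8)).astype(float)
    # orient to minor allele
    freq = dos.mean(axis=0) / 2
    dos[:, freq > 0.5] = 2 - dos[:, freq > 0.5]
    markers = pd.DataFrame({
        "snp_id": [f"m{j}" for j in range(8)],
        "chrom": 1,
        "pos": np.arange(1, 9) * 1000,
        "major": "A", "minor": "G",
    })
    return GenotypeMatrix(samples=[f"s{i}" for i in range(5)],
                          dosages=dos, markers=markers)
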