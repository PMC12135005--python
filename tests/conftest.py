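import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import mshage

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_dataset(matrix, positions, seq_length_bp, ploidy=2, chrom="22"):
    return mshage.HaplotypeDataset(
        haplotypes=np.asarray(matrix, dtype=np.uint8),
        positions=np.asarray(positions, dtype=np.int64),
        seq_length_bp=seq_length_bp,
        chrom=chrom,
        ploidy=ploidy,
    )


def random_segregating_dataset(rng, n_hap=20, n_sites=50, seq_length_bp=60_000):
    """A random phased matrix in which every site segregates."""
    H = (rng.random((n_hap, n_sites)) < rng.uniform(0.1, 0.6, size=n_sites)).astype(
        np.uint8
    )
    for j in range(n_sites):
        k = H[:, j].sum()
        if k == 0:
            H[rng.integers(n_hap), j] = 1
        elif k == n_hap:
            H[rng.integers(n_hap), j] = 0
    positions = np.sort(
        rng.choice(np.arange(10, seq_length_bp - 10), size=n_sites, replace=False)
    )
    return make_dataset(H, positions, seq_length_bp)


@pytest.fixture(scope="session")
def small_sim():
    """Simple-model simulation shared by read-only tests (n=100, 1 Mb)."""
    config = mshage.ModelConfig(
        model_id="simple",
        n_genomes=100,
        seq_length_bp=1_000_000,
        mu=1e-8,
        ne=10_000,
        flat_recomb_rate=1e-8,
        seed=42,
    )
    return mshage.exclude_recurrent_sites(mshage.simulate(config))


@pytest.fixture
def flat_config():
    return mshage.EstimatorConfig(mu=1e-8, flat_recomb_rate=1e-8, seed=0)
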