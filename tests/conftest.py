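import numpy as np
import pytest

from metanorm import CountMatrix, SyntheticConfig, filter_genes, generate_counts


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def small_cm(rng):
    """Random 50×6 integer matrix with moderate sparsity."""
    counts = rng.poisson(8.0, size=(50, 6))
    counts[rng.random(counts.shape) < 0.2] = 0
    return CountMatrix(
        counts,
        [f"g{i}" for i in range(50)],
        [f"s{j}" for j in range(6)],
    )


@pytest.fixture(scope="session")
def synthetic_cm():
    """Filtered synthetic matrix shared by the heavier tests."""
    cfg = SyntheticConfig(n_genes=2000, n_samples=60, seed=42)
    return filter_genes(generate_counts(cfg))


def random_count_matrix(rng, m=50, n=6, lam=8.0, zero_frac=0.2):
    counts = rng.poisson(lam, size=(m, n))
    counts[rng.random(counts.shape) < zero_frac] = 0
    return CountMatrix(
        counts, [f"g{i}" for i in range(m)], [f"s{j}" for j in range(n)]
    )
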