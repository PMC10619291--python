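import numpy as np
import pytest

from clustrat.io_genotype import GenotypeMatrix, NormalizedGenotypes


def make_genotypes(rng: np.random.Generator, m: int, n: int,
                   missing_rate: float = 0.0) -> GenotypeMatrix:
    """Random dosage matrix with frequency-spread columns (helper, not a fixture)."""
    freqs = rng.uniform(0.1, 0.9, size=n)
    dos = rng.binomial(2, freqs, size=(m, n)).astype(np.int8)
    if missing_rate > 0:
        mask = rng.random((m, n)) < missing_rate
        dos[mask] = -1
    samples = [f"s{i}" for i in range(m)]
    variants = [("1", f"v{j}", j + 1, "A", "G") for j in range(n)]
    return GenotypeMatrix(dos, samples, variants)


def normalized_random(rng: np.random.Generator, m: int, n: int) -> NormalizedGenotypes:
    """Continuous matrix standardized to the NormalizedGenotypes contract."""
    X = rng.standard_normal((m, n))
    X = (X - X.mean(axis=0)) / X.std(axis=0)
    return NormalizedGenotypes(X, np.arange(n))


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def small_genotypes(rng):
    return make_genotypes(rng, 12, 8)
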