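import numpy as np
import pytest

from salmhc import simulate


@pytest.fixture(scope="session")
def uba_library():
    return simulate.gen_allele_library("UBA", 8, lineage_count=4, seed=1)


@pytest.fixture(scope="session")
def dab_library():
    return simulate.gen_allele_library("DAB", 10, seed=2)


@pytest.fixture(scope="session")
def primer_pools():
    return simulate.default_primer_pools()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_spectrum(rng, n_alleles=None, max_count=40):
    """A random allele-copy spectrum with an even total (diploid data)."""
    from salmhc.popgen import FrequencySpectrum

    k = n_alleles or rng.integers(2, 12)
    counts = rng.integers(1, max_count, size=k)
    if counts.sum() % 2:
        counts[0] += 1
    labels = [f"A{i:02d}" for i in range(k)]
    return FrequencySpectrum("UBA", "pop", labels, counts)
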