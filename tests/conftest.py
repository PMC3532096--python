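import numpy as np
import pandas as pd
import pytest

from bdsmap.io import GenotypeDataset


def make_dataset(n, m, seed, freq_range=(0.1, 0.9), birth_span=(1950, 2000)):
    """Unstructured neutral genotype dataset with random birth dates."""
    rng = np.random.default_rng(seed)
    p = rng.uniform(*freq_range, m)
    calls = rng.binomial(2, p, size=(n, m)).astype(np.int8)
    mono = calls.std(axis=0) == 0
    calls[0, mono] = 1
    loci = pd.DataFrame({"snp": [f"s{j:04d}" for j in range(m)],
                         "chrom": "1", "pos": np.arange(1, m + 1) * 100})
    birth = rng.uniform(*birth_span, n)
    return GenotypeDataset([f"A{i:04d}" for i in range(n)], birth, loci, calls)


@pytest.fixture
def small_dataset():
    return make_dataset(50, 40, seed=7)


@pytest.fixture
def oracle_dataset():
    """n=50, m=200 complete dataset used by the dense-solver equivalences."""
    return make_dataset(50, 200, seed=11)
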