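import numpy as np
import pandas as pd
import pytest

from farmscan import GenotypeDataset, Phenotype, generate_fixture_genotypes


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_genotypes(rng, n, m, chromosomes=2):
    """Unstructured random dosages with a valid sorted map."""
    dosages = rng.integers(0, 3, size=(n, m)).astype(float)
    per = np.full(chromosomes, m // chromosomes)
    per[: m % chromosomes] += 1
    records = []
    k = 0
    for c, mc in enumerate(per):
        pos = np.sort(rng.choice(10_000_000, size=int(mc), replace=False)) + 1
        for p in pos:
            records.append((f"snp{k}", f"chr{c + 1}", int(p)))
            k += 1
    markers = pd.DataFrame(records, columns=["marker_id", "chrom", "pos"])
    return GenotypeDataset(dosages, [f"s{i}" for i in range(n)], markers)


@pytest.fixture
def small_genotypes(rng):
    return random_genotypes(rng, 20, 50)


@pytest.fixture
def ld_genotypes():
    return generate_fixture_genotypes(120, 400, chromosomes=4, seed=7)


@pytest.fixture
def gaussian_phenotype(rng, small_genotypes):
    return Phenotype(
        list(small_genotypes.sample_ids),
        rng.standard_normal(small_genotypes.n_samples),
    )
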