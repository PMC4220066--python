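import numpy as np
import pytest

import crosspred as cp


@pytest.fixture(scope="session")
def small_config():
    return cp.SimulationConfig(
        population_sizes=(30, 32, 28, 40, 50),
        population_names=("A", "B", "C", "D", "E"),
        n_snps=400,
        n_qtl=60,
        fst=(0.10, 0.04, 0.04, 0.04, 0.04),
        n_generations=2,
        seed=7,
        missing_rate=0.02,
    )


@pytest.fixture(scope="session")
def small_study(small_config):
    """A 180-animal, 400-SNP five-population study shared across test modules."""
    return cp.simulate_study(small_config)


@pytest.fixture(scope="session")
def clean_genotypes(small_study):
    genotypes, _ = cp.apply_qc(small_study.genotypes)
    return genotypes


def random_genotypes(rng, n, p, labels=None, maf_range=(0.1, 0.5)):
    """Unstructured genotype fixture: independent binomial dosages."""
    freqs = rng.uniform(*maf_range, size=p)
    values = rng.binomial(2, freqs, size=(n, p)).astype(float)
    if labels is None:
        labels = ["P"] * n
    return cp.GenotypeMatrix(
        values,
        [f"a{i}" for i in range(n)],
        [f"s{j}" for j in range(p)],
        list(labels),
    )
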