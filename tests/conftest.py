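import numpy as np
import pandas as pd
import pytest

from ventseep.demography import GenotypeMatrix, SampleConfig, published_median_params
from ventseep.coalescent import simulate_dataset


@pytest.fixture(scope="session")
def small_sample_config():
    return SampleConfig(sizes={"JR": 6, "OH": 6, "KK": 6, "OT": 6})


@pytest.fixture(scope="session")
def median_params():
    return published_median_params()


@pytest.fixture(scope="session")
def small_dataset(median_params, small_sample_config):
    """A modest scenario-1 dataset shared by read-only tests."""
    return simulate_dataset(median_params, small_sample_config, 300, rng_seed=42)


def make_matrix(genotypes, groups, scaffolds=None, positions=None):
    """Build a GenotypeMatrix from plain lists (tests' little helper)."""
    genotypes = np.asarray(genotypes, dtype=np.int8)
    n_ind, n_loci = genotypes.shape
    groups = np.asarray(groups)
    loci = pd.DataFrame(
        {
            "scaffold": scaffolds or [f"s{j + 1}" for j in range(n_loci)],
            "pos": positions or list(range(100, 100 + n_loci)),
        }
    )
    individuals = [f"{g}_{i}" for i, g in enumerate(groups)]
    return GenotypeMatrix(genotypes, individuals, groups, loci)
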