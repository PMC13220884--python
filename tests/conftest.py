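import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from phagetrace.catalog import genotype_haplotypes, load_table1_catalog
from phagetrace.simulate import mesocosm_experiment_config, simulate_metacommunity


@pytest.fixture(scope="session")
def table1():
    return load_table1_catalog()


@pytest.fixture(scope="session")
def table1_haplotypes(table1):
    return genotype_haplotypes(table1)


@pytest.fixture(scope="session")
def study_run():
    """One full simulated metacommunity under the default study scenario."""
    config = mesocosm_experiment_config(rng_seed=7)
    dataset, truth = simulate_metacommunity(config)
    return config, dataset, truth


def make_genotypes(haplotype_dict):
    """Helper: build Genotype objects from an {id: 0/1 vector} mapping."""
    from phagetrace.genotypes import Genotype

    return [
        Genotype(id=k, haplotype=np.asarray(v, dtype=int))
        for k, v in haplotype_dict.items()
    ]
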