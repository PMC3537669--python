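import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from aspnet.containers import GenotypeMatrix, Interactome
from aspnet.simulate import SimulationConfig, simulate_dataset

settings.register_profile("suite", derandomize=True, max_examples=50)
settings.load_profile("suite")


def make_genotypes(arr, chroms=None, positions=None, strains=None):
    """GenotypeMatrix from a plain array (markers x strains)."""
    arr = np.asarray(arr, dtype=float)
    m, n = arr.shape
    markers = [f"m{i + 1}" for i in range(m)]
    chroms = chroms or ["chr1"] * m
    if positions is None:
        # restart position counter per chromosome
        positions, counter = [], {}
        for c in chroms:
            counter[c] = counter.get(c, 0) + 1
            positions.append(counter[c] * 1000)
    calls = pd.DataFrame(arr, index=markers,
                         columns=strains or [f"s{j + 1}" for j in range(n)])
    mmap = pd.DataFrame({"chromosome": chroms, "position": positions},
                        index=markers)
    return GenotypeMatrix(calls, mmap)


@pytest.fixture(scope="session")
def small_config():
    return SimulationConfig(
        n_strains=60,
        n_chromosomes=4,
        n_markers_per_chrom=[40] * 4,
        n_genes=200,
        edge_counts_by_type={"PPI": 300, "PDI": 120, "KPI": 120, "EEI": 60},
        n_planted_eqtls=15,
        n_planted_ascp=5,
        n_planted_asdp=5,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    """(genotypes, expression, interactome, phenotypes, target_sets, truth)."""
    return simulate_dataset(small_config, n_compounds=5)


@pytest.fixture()
def triangle_interactome():
    return Interactome([("A", "B", "PPI"), ("B", "C", "PPI"), ("A", "C", "PPI")])
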