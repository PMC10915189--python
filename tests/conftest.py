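import numpy as np
import pandas as pd
import pytest

from singlestep.pedigree import sort_pedigree
from singlestep.simulate import SimConfig, simulate_dataset


def random_pedigree(n, n_founders=30, seed=0):
    """Random valid pedigree: founders then offspring of earlier animals."""
    rng = np.random.default_rng(seed)
    recs = [(i, 0, 0) for i in range(1, n_founders + 1)]
    for i in range(n_founders + 1, n + 1):
        s = int(rng.integers(1, i))
        d = int(rng.integers(1, i))
        while d == s:
            d = int(rng.integers(1, i))
        recs.append((i, s, d))
    return sort_pedigree(recs)


@pytest.fixture(scope="session")
def small_dataset():
    """Shared small simulated dataset (~600 animals, 300 SNPs, mixed QTL)."""
    cfg = SimConfig(n_founders=60, n_generations=3, offspring_per_mating=2,
                    prop_genotyped=0.5, n_chrom=3, snps_per_chrom=100,
                    sigma_a2=50.0, sigma_e2=50.0, n_qtl=10,
                    qtl_variance_share=0.3, seed=11)
    ped, geno, phen, truth = simulate_dataset(cfg)
    return cfg, ped, geno, phen, truth


@pytest.fixture
def trio_pedigree():
    """Two unrelated founders and their offspring."""
    return sort_pedigree([(1, 0, 0), (2, 0, 0), (3, 1, 2)])
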