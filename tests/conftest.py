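import numpy as np
import pytest

from mcalphabet import (
    ChainConfig,
    ClassAllocation,
    GenotypeMatrix,
    PhenotypeTable,
    SimulationConfig,
    simulate_dataset,
)


@pytest.fixture
def small_genotypes() -> GenotypeMatrix:
    """6 individuals x 5 SNPs on two chromosomes, one missing call."""
    dos = np.array(
        [
            [0, 1, 2, 0, 1],
            [1, 2, 0, 1, 1],
            [2, 0, 1, np.nan, 0],
            [0, 1, 1, 2, 2],
            [1, 1, 0, 0, 1],
            [2, 2, 2, 1, 0],
        ],
        dtype=float,
    )
    return GenotypeMatrix(
        dos,
        snp_ids=[f"s{j}" for j in range(5)],
        chromosomes=["1", "1", "1", "2", "2"],
        positions=[100, 200, 300, 100, 250],
        individual_ids=[f"i{k}" for k in range(6)],
    )


@pytest.fixture
def tiny_dataset():
    """Small simulated dataset shared by sampler/evaluation smoke tests."""
    cfg = SimulationConfig(
        n_individuals=120, n_snps=150, n_qtl_enriched=15, n_qtl_genomewide=4,
        heritabilities=(0.5,), seed=11,
    )
    return simulate_dataset(cfg)


@pytest.fixture
def tiny_dataset_mt():
    cfg = SimulationConfig(
        n_individuals=100, n_snps=120, n_qtl_enriched=12, n_qtl_genomewide=3,
        heritabilities=(0.5, 0.9), seed=13,
    )
    return simulate_dataset(cfg)


@pytest.fixture
def short_chain() -> ChainConfig:
    return ChainConfig(chain_length=300, burn_in=100, thin=2, seed=17)
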