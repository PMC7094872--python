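import numpy as np
import pandas as pd
import pytest

from vprotqtl.pedigree import PedigreeTable
from vprotqtl.synthgen import (
    SimConfig,
    simulate_genotypes,
    simulate_latent_traits,
    simulate_twin_cohort,
    trait_scores,
)


@pytest.fixture(scope="session")
def twin_cfg() -> SimConfig:
    return SimConfig(
        seed=11,
        n_individuals=40,
        n_mz_pairs=120,
        n_dz_pairs=120,
        n_snps=80,
        n_chromosomes=2,
        ld_block_size=4,
        ld_rho=0.6,
        ace_fractions=(0.5, 0.2, 0.3),
    )


@pytest.fixture(scope="session")
def twin_cohort(twin_cfg):
    pedigree = simulate_twin_cohort(twin_cfg)
    genotypes = simulate_genotypes(twin_cfg, pedigree)
    params = simulate_latent_traits(genotypes, pedigree, twin_cfg)
    return twin_cfg, pedigree, genotypes, params


@pytest.fixture(scope="session")
def twin_trait(twin_cohort) -> pd.Series:
    cfg, pedigree, _, params = twin_cohort
    return pd.Series(trait_scores(params, cfg.traits[0]), index=pedigree.individuals)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20240901)


def make_pedigree(n_mz: int, n_dz: int, n_unrelated: int = 0) -> PedigreeTable:
    rows = []
    for i in range(n_mz):
        rows += [(f"M{i}a", f"FM{i}", "MZ"), (f"M{i}b", f"FM{i}", "MZ")]
    for i in range(n_dz):
        rows += [(f"D{i}a", f"FD{i}", "DZ"), (f"D{i}b", f"FD{i}", "DZ")]
    for i in range(n_unrelated):
        rows.append((f"U{i}", f"FU{i}", "unrelated"))
    return PedigreeTable(pd.DataFrame(rows, columns=["individual", "family", "zygosity"]))
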