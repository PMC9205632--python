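import numpy as np
import pandas as pd
import pytest

from immunoqtl import SimulationConfig, simulate_cohort, simulate_genotypes


@pytest.fixture(scope="session")
def small_config():
    return SimulationConfig(
        n_samples_per_cohort=(120, 120),
        n_snps=200,
        ld_block_size=10,
        ld_rho=0.6,
        n_cell_traits=20,
        n_cytokine_traits=8,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_genotypes(small_config):
    return simulate_genotypes(small_config)


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return simulate_cohort(small_config)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def make_records(snps, traits, pvals, chrom="1", pos0=10_000):
    """Assemble a minimal association-record frame for locus/enrichment tests."""
    rows = []
    for i, s in enumerate(snps):
        for t in traits:
            rows.append(
                {
                    "snp": s,
                    "chrom": chrom,
                    "pos": pos0 + i * 1000,
                    "effect_allele": "G",
                    "other_allele": "A",
                    "trait": t,
                    "beta": 0.0,
                    "se": 1.0,
                    "t": 0.0,
                    "p": pvals[(s, t)] if isinstance(pvals, dict) else pvals,
                    "n": 100,
                    "note": "",
                }
            )
    return pd.DataFrame(rows)
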