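import pytest

from cellhap import (
    SimulationConfig,
    merge_tables,
    observe_single_cell,
    simulate_family,
)


@pytest.fixture(scope="session")
def clean_config():
    """Noise-free study conditions: no dropout, no genotype errors, deep cell."""
    return SimulationConfig(
        n_snps=300,
        mean_depth=60,
        ado_rate=0.0,
        fp_rate=0.0,
        crossover_prob=0.0,
        seed=42,
    )


@pytest.fixture(scope="session")
def clean_truth(clean_config):
    return simulate_family(clean_config)


@pytest.fixture(scope="session")
def clean_family(clean_truth):
    """Multi-sample table (FATHER/MOTHER/PROBAND/REFERENCE/CELL), noise-free."""
    return merge_tables(
        clean_truth.to_genotype_table(include_reference=True),
        observe_single_cell(clean_truth),
    )


@pytest.fixture(scope="session")
def noisy_config():
    """WGA-artifact conditions near the empirically reported regime."""
    return SimulationConfig(
        n_snps=400, mean_depth=40, ado_rate=0.15, fp_rate=0.05, seed=11
    )


@pytest.fixture(scope="session")
def noisy_truth(noisy_config):
    return simulate_family(noisy_config)


@pytest.fixture(scope="session")
def noisy_family(noisy_truth):
    return merge_tables(
        noisy_truth.to_genotype_table(include_reference=True),
        observe_single_cell(noisy_truth),
    )
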