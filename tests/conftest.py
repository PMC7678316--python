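import pytest

from crosscell.generate import GeneratorConfig, generate_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """A desk-toy dataset shared by unit tests (300 loci, 6 cell types)."""
    return generate_dataset(
        GeneratorConfig(n_loci=300, n_chromosomes=3, n_cell_types=6, seed=7)
    )


@pytest.fixture(scope="session")
def flat_dataset():
    """No cell-type variation: labels identical across every column."""
    return generate_dataset(
        GeneratorConfig(
            n_loci=300, n_chromosomes=3, n_cell_types=6,
            sigma_cell=0.0, sigma_lineage=0.0, seed=7,
        )
    )
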