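import numpy as np
import pytest

from clamtc.simulate import (SimulationConfig, simulate_cohort, simulate_species_pair,
                             simulate_tumour_lineage)


@pytest.fixture(scope="session")
def small_config():
    """Scaled-down study: short mitogenome and loci, modest coverage."""
    return SimulationConfig(seed=11, mito_length=4000,
                            nuclear_locus_lengths=(1200, 900),
                            coverage_mito=40, coverage_nuclear=40).validate()


@pytest.fixture(scope="session")
def species_pair(small_config):
    return simulate_species_pair(small_config)


@pytest.fixture(scope="session")
def tumour_lineage(small_config, species_pair):
    return simulate_tumour_lineage(species_pair, small_config)


@pytest.fixture(scope="session")
def host_cohort(small_config, species_pair):
    return simulate_cohort(species_pair, "host", 6, small_config)


@pytest.fixture(scope="session")
def donor_cohort(small_config, species_pair):
    return simulate_cohort(species_pair, "donor", 5, small_config)
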