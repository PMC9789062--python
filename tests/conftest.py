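import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from polycross.synthetic_data import (
    SimulationConfig,
    simulate_allele_counts,
    simulate_isoform_quants,
    simulate_triads,
)

settings.register_profile(
    "ci", derandomize=True, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def study_config() -> SimulationConfig:
    """The default study conditions the generators emulate."""
    return SimulationConfig(seed=20220923)


@pytest.fixture(scope="session")
def triad_dataset(study_config):
    return simulate_triads(study_config)


@pytest.fixture(scope="session")
def allele_dataset(study_config):
    return simulate_allele_counts(study_config)


@pytest.fixture(scope="session")
def isoform_dataset(study_config):
    return simulate_isoform_quants(study_config)


@pytest.fixture(scope="session")
def psi_groups(isoform_dataset):
    """Long PSI tables for the two simulated groups."""
    from polycross.splicing_psi import psi_per_isoform

    group1, group2, _, truth = isoform_dataset
    p1 = pd.concat([psi_per_isoform(t) for t in group1], ignore_index=True)
    p2 = pd.concat([psi_per_isoform(t) for t in group2], ignore_index=True)
    return p1, p2, truth
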