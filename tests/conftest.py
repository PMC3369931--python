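import pytest

from antarscan.motif import train_model
from antarscan.simulate import (eutp_leader_record, generate_genome,
                                synthetic_seed_alignment)


@pytest.fixture(scope="session")
def seed_alignment():
    return synthetic_seed_alignment()


@pytest.fixture(scope="session")
def model(seed_alignment):
    return train_model(seed_alignment)


@pytest.fixture(scope="session")
def leader():
    return eutp_leader_record()


@pytest.fixture(scope="session")
def genome_bundle():
    """One screened synthetic genome shared by the end-to-end tests."""
    return generate_genome(seed=0, n_in_cds=1)
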