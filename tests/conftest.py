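import numpy as np
import pytest
from hypothesis import settings

import fdcrowd as fd

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_genome():
    """2 kbp circular synthetic genome with the operator at a known position."""
    return fd.generate_genome(2000, seed=11)


@pytest.fixture(scope="session")
def small_pwm():
    return fd.generate_pwm(seed=11)


@pytest.fixture(scope="session")
def small_landscape(small_genome, small_pwm):
    return fd.build_landscape(small_pwm, small_genome, tau0=1e-5, beta=1.0)


@pytest.fixture()
def flat_single_molecule():
    """One sequence-nonspecific molecule on an empty 1 kbp circular genome."""
    genome = fd.generate_genome(1000, seed=5)
    species = [fd.noncognate_species(1, k_assoc=1800.0)]
    return genome, species
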