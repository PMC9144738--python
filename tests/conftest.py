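import numpy as np
import pytest
from hypothesis import settings

import tisseq as t

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def element():
    return t.make_element()


@pytest.fixture(scope="session")
def design(element):
    return t.LibraryDesign.for_element(element)


@pytest.fixture(scope="session")
def small_genome():
    return t.generate_genome([200_000], 0.42, seed=1)


@pytest.fixture(scope="session")
def small_truth(small_genome, element, design):
    return t.plant_insertions(small_genome, element, 2, 20, seed=2, design=design)


@pytest.fixture(scope="session")
def library(small_genome, small_truth, design):
    """One simulated amplicon library at default (realistic) settings."""
    reads, read_truth, site_table = t.simulate_tisseq_library(
        small_genome, small_truth, design, "s1", seed=3
    )
    return reads, read_truth, site_table


@pytest.fixture(scope="session")
def clean_design(element):
    """Artifact- and error-free design, for exact-recovery checks."""
    return t.LibraryDesign.for_element(
        element, error_rate=0.0, chimera_rate=0.0, contaminant_rate=0.0, depth=2000
    )


@pytest.fixture(scope="session")
def clean_library(small_genome, small_truth, clean_design):
    reads, read_truth, site_table = t.simulate_tisseq_library(
        small_genome, small_truth, clean_design, "clean", seed=4
    )
    return reads, read_truth, site_table


def random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=n))
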