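import numpy as np
import pytest

from hladr import datasets
from hladr.alignment import CohortGenotypes, parse_allele_table, translate_cohort


@pytest.fixture(scope="session")
def demo_table():
    return datasets.demo_allele_table()


@pytest.fixture(scope="session")
def demo_cohort():
    """One seeded study-scale cohort with the Asn37 risk effect."""
    from hladr.simulate import demo_spec, generate_cohort

    return generate_cohort(demo_spec(seed=20110601))


@pytest.fixture(scope="session")
def demo_matrix(demo_cohort, demo_table):
    return translate_cohort(demo_cohort, demo_table)


@pytest.fixture
def tiny_table():
    """Two positions (1, 2), three alleles differing at position 1."""
    return parse_allele_table(
        "allele\t1\t2\n"
        "DRB1*90:01\tN\tS\n"
        "DRB1*90:02\tY\tS\n"
        "DRB1*90:03\tF\tS\n"
    )


def make_cohort(rows):
    """rows: (sample_id, status, allele_a, allele_b)."""
    return CohortGenotypes(records=list(rows))


@pytest.fixture
def rng():
    return np.random.default_rng(7)
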