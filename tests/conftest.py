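import pytest

from rnaneo import parse_allele
from rnaneo.fixtures import CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def mouse_alleles():
    return [parse_allele(n) for n in ("H-2-Kd", "H-2-Dd", "H-2-IAd")]


@pytest.fixture(scope="session")
def cohort(tmp_path_factory):
    """A small free-draw cohort shared across read-only tests."""
    config = CohortConfig(n_genes=20, n_variants=40, seed=11)
    return generate_cohort(config, tmp_path_factory.mktemp("cohort"))


@pytest.fixture(scope="session")
def hard_cohort(tmp_path_factory):
    """Cohort exercising multi-exon and reverse-strand transcript models."""
    config = CohortConfig(n_genes=16, n_variants=40, seed=5,
                          multi_exon_fraction=0.4,
                          reverse_strand_fraction=0.4)
    return generate_cohort(config, tmp_path_factory.mktemp("hard_cohort"))
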