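import pytest

from sjkit.models import (
    exons_from_table,
    load_allelic_count_table,
    load_antisense_exon_table,
    load_sense_exon_table,
    load_sense_junction_table,
)
from sjkit.simulate import LocusSpec, generate_locus, simulate_reads


@pytest.fixture(scope="session")
def sense_exon_table():
    return load_sense_exon_table()


@pytest.fixture(scope="session")
def antisense_exon_table():
    return load_antisense_exon_table()


@pytest.fixture(scope="session")
def sense_junction_table():
    return load_sense_junction_table()


@pytest.fixture(scope="session")
def allelic_table():
    return load_allelic_count_table()


@pytest.fixture(scope="session")
def sense_exons(sense_exon_table):
    return exons_from_table(sense_exon_table)


@pytest.fixture(scope="session")
def antisense_exons(antisense_exon_table):
    return exons_from_table(antisense_exon_table)


@pytest.fixture(scope="session")
def default_truth():
    """Default synthetic two-gene locus, seed 1."""
    return generate_locus(LocusSpec(seed=1))


@pytest.fixture(scope="session")
def default_reads(default_truth):
    """Reads at 150 samples, 5x per-sample exon depth (seed 1)."""
    return simulate_reads(default_truth, n_samples=150, depth=5.0, seed=1)
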