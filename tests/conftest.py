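"""Shared fixtures: the packaged 16S haplotype table and its expansion."""

from importlib.resources import files

import pytest
from hypothesis import settings

import phylopop as pp

settings.register_profile("reproducible", derandomize=True, deadline=None)
settings.load_profile("reproducible")

EP, CPWP = "EP", "CP+WP"


@pytest.fixture(scope="session")
def fixture_dir():
    return files("phylopop") / "fixtures"


@pytest.fixture(scope="session")
def table16s(fixture_dir):
    return pp.parse_haplotype_table(fixture_dir / "table3_16s.tsv")


@pytest.fixture(scope="session")
def groups16s(fixture_dir):
    return pp.read_group_map(fixture_dir / "groups_16s.tsv")


@pytest.fixture(scope="session")
def aln16s(table16s, groups16s):
    """The 20-individual 16S alignment reconstructed from the table."""
    return pp.expand_table(table16s, groups16s)


@pytest.fixture(scope="session")
def matrix16s(aln16s):
    return pp.distance_matrix(aln16s)
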