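from __future__ import annotations

import networkx as nx
import pytest
from hypothesis import HealthCheck, settings

from condl import GeneDictionary, normalize_mentions
from condl import fixtures as fx
from condl.associations import AssociationTable, build_concept_network

settings.register_profile(
    "package",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("package")


WORKED_EXAMPLE_DICTIONARY = {
    "IFNA1": ["IFN-alpha"],
    "IL12B": ["IL-12"],
    "TNF": ["TNF-alpha"],
    "IL10": ["IL-10"],
}


@pytest.fixture(scope="session")
def worked_example_dictionary() -> GeneDictionary:
    return GeneDictionary(WORKED_EXAMPLE_DICTIONARY)


@pytest.fixture(scope="session")
def worked_example(worked_example_dictionary):
    """The worked-example sentence with mentions normalized to symbols."""
    return normalize_mentions(fx.worked_example_sentence(), worked_example_dictionary)


@pytest.fixture(scope="session")
def worked_example_mentions(worked_example):
    return {m.surface: m for m in worked_example.mentions}


@pytest.fixture(scope="session")
def table2_network() -> nx.Graph:
    table = AssociationTable.from_gene_sets(fx.table2_gene_sets())
    return build_concept_network(table)
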