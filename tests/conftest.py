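"""Shared fixtures: small handcrafted layouts and synthetic study objects."""

import pytest

from cofunc.genome import GeneRecord, GenomeLayout
from cofunc.groups import FunctionalGroup, GroupCollection
from cofunc.synthetic import (
    SyntheticConfig,
    generate_contact_map,
    generate_genome,
    generate_groups,
)


@pytest.fixture
def toy_layout() -> GenomeLayout:
    """Seven genes on three chromosomes with easy midpoints."""
    return GenomeLayout(
        [
            GeneRecord("a", "chr1", 100, 300),    # mid 200
            GeneRecord("b", "chr1", 500, 700),    # mid 600
            GeneRecord("c", "chr1", 900, 1100),   # mid 1000
            GeneRecord("d", "chr2", 0, 200),      # mid 100
            GeneRecord("e", "chr2", 400, 600),    # mid 500
            GeneRecord("f", "chr3", 50, 150),     # mid 100
            GeneRecord("g", "chr3", 250, 350),    # mid 300
        ]
    )


@pytest.fixture
def toy_collection() -> GroupCollection:
    return GroupCollection(
        "pathway",
        (
            FunctionalGroup("G1", "pathway", frozenset({"a", "b", "c"})),
            FunctionalGroup("G2", "pathway", frozenset({"a", "d"})),
            FunctionalGroup("G3", "pathway", frozenset({"b", "e", "f", "g"})),
        ),
    )


@pytest.fixture(scope="session")
def small_study():
    """A 3-chromosome synthetic study with a contact map, reused read-only."""
    cfg = SyntheticConfig(
        n_chromosomes=3,
        genes_per_chromosome=(30, 25, 20),
        n_groups=12,
        seed=42,
    )
    layout = generate_genome(cfg)
    collection = generate_groups(layout, cfg, "null")
    cmap = generate_contact_map(layout, cfg)
    return cfg, layout, collection, cmap
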