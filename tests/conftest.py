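import numpy as np
import pandas as pd
import pytest

from parweb.networks import (
    InteractionRecord,
    MetaNetwork,
    TraitTable,
    PHENO_COLUMNS,
)


def make_trait_row(species_id, guild, body_size, pheno, nd=0.5, status="native",
                   abundance=10):
    row = {
        "species_id": species_id,
        "guild": guild,
        "body_size": body_size,
        "biogeographic_status": status if guild == "host" else "",
        "nd": nd,
        "total_abundance": abundance,
    }
    for col, value in zip(PHENO_COLUMNS, pheno):
        row[col] = value
    return row


@pytest.fixture
def small_traits():
    """Three hosts and three parasitoids with simple, distinct traits."""
    rows = [
        make_trait_row("H:a", "host", 4.0, [1, 1, 0, 0, 0, 0, 0], nd=0.2),
        make_trait_row("H:b", "host", 8.0, [0, 0, 1, 1, 0, 0, 0], nd=0.5,
                       status="exotic"),
        make_trait_row("H:c", "host", 16.0, [0, 0, 0, 0, 1, 1, 1], nd=0.8),
        make_trait_row("P:x", "parasitoid", 2.0, [1, 1, 0, 0, 0, 0, 0], nd=0.3),
        make_trait_row("P:y", "parasitoid", 4.0, [0, 0, 1, 1, 0, 0, 0], nd=0.6),
        make_trait_row("P:z", "parasitoid", 8.0, [0, 0, 0, 0, 1, 1, 1], nd=0.9),
    ]
    return TraitTable(pd.DataFrame(rows))


@pytest.fixture
def small_meta():
    counts = pd.DataFrame(
        [[4, 0, 0], [1, 3, 0], [0, 0, 5]],
        index=["H:a", "H:b", "H:c"],
        columns=["P:x", "P:y", "P:z"],
    )
    return MetaNetwork(counts=counts, mode="weighted", provenance="combined")


def make_records():
    """Six interaction records over two habitats and two sites."""
    base = dict(transect="edge", occasion=1, time_step="training")
    return [
        InteractionRecord(site_id="s1", habitat="native", host_id="H:a",
                          parasitoid_id="P:x", count=2, **base),
        InteractionRecord(site_id="s1", habitat="native", host_id="H:b",
                          parasitoid_id="P:x", count=1, **base),
        InteractionRecord(site_id="s2", habitat="native", host_id="H:a",
                          parasitoid_id="P:x", count=2, **base),
        InteractionRecord(site_id="s2", habitat="native", host_id="H:b",
                          parasitoid_id="P:y", count=3, **base),
        InteractionRecord(site_id="s3", habitat="plantation", host_id="H:c",
                          parasitoid_id="P:z", count=4, **base),
        InteractionRecord(site_id="s3", habitat="plantation", host_id="H:a",
                          parasitoid_id="P:y", count=1, **base),
    ]


@pytest.fixture
def records():
    return make_records()
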